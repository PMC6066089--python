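"""Chromatin-feature overlap enrichment, epigenetic-switching detection, and
ChIP-qPCR fold-enrichment arithmetic.

Overlap enrichment compares the fraction of a probe set falling inside a
genomic interval track against the array background (all manifest probes by
default) with a Fisher exact test. Epigenetic switching — Polycomb (H3K27me3)
repression in stem cells replaced by DNA hypermethylation in tumor cells — is
detected as tumor-hypermethylated probes lying inside a reference Polycomb
occupancy track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import IntervalTrack, ProbeAnnotationTable, ValidationError

OR_CAP = 1e6


@dataclass
class EnrichmentRow:
    track: str
    n_set: int
    n_set_in: int
    n_background: int
    n_background_in: int
    pct_in_set: float
    pct_in_background: float
    odds_ratio: float
    or_capped: bool
    fisher_p: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _positions(manifest: ProbeAnnotationTable, probe_ids) -> tuple[np.ndarray, np.ndarray]:
    probes = manifest.probes.loc[list(probe_ids)]
    return probes["chrom"].to_numpy(), probes["pos"].to_numpy(int)


def overlap_enrichment(probe_ids, track: IntervalTrack, manifest: ProbeAnnotationTable,
                       background_ids=None) -> EnrichmentRow:
    """Fisher enrichment of a probe set inside a track vs the array background.

    The background defaults to all manifest probes (the set is part of its
    own background, as when comparing against the full array annotation).
    Probe-in-interval uses the half-open rule. Degenerate odds ratios are
    capped at 1e6 and flagged.
    """
    probe_ids = sorted(set(probe_ids))
    if not probe_ids:
        raise ValidationError("empty probe set")
    if len(track) == 0:
        raise ValidationError("empty interval track")
    if background_ids is None:
        background_ids = manifest.probe_ids
    background_ids = sorted(set(background_ids))

    sc, sp = _positions(manifest, probe_ids)
    bc, bp = _positions(manifest, background_ids)
    set_in = int(track.contains(sc, sp).sum())
    bg_in = int(track.contains(bc, bp).sum())
    n_set, n_bg = len(probe_ids), len(background_ids)
    table = np.array([[set_in, n_set - set_in], [bg_in, n_bg - bg_in]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    num = set_in * (n_bg - bg_in)
    den = (n_set - set_in) * bg_in
    capped = False
    if den == 0:
        odds = 0.0 if num == 0 else OR_CAP
        capped = num != 0
    else:
        odds = num / den
        if odds > OR_CAP:
            odds, capped = OR_CAP, True
    return EnrichmentRow(
        track=track.name,
        n_set=n_set,
        n_set_in=set_in,
        n_background=n_bg,
        n_background_in=bg_in,
        pct_in_set=100.0 * set_in / n_set,
        pct_in_background=100.0 * bg_in / n_bg,
        odds_ratio=float(odds),
        or_capped=capped,
        fisher_p=float(p),
    )


def detect_switching(hyper_ids, manifest: ProbeAnnotationTable,
                     polycomb_track: IntervalTrack) -> tuple[set[str], pd.DataFrame]:
    """Probes hypermethylated in tumors AND inside the Polycomb track.

    Returns the switched probe set and a per-gene rollup (switched probe
    count per annotated gene, e.g. HOX-cluster style blocks).
    """
    hyper_ids = sorted(set(hyper_ids))
    if not hyper_ids:
        return set(), pd.DataFrame(columns=["gene", "n_switched"]).set_index("gene")
    chroms, pos = _positions(manifest, hyper_ids)
    inside = polycomb_track.contains(chroms, pos)
    switched = {pid for pid, ok in zip(hyper_ids, inside) if ok}
    rec = manifest.records
    rows = rec[rec["probe_id"].isin(switched) & (rec["gene"] != "")]
    rollup = (
        rows.groupby("gene")["probe_id"].nunique().rename("n_switched").to_frame()
        .sort_values("n_switched", ascending=False)
    )
    return switched, rollup


def chip_fold_enrichment(target_signal: float, target_norm: float,
                         control_signal: float, control_norm: float) -> float:
    """Fold enrichment of a ChIP signal at a target locus over a control region.

    fold = (signal/normalizer at target) / (signal/normalizer at control),
    where the normalizer is total H3 or input. With quantities derived from
    Ct at 100% efficiency this equals 2^(ΔΔCt).
    """
    for q in (target_signal, target_norm, control_signal, control_norm):
        if q <= 0:
            raise ValueError("ChIP quantities must be > 0")
    return (target_signal / target_norm) / (control_signal / control_norm)
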