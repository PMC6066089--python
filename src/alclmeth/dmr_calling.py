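"""Region-level differential methylation (DMR calling).

Probes are aggregated over the annotated region categories: per gene and
category (TSS1500, TSS200, 5'UTR, first exon, body, 3'UTR) plus a merged
per-gene TSS view (TSS200 ∪ TSS1500), and contiguous runs of probes sharing a
CpG-island relation (island, shore, shelf). Region β per sample is the
arithmetic mean of member probes; testing is Welch on M-transformed region
means with BH adjustment within each category family, and the filter is
p_adj < 0.05 (strict) with |Δβ| ≥ 0.15 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import (
    BetaMatrix,
    ProbeAnnotationTable,
    SampleSheet,
    ValidationError,
    GENE_LINKED_CATEGORIES,
    ISLAND_FEATURES,
)
from .mvp_calling import DEFAULT_EPSILON, beta_to_m, bh_adjust, welch_t

MERGED_TSS = "TSS"
DMR_CATEGORIES = tuple(GENE_LINKED_CATEGORIES) + (MERGED_TSS,) + tuple(ISLAND_FEATURES)


@dataclass
class RegionBetaMatrix:
    """Regions × samples mean methylation plus per-region metadata."""

    df: pd.DataFrame  # region_id × sample
    info: pd.DataFrame  # region_id × (category, gene, chrom, start, end, n_probes)

    def __len__(self) -> int:
        return len(self.df)


def region_members(manifest: ProbeAnnotationTable) -> pd.DataFrame:
    """region_id → member probes, one row per (region_id, probe_id).

    Gene-linked categories use id ``gene|category``; the merged promoter view
    uses ``gene|TSS``; island features use contiguous same-relation probe
    runs with id ``chrom:start-end|relation``.
    """
    rows = []
    rec = manifest.records
    gene_linked = rec[rec["region_category"].isin(GENE_LINKED_CATEGORIES) & (rec["gene"] != "")]
    for r in gene_linked.itertuples():
        rows.append((f"{r.gene}|{r.region_category}", r.region_category, r.gene, r.probe_id))
        if r.region_category in ("TSS200", "TSS1500"):
            rows.append((f"{r.gene}|{MERGED_TSS}", MERGED_TSS, r.gene, r.probe_id))

    probes = manifest.probes.sort_values(["chrom", "pos"])
    run_chrom = run_rel = None
    run: list[tuple[str, int]] = []

    def flush():
        if run and run_rel in ISLAND_FEATURES:
            start, end = run[0][1], run[-1][1] + 1
            rid = f"{run_chrom}:{start}-{end}|{run_rel}"
            for pid, _ in run:
                rows.append((rid, run_rel, "", pid))

    for pid, pr in probes.iterrows():
        if pr["chrom"] != run_chrom or pr["island_relation"] != run_rel:
            flush()
            run_chrom, run_rel = pr["chrom"], pr["island_relation"]
            run = []
        run.append((pid, int(pr["pos"])))
    flush()
    df = pd.DataFrame(rows, columns=["region_id", "category", "gene", "probe_id"])
    # a probe may map to one region only once even if listed twice in the manifest
    return df.drop_duplicates(["region_id", "probe_id"]).reset_index(drop=True)


def aggregate_regions(beta: BetaMatrix, manifest: ProbeAnnotationTable) -> RegionBetaMatrix:
    """Per region and sample, the arithmetic mean of member-probe β values.

    Regions whose probes are all absent from the β matrix are dropped.
    """
    members = region_members(manifest)
    members = members[members["probe_id"].isin(beta.probe_ids)]
    if members.empty:
        raise ValidationError("no region has probes present in the beta matrix")
    vals = pd.DataFrame(beta.df.loc[members["probe_id"]].to_numpy(dtype=float),
                        columns=beta.sample_ids)
    keys = members["region_id"].to_numpy()
    grouped = vals.groupby(keys)
    # mean computed as first + mean(x - first): exact when all member rows agree
    first = grouped.transform("first")
    agg = (vals - first).groupby(keys).mean() + grouped.first()
    agg.index.name = "region_id"

    pos = manifest.probes["pos"]
    chrom = manifest.probes["chrom"]
    info = members.assign(
        pos=pos.loc[members["probe_id"]].to_numpy(int),
        chrom=chrom.loc[members["probe_id"]].to_numpy(),
    ).groupby("region_id").agg(
        category=("category", "first"),
        gene=("gene", "first"),
        chrom=("chrom", "first"),
        start=("pos", "min"),
        end=("pos", "max"),
        n_probes=("probe_id", "nunique"),
    )
    info["end"] = info["end"] + 1  # half-open span over member probes
    return RegionBetaMatrix(agg, info.loc[agg.index])


def call_dmrs(regions: RegionBetaMatrix, sheet: SampleSheet, group_a: str, group_b: str,
              p_adj_max: float = 0.05, min_abs_delta: float = 0.15,
              epsilon: float = DEFAULT_EPSILON) -> pd.DataFrame:
    """Welch test on M-transformed region means; BH within each category.

    Returns one row per region: category, n_probes, mean_beta_a, mean_beta_b,
    delta_beta, m_stat, p, p_adj, direction, significant. The significance
    filter is p_adj < p_adj_max (strict) and |Δβ| ≥ min_abs_delta (inclusive).
    """
    sa, sb = sheet.samples(group_a), sheet.samples(group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValidationError(f"need >= 2 samples in both {group_a} and {group_b}")
    a = regions.df[sa].to_numpy(dtype=float)
    b = regions.df[sb].to_numpy(dtype=float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    t, p, floored = welch_t(beta_to_m(a, epsilon), beta_to_m(b, epsilon))
    out = pd.DataFrame(
        {
            "category": regions.info["category"],
            "gene": regions.info["gene"],
            "n_probes": regions.info["n_probes"],
            "mean_beta_a": ma,
            "mean_beta_b": mb,
            "delta_beta": ma - mb,
            "m_stat": t,
            "p": p,
            "var_floored": floored,
        },
        index=regions.df.index,
    )
    out["p_adj"] = np.nan
    for _, idx in out.groupby("category").groups.items():
        out.loc[idx, "p_adj"] = bh_adjust(out.loc[idx, "p"].to_numpy())
    out["direction"] = np.where(out["delta_beta"] > 0, "hyper", "hypo")
    out["significant"] = significance_mask(out, p_adj_max, min_abs_delta)
    return out


def significance_mask(dmr_table: pd.DataFrame, p_adj_max: float = 0.05,
                      min_abs_delta: float = 0.15) -> pd.Series:
    """p_adj strictly below the cutoff, |Δβ| at or above the effect cutoff."""
    return (dmr_table["p_adj"] < p_adj_max) & (dmr_table["delta_beta"].abs() >= min_abs_delta)


def count_by_category(dmr_table: pd.DataFrame) -> pd.DataFrame:
    """Significant-DMR counts per category × direction."""
    out = pd.DataFrame(0, index=list(DMR_CATEGORIES), columns=["hyper", "hypo"])
    sig = dmr_table[dmr_table["significant"] == True]  # noqa: E712 (empty-frame safe)
    if sig.empty:
        return out
    for (cat, direction), cnt in sig.groupby(["category", "direction"]).size().items():
        out.loc[cat, direction] = int(cnt)
    return out


def export_bed(dmr_table: pd.DataFrame, regions: RegionBetaMatrix, path,
               significant_only: bool = True) -> None:
    """Write DMR spans (min..max member-probe position, half-open) as BED3."""
    tab = dmr_table[dmr_table["significant"]] if significant_only else dmr_table
    info = regions.info.loc[tab.index]
    df = pd.DataFrame({
        "chrom": info["chrom"],
        "start": info["start"].astype(int),
        "end": info["end"].astype(int),
    }).sort_values(["chrom", "start"])
    df.to_csv(path, sep="\t", header=False, index=False)
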