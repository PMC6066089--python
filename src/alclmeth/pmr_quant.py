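"""MethyLight-style PMR (percentage of methylated reference) quantification.

PMR = 100 × [(GeneX mean quantity / Alu mean quantity) of the sample] /
[(GeneX mean quantity / Alu mean quantity) of fully methylated
M.SssI-treated DNA]. Quantities are derived from Ct values at a fixed
amplification efficiency (100% by default, quantity = 2^−Ct); replicate
quantities are averaged on the quantity scale before forming ratios.
Group comparison follows the one-way-ANOVA-then-pairwise-Welch scheme.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CtTable, ValidationError

DEFAULT_EFFICIENCY = 1.0
REF_SAMPLE = "MSssI"
ALU_ASSAY = "Alu"


def quantity_from_ct(ct, efficiency: float = DEFAULT_EFFICIENCY):
    """Relative template quantity (1+E)^(−Ct); NaN ('no amplification') → 0."""
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    arr = np.asarray(ct, dtype=float)
    qty = np.where(np.isnan(arr), 0.0, (1.0 + efficiency) ** (-arr))
    return qty if qty.shape else float(qty)


def compute_pmr(sample_genex_ct, sample_alu_ct, ref_genex_ct, ref_alu_ct,
                efficiency: float = DEFAULT_EFFICIENCY) -> float:
    """PMR from replicate Ct arrays of sample and M.SssI reference.

    Means are taken over replicates on the quantity scale. PMR may exceed
    100 (it is reported, never clipped). Zero Alu or reference quantity is a
    normalization error; an all-no-amplification GeneX reaction gives PMR 0.
    """
    sg = np.mean(quantity_from_ct(sample_genex_ct, efficiency))
    sa = np.mean(quantity_from_ct(sample_alu_ct, efficiency))
    rg = np.mean(quantity_from_ct(ref_genex_ct, efficiency))
    ra = np.mean(quantity_from_ct(ref_alu_ct, efficiency))
    if sa <= 0 or ra <= 0:
        raise ValidationError("Alu normalizer quantity is zero")
    if rg <= 0:
        raise ValidationError("M.SssI reference GeneX quantity is zero")
    return 100.0 * (sg / sa) / (rg / ra)


def pmr_table(ct: CtTable, genes: list[str] | None = None,
              ref_sample: str = REF_SAMPLE, alu_assay: str = ALU_ASSAY,
              efficiency: float = DEFAULT_EFFICIENCY) -> pd.DataFrame:
    """PMR per (sample, gene) from a replicate-level Ct table.

    Every assay needs reference rows for ``ref_sample``. Returns a tidy
    DataFrame: sample_id, gene, pmr, exceeds_100.
    """
    assays = sorted(set(ct.df["assay"]) - {alu_assay})
    if genes is not None:
        missing = set(genes) - set(assays)
        if missing:
            raise ValidationError(f"assay(s) absent from Ct table: {sorted(missing)}")
        assays = list(genes)
    samples = [s for s in ct.df["sample_id"].unique() if s != ref_sample]
    ref_alu = ct.replicates(ref_sample, alu_assay)
    if ref_alu.size == 0:
        raise ValidationError(f"reference sample {ref_sample!r} has no {alu_assay} rows")
    rows = []
    for gene in assays:
        ref_gene = ct.replicates(ref_sample, gene)
        if ref_gene.size == 0:
            raise ValidationError(f"reference sample {ref_sample!r} missing assay {gene!r}")
        for s in samples:
            sg = ct.replicates(s, gene)
            sa = ct.replicates(s, alu_assay)
            if sg.size == 0 or sa.size == 0:
                continue
            pmr = compute_pmr(sg, sa, ref_gene, ref_alu, efficiency)
            rows.append(dict(sample_id=s, gene=gene, pmr=pmr, exceeds_100=pmr > 100.0))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "pmr", "exceeds_100"])


@dataclass
class GroupComparison:
    anova_f: float
    anova_p: float
    zero_variance: bool
    group_stats: pd.DataFrame  # group × (n, mean, sem)
    pairwise: pd.DataFrame  # group vs control Welch t results (empty if ANOVA ns)


def compare_groups(pmr: pd.DataFrame, groups: pd.DataFrame, control_group: str,
                   alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA across groups, then pairwise Welch t vs control.

    ``pmr`` is a pmr_table result for one gene; ``groups`` maps sample_id →
    group. Pairwise tests run only when ANOVA p < alpha. All-constant input
    is degenerate: p is reported as 1 with a zero-variance flag.
    """
    merged = pmr.merge(groups, on="sample_id")
    if control_group not in set(merged["group"]):
        raise ValidationError(f"control group {control_group!r} has no samples")
    by_group = {g: sub["pmr"].to_numpy(float) for g, sub in merged.groupby("group")}
    if len(by_group) < 2:
        raise ValidationError("need >= 2 groups to compare")
    arrays = list(by_group.values())
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        f_stat, p, zero_var = 0.0, 1.0, True
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            f_stat, p = stats.f_oneway(*arrays)
        zero_var = not np.isfinite(f_stat)
        if zero_var:
            f_stat, p = 0.0, 1.0
    gs = pd.DataFrame(
        {
            "n": {g: len(a) for g, a in by_group.items()},
            "mean": {g: float(np.mean(a)) for g, a in by_group.items()},
            "sem": {g: float(stats.sem(a)) if len(a) > 1 else np.nan
                    for g, a in by_group.items()},
        }
    )
    pair_rows = []
    if p < alpha:
        ctrl = by_group[control_group]
        for g, a in by_group.items():
            if g == control_group:
                continue
            t, tp = stats.ttest_ind(a, ctrl, equal_var=False)
            pair_rows.append(dict(group=g, t=float(t), p=float(tp)))
    pairwise = pd.DataFrame(pair_rows, columns=["group", "t", "p"])
    return GroupComparison(float(f_stat), float(p), zero_var, gs, pairwise)
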