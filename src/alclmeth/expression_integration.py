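"""Promoter-methylation × gene-expression concordance.

Significant promoter (TSS) DMRs are joined to a linear-scale expression
table by gene symbol and classified by the tumor/control fold change:
concordant pairs are hypermethylated∧downregulated and
hypomethylated∧upregulated; the two discordant classes are reported too.
Up/down means strictly more than 1.5-fold in either direction by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .core_io import ExpressionTable, SampleSheet, ValidationError

log = logging.getLogger(__name__)

DEFAULT_FOLD = 1.5


def fold_change(expr_a_mean: float, expr_b_mean: float) -> float:
    """Ratio of linear-scale group means a/b."""
    if expr_a_mean <= 0 or expr_b_mean <= 0:
        raise ValueError("expression means must be > 0")
    return expr_a_mean / expr_b_mean


def percent_round_half_up(count: int, denom: int) -> int:
    """Integer percentage, rounding halves up: 100 × count/denom."""
    if denom <= 0:
        return 0
    return int(math.floor(100.0 * count / denom + 0.5))


@dataclass
class ConcordanceSummary:
    """Counts and integer percentages for the four methylation×expression classes."""

    n_hyper: int
    n_hypo: int
    hyper_down: int
    hypo_up: int
    hyper_up: int
    hypo_down: int
    n_unmapped: int

    def percentages(self) -> dict[str, int]:
        return {
            "hyper_down_pct": percent_round_half_up(self.hyper_down, self.n_hyper),
            "hypo_up_pct": percent_round_half_up(self.hypo_up, self.n_hypo),
            "hyper_up_pct": percent_round_half_up(self.hyper_up, self.n_hyper),
            "hypo_down_pct": percent_round_half_up(self.hypo_down, self.n_hypo),
        }

    def as_dict(self) -> dict:
        d = {
            "n_hyper": self.n_hyper,
            "n_hypo": self.n_hypo,
            "hyper_down": self.hyper_down,
            "hypo_up": self.hypo_up,
            "hyper_up": self.hyper_up,
            "hypo_down": self.hypo_down,
            "n_unmapped": self.n_unmapped,
        }
        d.update(self.percentages())
        return d


def classify_concordance(dmr_table: pd.DataFrame, expr: ExpressionTable,
                         sheet: SampleSheet, group_a: str, group_b: str,
                         fold: float = DEFAULT_FOLD,
                         tss_categories: tuple[str, ...] = ("TSS",),
                         ) -> tuple[ConcordanceSummary, pd.DataFrame]:
    """Classify significant TSS DMRs against expression fold changes.

    ``dmr_table`` is a call_dmrs result; only rows with
    ``significant == True`` and a category in ``tss_categories`` enter.
    Denominators are the hyper/hypo TSS DMRs whose gene is present in the
    expression table; unmapped genes are dropped from numerator and
    denominator with a logged count. up: ratio > fold (strict);
    down: ratio < 1/fold (strict). Returns the summary plus a per-gene table.
    """
    if expr.df.index.duplicated().any():
        raise ValidationError("duplicate gene rows in expression table")
    sa, sb = sheet.samples(group_a), sheet.samples(group_b)
    if not sa or not sb:
        raise ValidationError("both groups must have expression samples")
    tss = dmr_table[dmr_table["significant"] & dmr_table["category"].isin(tss_categories)]
    # one direction per gene; if a gene has several TSS DMRs keep the smallest p
    tss = tss.sort_values("p")
    tss = tss[~tss["gene"].duplicated().to_numpy()]
    genes = tss["gene"]
    mapped = genes.isin(expr.df.index)
    n_unmapped = int((~mapped).sum())
    if n_unmapped:
        log.info("dropping %d TSS DMR gene(s) absent from expression table", n_unmapped)
    tss = tss[mapped.to_numpy()]

    mean_a = expr.df.loc[tss["gene"], sa].mean(axis=1).to_numpy()
    mean_b = expr.df.loc[tss["gene"], sb].mean(axis=1).to_numpy()
    ratio = mean_a / mean_b
    per_gene = pd.DataFrame(
        {
            "gene": tss["gene"].to_numpy(),
            "direction": tss["direction"].to_numpy(),
            "delta_beta": tss["delta_beta"].to_numpy(),
            "expr_ratio": ratio,
        }
    ).set_index("gene")
    up = per_gene["expr_ratio"] > fold
    down = per_gene["expr_ratio"] < 1.0 / fold
    per_gene["expr_class"] = "flat"
    per_gene.loc[up, "expr_class"] = "up"
    per_gene.loc[down, "expr_class"] = "down"
    hyper = per_gene["direction"] == "hyper"
    hypo = per_gene["direction"] == "hypo"
    summary = ConcordanceSummary(
        n_hyper=int(hyper.sum()),
        n_hypo=int(hypo.sum()),
        hyper_down=int((hyper & down).sum()),
        hypo_up=int((hypo & up).sum()),
        hyper_up=int((hyper & up).sum()),
        hypo_down=int((hypo & down).sum()),
        n_unmapped=n_unmapped,
    )
    return summary, per_gene
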