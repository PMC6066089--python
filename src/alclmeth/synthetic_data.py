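"""Synthetic cohorts with ground truth.

Emulates the statistical structure of a 450K-style tumor/control methylation
study: two tumor groups plus one control group (n = 5 each by default),
bimodal Beta-distributed probe methylation, differential probes planted in
region-sized blocks at a chosen Δβ, an expression table with a controllable
methylation–expression concordance rate, chromatin tracks covering a chosen
fraction of hypermethylated sites, 100-bp sequence windows with a planted
AP1-like motif, and MethyLight Ct tables back-computed from true PMR values.

Every generator is deterministic under the config seed. A single cohort seed
fans out to fixed per-generator child seeds so adding one generator never
reshuffles another.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    BetaMatrix,
    CtTable,
    ExpressionTable,
    IntervalTrack,
    ProbeAnnotationTable,
    SampleSheet,
    GENE_LINKED_CATEGORIES,
    ISLAND_RELATIONS,
    REGION_CATEGORIES,
)

# fixed tags for per-generator child seeds
_TAG_COHORT = 1
_TAG_EXPRESSION = 2
_TAG_TRACKS = 3
_TAG_SEQUENCES = 4
_TAG_CT = 5
_TAG_STAGES = 6

BETA_FLOOR, BETA_CEIL = 0.02, 0.98
_MEAN_LO, _MEAN_HI = 0.05, 0.95  # truncation of baseline probe means

# probability that a block's baseline sits in the methylated (high) component,
# by CpG-island relation: islands are normally unmethylated, open sea methylated
_P_HIGH = {"Island": 0.1, "Shore": 0.3, "Shelf": 0.6, "OpenSea": 0.8}


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), tag)))


@dataclass
class TruthEffect:
    direction: str  # "hyper" | "hypo"
    delta: float  # signed realized shift (affected − control), |delta| <= 1
    affected_groups: tuple[str, ...]


@dataclass
class TruthSet:
    """Ground truth of planted effects, keyed as downstream callers report them."""

    mvp_truth: dict[str, TruthEffect] = field(default_factory=dict)
    dmr_truth: dict[str, TruthEffect] = field(default_factory=dict)
    motif_truth: set[str] = field(default_factory=set)
    concordant_genes: set[str] = field(default_factory=set)

    def hyper_probes(self) -> list[str]:
        return [p for p, e in self.mvp_truth.items() if e.direction == "hyper"]

    def hypo_probes(self) -> list[str]:
        return [p for p, e in self.mvp_truth.items() if e.direction == "hypo"]

    def to_json(self, path) -> None:
        payload = {
            "mvp_truth": {k: asdict(v) for k, v in sorted(self.mvp_truth.items())},
            "dmr_truth": {k: asdict(v) for k, v in sorted(self.dmr_truth.items())},
            "motif_truth": sorted(self.motif_truth),
            "concordant_genes": sorted(self.concordant_genes),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class CohortConfig:
    """Study conditions for the simulated cohort.

    Defaults mirror the analysis this package targets: three groups of five
    samples, Δβ = 0.3 effects, a ~13% methylation–expression concordance
    rate, and a 30% motif plant rate in hypomethylated windows.
    """

    n_probes: int = 10_000
    n_per_group: int = 5
    groups: tuple[str, ...] = ("ALK_POS", "ALK_NEG", "CONTROL")
    fraction_hyper: float = 0.02
    fraction_hypo: float = 0.02
    delta_beta: float = 0.3
    beta_shape_lo: tuple[float, float] = (1.0, 9.0)  # baseline mean ~ 0.1
    beta_shape_hi: tuple[float, float] = (8.5, 1.5)  # baseline mean ~ 0.85
    mix_weight_hi: float = 0.5
    precision: float = 100.0  # Beta noise precision; sd ~ sqrt(m(1-m)/(1+prec))
    probes_per_region: tuple[int, int] = (2, 8)
    concordance_rate: float = 0.13
    motif_plant_rate: float = 0.3
    affected_groups: tuple[str, ...] = ("ALK_POS", "ALK_NEG")
    shared_effect_rate: float = 0.7  # fraction of spiked blocks affecting all tumor groups
    probe_spacing: int = 1000
    probes_per_chrom: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_hyper", "fraction_hypo", "concordance_rate",
                     "motif_plant_rate", "mix_weight_hi", "shared_effect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not 0.0 < self.delta_beta <= 1.0:
            raise ValueError("delta_beta must be in (0, 1]")
        if self.probes_per_region[0] < 1 or self.probes_per_region[0] > self.probes_per_region[1]:
            raise ValueError("invalid probes_per_region range")
        if "CONTROL" not in self.groups:
            raise ValueError("cohort requires a CONTROL group")
        bad = set(self.affected_groups) - (set(self.groups) - {"CONTROL"})
        if bad:
            raise ValueError(f"affected_groups not tumor groups of this cohort: {bad}")


def sample_names(config: CohortConfig) -> dict[str, list[str]]:
    return {g: [f"{g}_{i + 1}" for i in range(config.n_per_group)] for g in config.groups}


# ---------------------------------------------------------------------------
# manifest / block layout

_CAT_CYCLE = list(REGION_CATEGORIES)
_REL_CYCLE = list(ISLAND_RELATIONS)


def _build_blocks(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign consecutive probe blocks (2–8 probes) to regions per category.

    Every ~cycle a TSS1500 block reuses the preceding TSS200 gene so the
    merged per-gene TSS view has something to merge.
    """
    lo, hi = config.probes_per_region
    rows = []
    i = 0
    block_id = 0
    gene_id = 0
    prev_cat, prev_gene = None, ""
    while i < config.n_probes:
        size = int(rng.integers(lo, hi + 1))
        size = min(size, config.n_probes - i)
        cat = _CAT_CYCLE[block_id % len(_CAT_CYCLE)]
        rel = _REL_CYCLE[(block_id // 2) % len(_REL_CYCLE)]
        if cat == "Intergenic":
            gene = ""
        elif cat == "TSS1500" and prev_cat == "TSS200":
            gene = prev_gene  # same gene, two promoter windows
        else:
            gene_id += 1
            gene = f"GENE{gene_id:05d}"
        rows.append(dict(block=block_id, start_probe=i, size=size,
                         category=cat, relation=rel, gene=gene))
        prev_cat, prev_gene = cat, gene
        i += size
        block_id += 1
    return pd.DataFrame(rows)


def _manifest_from_blocks(config: CohortConfig, blocks: pd.DataFrame) -> ProbeAnnotationTable:
    recs = []
    for b in blocks.itertuples():
        for j in range(b.size):
            k = b.start_probe + j
            chrom = f"chr{k // config.probes_per_chrom + 1}"
            pos = (k % config.probes_per_chrom) * config.probe_spacing + config.probe_spacing
            recs.append(dict(
                probe_id=f"cg{k:08d}",
                chrom=chrom,
                pos=pos,
                strand="+",
                gene=b.gene,
                region_category=b.category,
                island_relation=b.relation,
            ))
    return ProbeAnnotationTable(pd.DataFrame(recs))


def generate_cohort(config: CohortConfig
                    ) -> tuple[ProbeAnnotationTable, BetaMatrix, SampleSheet, TruthSet]:
    """Simulate a manifest, β matrix, sample sheet and truth set.

    Baseline probe means are drawn from a two-component Beta mixture (low
    component centered near 0.1, high near 0.85); each block's component is
    tied to its CpG-island relation (islands mostly unmethylated, open sea
    mostly methylated) and means are truncated to [0.05, 0.95]. Effects are
    planted on whole region blocks: hyper spikes go to low-baseline blocks
    (shift +Δβ) — hence mostly islands/shores — and hypo spikes to
    high-baseline blocks (−Δβ), truncated to [0.02, 0.98] with a warning.
    Per-sample values are Beta-distributed around the probe-group mean.
    """
    rng = _rng(config.seed, _TAG_COHORT)
    blocks = _build_blocks(config, rng)
    manifest = _manifest_from_blocks(config, blocks)

    n = config.n_probes
    # baseline component per block, driven by island relation
    p_high = blocks["relation"].map(_P_HIGH).to_numpy(float)
    # mix_weight_hi rescales the overall methylated fraction around its mean
    p_high = np.clip(p_high * (config.mix_weight_hi / np.mean(list(_P_HIGH.values()))), 0, 1)
    block_hi = rng.random(len(blocks)) < p_high

    # choose spiked blocks among those whose baseline leaves room for the shift
    target_hyper = int(round(config.fraction_hyper * n))
    target_hypo = int(round(config.fraction_hypo * n))
    lo_pool = [int(i) for i in rng.permutation(np.flatnonzero(~block_hi))]
    hi_pool = [int(i) for i in rng.permutation(np.flatnonzero(block_hi))]
    hyper_blocks, hypo_blocks = [], []
    got = 0
    for bi in lo_pool:
        if got >= target_hyper:
            break
        hyper_blocks.append(bi)
        got += int(blocks.loc[bi, "size"])
    if got < target_hyper:
        warnings.warn("fewer low-baseline blocks than fraction_hyper demands", stacklevel=2)
    got = 0
    for bi in hi_pool:
        if got >= target_hypo:
            break
        hypo_blocks.append(bi)
        got += int(blocks.loc[bi, "size"])
    if got < target_hypo:
        warnings.warn("fewer high-baseline blocks than fraction_hypo demands", stacklevel=2)

    lo_a, lo_b = config.beta_shape_lo
    hi_a, hi_b = config.beta_shape_hi
    comp_hi = np.repeat(block_hi, blocks["size"].to_numpy())
    base = np.where(comp_hi, rng.beta(hi_a, hi_b, size=n), rng.beta(lo_a, lo_b, size=n))
    base = np.clip(base, _MEAN_LO, _MEAN_HI)

    # per-block effect direction and affected tumor groups
    spike = np.zeros(n)
    direction = np.array([""] * n, dtype=object)
    affected_of_block: dict[int, tuple[str, ...]] = {}
    for sign, blist in ((1.0, hyper_blocks), (-1.0, hypo_blocks)):
        for bi in blist:
            s, z = blocks.loc[bi, "start_probe"], blocks.loc[bi, "size"]
            spike[s:s + z] = sign * config.delta_beta
            direction[s:s + z] = "hyper" if sign > 0 else "hypo"
            if len(config.affected_groups) > 1 and rng.random() >= config.shared_effect_rate:
                pick = int(rng.integers(len(config.affected_groups)))
                affected_of_block[bi] = (config.affected_groups[pick],)
            else:
                affected_of_block[bi] = tuple(config.affected_groups)

    affected_of_probe: dict[int, tuple[str, ...]] = {}
    for bi, grp in affected_of_block.items():
        s, z = int(blocks.loc[bi, "start_probe"]), int(blocks.loc[bi, "size"])
        for k in range(s, s + z):
            affected_of_probe[k] = grp

    shifted = base + spike
    clipped = np.clip(shifted, BETA_FLOOR, BETA_CEIL)
    n_trunc = int((clipped != shifted).sum())
    if n_trunc:
        warnings.warn(
            f"{n_trunc} spiked probe mean(s) truncated to [{BETA_FLOOR}, {BETA_CEIL}]",
            stacklevel=2,
        )
    realized_delta = clipped - base

    names = sample_names(config)
    cols: dict[str, np.ndarray] = {}
    prec = config.precision
    for g in config.groups:
        in_g = np.array([g in affected_of_probe.get(k, ()) for k in range(n)])
        mean_g = np.where(in_g, clipped, base)
        a, b = mean_g * prec, (1.0 - mean_g) * prec
        for s in names[g]:
            cols[s] = rng.beta(a, b)
    beta = BetaMatrix(pd.DataFrame(cols, index=manifest.probe_ids.tolist()))

    sheet = SampleSheet(pd.DataFrame(
        [(s, g) for g in config.groups for s in names[g]],
        columns=["sample_id", "group"],
    ))

    truth = TruthSet()
    pids = manifest.probe_ids.to_numpy()
    for bi in list(hyper_blocks) + list(hypo_blocks):
        b = blocks.loc[bi]
        s, z = int(b["start_probe"]), int(b["size"])
        for k in range(s, s + z):
            truth.mvp_truth[pids[k]] = TruthEffect(
                direction=str(direction[k]),
                delta=float(realized_delta[k]),
                affected_groups=affected_of_block[bi],
            )
        if b["category"] in GENE_LINKED_CATEGORIES and b["gene"] != "":
            region_id = f"{b['gene']}|{b['category']}"
            truth.dmr_truth[region_id] = TruthEffect(
                direction=str(direction[s]),
                delta=float(np.mean(realized_delta[s:s + z])),
                affected_groups=affected_of_block[bi],
            )
    return manifest, beta, sheet, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression(truth: TruthSet, manifest: ProbeAnnotationTable,
                        config: CohortConfig) -> ExpressionTable:
    """Expression table with fold changes anti-correlated with promoter methylation.

    Genes whose promoter (TSS200/TSS1500) carries a planted effect are made
    concordant at rate ``concordance_rate``: hypermethylated promoters get a
    tumor/control ratio well below 1/1.5, hypomethylated ones well above 1.5.
    All other genes sit at ratio ~1 with lognormal noise. Chosen genes are
    recorded in ``truth.concordant_genes``.
    """
    rng = _rng(config.seed, _TAG_EXPRESSION)
    genes = sorted({g for g in manifest.records["gene"] if g != ""})
    promoter_cats = {"TSS200", "TSS1500"}
    rec = manifest.records
    promoter_gene_of_probe = {}
    for r in rec.itertuples():
        if r.region_category in promoter_cats and r.gene != "":
            promoter_gene_of_probe.setdefault(r.probe_id, set()).add(r.gene)

    # direction and affected groups per truth promoter gene
    gene_dir: dict[str, str] = {}
    gene_groups: dict[str, tuple[str, ...]] = {}
    for pid, eff in truth.mvp_truth.items():
        for g in promoter_gene_of_probe.get(pid, ()):
            gene_dir[g] = eff.direction
            gene_groups[g] = eff.affected_groups

    truth.concordant_genes = set()
    ratio = {}
    for g in sorted(gene_dir):
        if rng.random() < config.concordance_rate:
            fold = 1.5 * rng.uniform(1.5, 2.5)  # comfortably past the 1.5x rule
            ratio[g] = (1.0 / fold) if gene_dir[g] == "hyper" else fold
            truth.concordant_genes.add(g)

    names = sample_names(config)
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=len(genes))
    cols = {}
    for grp in config.groups:
        r = np.array([
            ratio.get(g, 1.0) if grp in gene_groups.get(g, ()) else 1.0
            for g in genes
        ])
        for s in names[grp]:
            noise = rng.lognormal(mean=0.0, sigma=0.1, size=len(genes))
            cols[s] = base * r * noise
    return ExpressionTable(pd.DataFrame(cols, index=genes))


# ---------------------------------------------------------------------------
# chromatin tracks


def generate_tracks(truth: TruthSet, manifest: ProbeAnnotationTable,
                    overlap_rate: float, background_rate: float = 0.0,
                    half_width: int = 100, name: str = "polycomb",
                    seed: int = 0) -> IntervalTrack:
    """Track covering ``overlap_rate`` of hyper truth probes and
    ``background_rate`` of the remaining probes (±half_width around each)."""
    rng = _rng(seed, _TAG_TRACKS)
    hyper = sorted(truth.hyper_probes())
    rest = sorted(set(manifest.probe_ids) - set(hyper))
    chosen: list[str] = []
    if hyper:
        k = int(round(overlap_rate * len(hyper)))
        chosen += list(rng.choice(hyper, size=k, replace=False))
    if rest and background_rate > 0:
        k = int(round(background_rate * len(rest)))
        chosen += list(rng.choice(rest, size=k, replace=False))
    probes = manifest.probes.loc[chosen]
    iv = pd.DataFrame({
        "chrom": probes["chrom"].to_numpy(),
        "start": np.maximum(probes["pos"].to_numpy(int) - half_width, 0),
        "end": probes["pos"].to_numpy(int) + half_width,
    })
    return IntervalTrack(name, iv).merged() if len(iv) else IntervalTrack(name, iv)


# ---------------------------------------------------------------------------
# sequences

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def random_windows(n: int, width: int, seed: int, prefix: str = "bg") -> dict[str, str]:
    """Uniform-random background windows (no planted motif)."""
    rng = _rng(seed, _TAG_SEQUENCES)
    return {f"{prefix}_{i:05d}": _random_seq(rng, width) for i in range(n)}


def generate_sequences(truth: TruthSet, width: int = 100, motif: str = "TGACTCA",
                       plant_rate: float = 0.3, seed: int = 0,
                       window_ids: list[str] | None = None
                       ) -> tuple[dict[str, str], list[str]]:
    """100-bp windows around hypomethylated truth probes with a planted motif.

    The motif (or its reverse complement) is inserted once at a random offset
    in ``plant_rate`` of the windows; planted ids are recorded in
    ``truth.motif_truth``. ``window_ids`` overrides the default (one window
    per hypo truth probe).
    """
    rng = _rng(seed, _TAG_SEQUENCES)
    ids = window_ids if window_ids is not None else sorted(truth.hypo_probes())
    seqs = {wid: _random_seq(rng, width) for wid in ids}
    k = int(round(plant_rate * len(ids)))
    planted = list(rng.choice(ids, size=k, replace=False)) if k else []
    for wid in planted:
        m = motif if rng.random() < 0.5 else _revcomp(motif)
        off = int(rng.integers(0, width - len(m) + 1))
        s = seqs[wid]
        seqs[wid] = s[:off] + m + s[off + len(m):]
    truth.motif_truth = set(planted)
    return seqs, planted


def generate_genome(manifest: ProbeAnnotationTable, truth: TruthSet,
                    motif: str = "TGACTCA", plant_rate: float = 0.3,
                    window: int = 100, seed: int = 0, margin: int = 200
                    ) -> dict[str, str]:
    """Random genome covering all probe positions, with the motif planted
    inside the ±window/2 neighbourhood of ``plant_rate`` of hypo truth probes."""
    rng = _rng(seed, _TAG_SEQUENCES)
    chroms = {}
    probes = manifest.probes
    for chrom, g in probes.groupby("chrom"):
        length = int(g["pos"].max()) + margin
        chroms[chrom] = np.array(list(_random_seq(rng, length)))
    hypo = sorted(truth.hypo_probes())
    k = int(round(plant_rate * len(hypo)))
    planted = list(rng.choice(hypo, size=k, replace=False)) if k else []
    half = window // 2
    for pid in planted:
        chrom, pos = probes.loc[pid, "chrom"], int(probes.loc[pid, "pos"])
        m = motif if rng.random() < 0.5 else _revcomp(motif)
        lo = max(pos - half, 0)
        hi = min(pos + half, len(chroms[chrom])) - len(m)
        off = int(rng.integers(lo, hi + 1))
        chroms[chrom][off:off + len(m)] = list(m)
    truth.motif_truth = set(planted)
    return {c: "".join(a) for c, a in chroms.items()}


# ---------------------------------------------------------------------------
# MethyLight Ct tables

REF_SAMPLE = "MSssI"
_REF_ALU_CT = 18.0
_REF_RATIO = 0.25  # (GeneX/Alu) quantity ratio of the fully methylated reference


def generate_ct_table(groups: dict[str, list[str]], pmr_targets: dict[str, dict[str, float]],
                      replicates: int = 3, ct_sd: float = 0.0, seed: int = 0,
                      alu_assay: str = "Alu") -> tuple[CtTable, pd.DataFrame]:
    """Ct tables back-computed from true PMR values at 100% efficiency.

    ``groups`` maps group → sample ids; ``pmr_targets`` maps gene →
    {group: true PMR}. Quantity = 2^(−Ct); Gaussian noise of sd ``ct_sd`` is
    added per replicate. True PMR 0 yields 'no amplification' rows (NaN Ct).
    Returns the CtTable and the sample→group table.
    """
    rng = _rng(seed, _TAG_CT)
    rows = []

    def add(sample, assay, true_ct, n):
        for _ in range(n):
            ct = np.nan if true_ct is None else true_ct + (rng.normal(0, ct_sd) if ct_sd else 0.0)
            rows.append((sample, assay, ct))

    genes = sorted(pmr_targets)
    # fully methylated reference
    add(REF_SAMPLE, alu_assay, _REF_ALU_CT, replicates)
    ref_gene_ct = _REF_ALU_CT - np.log2(_REF_RATIO)
    for gene in genes:
        add(REF_SAMPLE, gene, ref_gene_ct, replicates)
    sample_rows = []
    for group, samples in groups.items():
        for s in samples:
            alu_ct = _REF_ALU_CT + rng.uniform(0.0, 2.0)  # per-sample input amount
            add(s, alu_assay, alu_ct, replicates)
            alu_qty = 2.0 ** (-alu_ct)
            for gene in genes:
                pmr = pmr_targets[gene][group]
                if pmr <= 0:
                    add(s, gene, None, replicates)
                else:
                    qty = (pmr / 100.0) * _REF_RATIO * alu_qty
                    add(s, gene, -np.log2(qty), replicates)
            sample_rows.append((s, group))
    table = CtTable(pd.DataFrame(rows, columns=["sample_id", "assay", "ct"]))
    return table, pd.DataFrame(sample_rows, columns=["sample_id", "group"])


# ---------------------------------------------------------------------------
# reference developmental stages (for cell-of-origin assignment)


def generate_stage_reference(stages: tuple[str, ...], n_probes: int = 500,
                             n_per_stage: int = 3, signature_fraction: float = 0.2,
                             delta: float = 0.4, precision: float = 100.0,
                             seed: int = 0) -> tuple[BetaMatrix, SampleSheet, pd.DataFrame]:
    """Reference methylomes for developmental stages with stage-specific signatures.

    Each stage flips its own disjoint probe signature by ±delta from a shared
    baseline. Returns (reference β, sample sheet with REFERENCE_STAGE groups,
    stage mean profiles probes × stages).
    """
    rng = _rng(seed, _TAG_STAGES)
    base = np.clip(rng.beta(2.0, 2.0, size=n_probes), _MEAN_LO, _MEAN_HI)
    sig_size = int(signature_fraction * n_probes / len(stages))
    if sig_size < 1:
        raise ValueError("signature_fraction too small for n_probes/stages")
    probe_ids = [f"cg{k:08d}" for k in range(n_probes)]
    means = {}
    for i, st in enumerate(stages):
        m = base.copy()
        sl = slice(i * sig_size, (i + 1) * sig_size)
        m[sl] = np.clip(m[sl] + np.where(m[sl] < 0.5, delta, -delta), BETA_FLOOR, BETA_CEIL)
        means[st] = m
    cols, rows = {}, []
    prec = precision
    for st in stages:
        for j in range(n_per_stage):
            sid = f"{st}_{j + 1}"
            cols[sid] = rng.beta(means[st] * prec, (1 - means[st]) * prec)
            rows.append((sid, f"REFERENCE_STAGE:{st}"))
    beta = BetaMatrix(pd.DataFrame(cols, index=probe_ids))
    sheet = SampleSheet(pd.DataFrame(rows, columns=["sample_id", "group"]))
    return beta, sheet, pd.DataFrame(means, index=probe_ids)


def sample_from_stage(stage_means: pd.DataFrame, stage: str, n: int,
                      precision: float = 100.0, seed: int = 0,
                      prefix: str = "tumor") -> BetaMatrix:
    """Draw n samples from a stage's mean profile (Beta noise)."""
    rng = _rng(seed, _TAG_STAGES + 1)
    m = stage_means[stage].to_numpy()
    cols = {f"{prefix}_{i + 1}": rng.beta(m * precision, (1 - m) * precision)
            for i in range(n)}
    return BetaMatrix(pd.DataFrame(cols, index=stage_means.index))
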