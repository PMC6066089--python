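# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical conventions, and the design choices behind `alclmeth`, in the order
the pipeline runs them.

## Data model and coordinates

All methylation data are probe-level β values (fraction methylated signal,
β ∈ [0,1]) on a 450K-style array abstraction: a probe manifest (probe id,
chromosome, position, strand, gene, region category, CpG-island relation), a
probes × samples β matrix, and a sample sheet mapping samples to groups
(`ALK_POS`, `ALK_NEG`, `CONTROL`, or `REFERENCE_STAGE:<name>`).

Coordinates are 0-based half-open everywhere in memory; a probe at position
p overlaps an interval (s, e) iff s ≤ p < e. BED files are read natively;
the manifest TSV stores 1-based positions (the convention of array manifests)
and is converted on read and write. Probes may carry several gene/category
memberships (";"-joined on disk); probe-level statistics are computed once
per probe, region membership is many-to-many.

Input β values are assumed already normalized; the package performs no
array normalization or probe QC of its own. Missing β values are rejected by
default (`on_missing="drop"` masks whole probes instead).

## Probe-level testing (MVPs)

β is variance-stabilized with the logit2 transform
M = log2((β + ε)/(1 − β + ε)), ε = 1e-6 by default (the transform is
undefined at β ∈ {0,1}; ε only matters within ~ε of the boundaries).

Two per-probe tests are provided:

- **Moderated t (default).** Pooled per-probe variances are shrunk toward an
  empirical-Bayes scaled-inverse-chi-square prior fitted across all probes by
  method of moments on log variances; the statistic gains the prior degrees
  of freedom d0 (t on d0 + n_a + n_b − 2 df). This is the field-standard
  remedy for small-n array designs: at n = 5 per group a plain t statistic
  cannot produce two-sided p-values much below ~1e-4 regardless of effect
  size (the df-limited tail), which makes genome-wide adjusted-p thresholds
  unreachable for genuine effects. With moderation, planted Δβ = 0.3 effects
  at n = 5 vs 5 are recovered essentially completely, and null cohorts remain
  calibrated (raw p uniform by KS; ≈0 BH-significant calls at q < 0.05 over
  10,000 probes).
- **Welch t (`method="welch"`).** The unequal-variance t on M values, kept
  for hand-checkable arithmetic and for large-n designs where moderation is
  unnecessary.

Zero-variance probes: if both groups are constant and equal the probe is an
exact tie (p = 1, t = 0); if constant but different, the squared standard
error is floored at 1e-12 and the record flagged `var_floored`.

Multiple testing is Benjamini–Hochberg across all probes of one comparison.
Effect size Δβ is always the difference of group means on the β scale, even
though testing is on M — thresholds on both scales follow common reporting
practice. MVP significance uses strict inequalities: adjusted p < 0.01 AND
|Δβ| > 0.2 (defaults). Direction is `hyper` iff Δβ > 0 with respect to the
first group.

## Region-level testing (DMRs)

Region β per sample is the arithmetic mean of member-probe β values,
computed as `first + mean(x − first)` so a region of identical probe rows
reproduces the probe value exactly. Region identities:

- gene-linked categories: `gene|category` for TSS1500, TSS200, 5′UTR,
  first exon, body, 3′UTR;
- a merged promoter view `gene|TSS` (union of the gene's TSS200 and TSS1500
  probes), since promoter-level summaries conventionally pool both windows;
- island features: maximal runs of consecutive probes (in chromosome order)
  sharing the same island relation, `chrom:start-end|relation`. The manifest
  carries no island identifier, so runs are derived from probe order; a
  relation change or chromosome change breaks the run.

Testing mirrors the probe level (same transform, Welch by default at the
region level since aggregation already pools probes — regions are far fewer,
so the BH cutoff is not df-limited). BH families are per category: regions of
one category form one family, keeping per-category counts self-contained;
the merged TSS view is its own family. Significance: adjusted p < 0.05
(strict) AND |Δβ| ≥ 0.15 (inclusive — the effect threshold is conventionally
quoted as "at least").

## Clustering, PCA, stage assignment

Two normalization conventions coexist deliberately: heatmap-style
hierarchical clustering runs on raw β (percent-methylation scale), while PCA
and reference-stage comparisons first z-score each sample column to mean 0,
population variance 1, removing per-array intensity offsets.

- Hierarchical clustering: 1 − Pearson correlation between sample columns,
  average linkage (both configurable); deterministic given input order;
  exported as Newick.
- Probe selection: rank by ascending p, ties by larger |Δβ| then probe id;
  either the top ceil(fraction × total) probes or all with p below a cutoff.
- PCA: SVD of centered samples × probes; sign fixed by making each
  component's largest-magnitude loading positive, so coordinates are
  reproducible up to sample order.
- Stage assignment: each tumor sample is assigned to the reference stage
  whose centroid (mean normalized profile) is nearest in Euclidean distance;
  ties resolve to the first stage in input order and are flagged. This makes
  "the tumor methylome resembles stage X" an assertable operation rather
  than a visual reading of a dendrogram.

## Methylation × expression concordance

Significant promoter (merged TSS) DMRs are joined to a linear-scale
expression table by gene symbol; if a gene has several promoter DMRs the
smallest-p one is kept. The expression fold change is the ratio of group
means; up means ratio > 1.5 and down means ratio < 1/1.5, both strict
("more than 1.5-fold"). Denominators are the hyper- and hypomethylated TSS
DMRs whose gene appears in the expression table; unmapped genes are dropped
from numerator and denominator with a logged count. Percentages are
100 × count/denominator rounded half-up to integers and always recompute
from the reported counts. Joins are at gene-symbol level; isoform-specific
promoters are out of scope.

## Chromatin enrichment and epigenetic switching

Overlap enrichment compares the fraction of a probe set inside a track with
the fraction of the background (all manifest probes by default — the set is
part of its own background, matching comparisons against the full array
annotation) via a two-sided Fisher exact test on the 2×2 table. The odds
ratio of degenerate tables is capped at 1e6 and flagged. Enrichment is
invariant to interval fragmentation because intervals are merged before the
half-open point test.

Epigenetic switching — Polycomb (H3K27me3) repression in stem cells replaced
by DNA hypermethylation in tumors — is detected as tumor-hypermethylated
probes lying inside a reference Polycomb occupancy track, with a per-gene
rollup. Histone-mark changes at switched loci are quantified separately from
ChIP-qPCR quantities as fold = (signal/normalizer at target) /
(signal/normalizer at control region), which equals 2^(ΔΔCt) at 100%
amplification efficiency.

## Motif enrichment

Windows of 100 bp are extracted around significant hypomethylated probes
([pos − 50, pos + 50), clipped at chromosome ends; N never matches). K-mers
(k = 8 by default, matching an AP1-sized site) are counted canonically — a
k-mer and its reverse complement collapse to one key — in foreground and
background windows. Each foreground-observed k-mer gets a one-sided binomial
p-value for its foreground count against the background rate (pseudocount
0.5 on background counts), and an e-value = p × 4^k/2 (Bonferroni over
canonical k-mers). Ranking is by e-value, ties by foreground count then
lexicographic k-mer. Hits are scored against the AP1 bZIP consensus TGASTCA
(S = C or G) by the best ungapped alignment over both strands and all
offsets, as matched positions / 7.

This canonical-k-mer binomial scan is a deliberate, deterministic stand-in
for EM-based motif discovery (PWM optimization is a non-goal): it is exactly
testable against closed-form oracles and captures the claim of interest —
an AP1-like word enriched near hypomethylated CpGs. Its e-value is a
corrected binomial p and is **not numerically comparable** to E-values of
EM-based motif finders. The default background is a dinucleotide-preserving
shuffle of the foreground (Altschul–Erickson Eulerian-path construction,
seeded); windows around non-significant probes can be supplied instead.

## MethyLight PMR

Relative template quantity from a Ct value is (1 + E)^(−Ct) with efficiency
E = 1 by default (quantity = 2^−Ct); a "no amplification" reading is
quantity 0. Replicates are averaged on the quantity scale (not the Ct
scale — the defining formula uses mean measured quantities), then
PMR = 100 × [(GeneX mean)/(Alu mean)]_sample / [(GeneX mean)/(Alu mean)]_M.SssI,
where the denominator comes from fully methylated M.SssI-treated control
DNA. PMR is scale-invariant in per-sample input amount, may exceed 100
(flagged, never clipped), and is 0 iff the gene reaction yields no product.
Group comparison is one-way ANOVA followed by pairwise Welch t-tests against
the control group only when ANOVA p < 0.05; all-constant input is degenerate
and reported as p = 1 with a zero-variance flag.

## Synthetic-data generator

The generator emulates the statistical structure of the target study design;
its defaults are the study conditions the tests run under.

- **Cohort**: three groups (`ALK_POS`, `ALK_NEG`, `CONTROL`) of
  n_per_group = 5 samples; 10,000 probes by default, laid out in consecutive
  blocks of 2–8 probes, each block a region (gene × category, cycling through
  the seven categories; roughly every other TSS1500 block shares its gene
  with the preceding TSS200 block so the merged TSS view is exercised).
- **Baselines**: block-level two-component Beta mixture — low component
  Beta(1, 9) (mean ≈ 0.1, unmethylated) and high component Beta(8.5, 1.5)
  (mean ≈ 0.85, methylated) — with the component probability tied to the
  island relation (P(methylated) = 0.1 islands, 0.3 shores, 0.6 shelves,
  0.8 open sea), reflecting that CpG islands are normally unmethylated.
  Baseline means are truncated to [0.05, 0.95]: normalized array data rarely
  sit at exactly 0/1, and the truncation keeps M-value tails well behaved.
- **Effects**: planted on whole blocks — hypermethylation (+Δβ, default 0.3)
  on low-baseline blocks, hypomethylation (−Δβ) on high-baseline blocks, so
  the planted effect is fully expressible within [0.02, 0.98] (anything
  outside is truncated with a warning). This also reproduces the real-data
  asymmetry that hypomethylated CpG islands are rare. A configurable
  fraction of spiked blocks (`shared_effect_rate`, default 0.7) affects both
  tumor groups; the rest affect one tumor group at random, giving the three
  groups distinguishable signatures. Ground truth (per-probe and per-region
  direction, realized Δ, affected groups) is recorded in a `TruthSet`.
- **Noise**: per-sample β ~ Beta(mβ·φ, (1−mβ)·φ) around the probe-group mean
  with precision φ = 100 (sd ≈ 0.05 at β = 0.5, smaller near the
  boundaries) — chosen as a realistic combination of technical and
  small-cohort biological variability for tumor tissue.
- **Expression**: lognormal baselines; genes with a spiked promoter become
  concordant at rate `concordance_rate` (default 0.13, the ballpark of
  reported methylation–expression coupling): hypermethylated promoters get a
  tumor/control ratio well below 1/1.5, hypomethylated well above 1.5, only
  in that gene's affected groups; everything else fluctuates around ratio 1
  (lognormal σ = 0.1).
- **Tracks**: intervals (±100 bp) around a chosen fraction of
  hypermethylated truth probes (default 0.55) plus a background fraction of
  all other probes (default 0.33), then merged — emulating Polycomb occupancy
  enriched at tumor-hypermethylated sites.
- **Sequences**: uniform-random windows (or whole chromosomes covering the
  manifest) with the AP1 heptamer TGACTCA planted once, random offset and
  strand, in `motif_plant_rate` of hypomethylated windows (default 0.3).
- **Ct tables**: back-computed from chosen true PMR values at 100%
  efficiency, with per-sample input-amount offsets and optional Gaussian Ct
  noise; true PMR 0 yields "no amplification" rows.
- **Reference stages**: a shared Beta(2, 2) baseline with disjoint
  stage-specific signatures (default 20% of probes split across stages,
  ±0.4 shifts), plus a sampler that draws tumor profiles from a stage mean.

Determinism: every generator derives its random stream from the config seed
through fixed per-generator child seeds, so adding one generator to a run
never reshuffles another, and equal seeds give byte-identical outputs.

What the generator does **not** emulate — and hence what passing tests do not
show about real data: array chemistry and probe-type (Infinium I/II) bias,
batch effects, cell-composition mixtures, spatial correlation beyond the
block structure, probe cross-hybridization, realistic gene-length/GC
structure in sequences, and qPCR efficiency drift. Recovery rates measured
here are upper bounds for data with those artifacts.

## Pipeline and reproducibility

`run_pipeline` executes the stages in dependency order from one flat
key = value config (CLI flags override), writes plain-TSV/BED/FASTA/JSON
artifacts plus a machine-readable report, logs thresholds, seed and row
counts, and is byte-identical under a fixed seed. Reported percentages
always recompute from the report's own counts. The acceptance script
(`scripts/acceptance.py`) re-runs the full chain at the study's sample sizes
(10,000-probe cohorts, 100-replicate assignment experiments, 20-replicate
motif recovery) — sizes chosen to make each quantity statistically stable
while keeping a full run in the minutes range on one CPU.

## Known limitations

- Array normalization/QC is out of scope; β is trusted as given.
- The moderated test assumes a common variance prior across probes; probes
  with genuinely heavy-tailed variance may be over-shrunk.
- Island regions derive from probe-run adjacency, not true island
  coordinates; sparse manifests can split one island into several runs.
- Gene-symbol joins ignore isoform-specific promoters.
- The motif scanner finds enriched exact words (canonical k-mers), not
  degenerate PWMs; a motif with high internal variability would be split
  across several k-mers and lose rank.
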