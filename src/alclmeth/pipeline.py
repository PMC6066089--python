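"""End-to-end orchestration: simulate → MVP → DMR → cluster/PCA → integrate →
enrich/switch → motif → PMR → report.

Every stage writes plain-text artifacts into the output directory and
contributes counts to a machine-readable JSON report. All randomness derives
from the single run seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import core_io, synthetic_data as synth
from . import cluster_embed, dmr_calling, enrichment_switching, expression_integration
from . import motif_enrichment, mvp_calling, pmr_quant

log = logging.getLogger("alclmeth")

ALL_STAGES = ("mvp", "dmr", "cluster", "integrate", "enrich", "motif", "pmr")


@dataclass
class RunConfig:
    """Thresholds, sizes and toggles for one pipeline run."""

    outdir: str = "alclmeth_run"
    seed: int = 7
    n_probes: int = 4000
    n_per_group: int = 5
    fraction_hyper: float = 0.02
    fraction_hypo: float = 0.02
    delta_beta: float = 0.3
    mvp_padj: float = 0.01
    mvp_min_delta: float = 0.2
    dmr_padj: float = 0.05
    dmr_min_delta: float = 0.15
    fold: float = 1.5
    k: int = 8
    window: int = 100
    top_fraction: float = 0.01
    concordance_rate: float = 0.13
    motif_plant_rate: float = 0.3
    track_overlap_rate: float = 0.55
    track_background_rate: float = 0.33
    stages: tuple[str, ...] = ALL_STAGES

    def __post_init__(self) -> None:
        for thr in ("mvp_padj", "mvp_min_delta", "dmr_padj", "dmr_min_delta",
                    "top_fraction"):
            v = getattr(self, thr)
            if not 0 < v < 1:
                raise ValueError(f"{thr} must be in (0, 1)")
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")


def load_config(path) -> RunConfig:
    """Flat key=value config file; '#' starts a comment; stages comma-separated."""
    kwargs: dict = {}
    types = {f.name: f.type for f in fields(RunConfig)}
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in types:
                raise ValueError(f"unknown config key: {key}")
            if key == "stages":
                kwargs[key] = tuple(s for s in val.split(",") if s)
            elif key == "outdir":
                kwargs[key] = val
            elif key in ("seed", "n_probes", "n_per_group", "k", "window"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
    return RunConfig(**kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), 6)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {}
    try:
        if not config.stages:
            (out / "report.json").write_text("{}\n")
            return report
        log.info("seed=%d n_probes=%d stages=%s", config.seed, config.n_probes,
                 ",".join(config.stages))
        cc = synth.CohortConfig(
            n_probes=config.n_probes,
            n_per_group=config.n_per_group,
            fraction_hyper=config.fraction_hyper,
            fraction_hypo=config.fraction_hypo,
            delta_beta=config.delta_beta,
            concordance_rate=config.concordance_rate,
            motif_plant_rate=config.motif_plant_rate,
            seed=config.seed,
        )
        manifest, beta, sheet, truth = synth.generate_cohort(cc)
        core_io.write_manifest(manifest, out / "manifest.tsv")
        core_io.write_beta_matrix(beta, out / "beta.tsv")
        core_io.write_sample_sheet(sheet, out / "samples.tsv")
        report["cohort"] = {
            "n_probes": len(manifest),
            "n_samples": len(sheet.df),
            "n_truth_mvp": len(truth.mvp_truth),
            "n_truth_dmr": len(truth.dmr_truth),
            "seed": config.seed,
        }

        comparisons = [("ALK_POS", "CONTROL"), ("ALK_NEG", "CONTROL"), ("ALK_POS", "ALK_NEG")]
        mvp_sets = {}
        if "mvp" in config.stages:
            venn_input = {}
            report["mvp"] = {}
            for a, b in comparisons:
                tab = mvp_calling.call_mvps(beta, sheet, a, b)
                tab.to_csv(out / f"mvp_{a}_vs_{b}.tsv", sep="\t", float_format="%.6g")
                s = mvp_calling.filter_mvps(tab, config.mvp_padj, config.mvp_min_delta)
                mvp_sets[(a, b)] = s
                venn_input[(a, b)] = s.probe_ids
                by_cat, by_rel = mvp_calling.genomic_distribution(s, manifest)
                report["mvp"][f"{a}_vs_{b}"] = {
                    "n_mvp": len(s),
                    "n_hyper": len(s.hyper),
                    "n_hypo": len(s.hypo),
                    "by_region_category": by_cat.to_dict(),
                    "by_island_relation": by_rel.to_dict(),
                }
                log.info("mvp %s vs %s: %d significant", a, b, len(s))
            report["mvp"]["venn"] = mvp_calling.venn_counts(
                *[venn_input[c] for c in comparisons])

        dmr_tables = {}
        regions = None
        if "dmr" in config.stages:
            regions = dmr_calling.aggregate_regions(beta, manifest)
            report["dmr"] = {"n_regions": len(regions)}
            for a, b in comparisons[:2]:
                tab = dmr_calling.call_dmrs(regions, sheet, a, b,
                                            config.dmr_padj, config.dmr_min_delta)
                tab.to_csv(out / f"dmr_{a}_vs_{b}.tsv", sep="\t", float_format="%.6g")
                dmr_tables[(a, b)] = tab
                counts = dmr_calling.count_by_category(tab)
                report["dmr"][f"{a}_vs_{b}"] = {
                    "n_significant": int(tab["significant"].sum()),
                    "by_category": counts.to_dict(),
                }
                log.info("dmr %s vs %s: %d significant", a, b,
                         int(tab["significant"].sum()))

        if "cluster" in config.stages and mvp_sets:
            s = mvp_sets[("ALK_POS", "CONTROL")]
            probes = sorted(s.probe_ids) or list(beta.probe_ids[:50])
            dend = cluster_embed.hier_cluster(beta.df.loc[probes])
            (out / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
            z = cluster_embed.zscore_samples(beta.df.loc[probes])
            emb = cluster_embed.pca(z, n_components=3)
            labels = dend.labels(3)
            report["cluster"] = {
                "n_probes_clustered": len(probes),
                "leaf_order": dend.leaf_order,
                "labels_k3": labels,
                "pc_variance_ratio": list(emb.explained_variance_ratio),
            }

        if "integrate" in config.stages and dmr_tables:
            expr = synth.generate_expression(truth, manifest, cc)
            core_io.write_expression(expr, out / "expression.tsv")
            report["concordance"] = {}
            for (a, b), tab in dmr_tables.items():
                summary, per_gene = expression_integration.classify_concordance(
                    tab, expr, sheet, a, b, fold=config.fold)
                per_gene.to_csv(out / f"concordance_{a}_vs_{b}.tsv", sep="\t",
                                float_format="%.6g")
                report["concordance"][f"{a}_vs_{b}"] = summary.as_dict()

        if "enrich" in config.stages and mvp_sets:
            track = synth.generate_tracks(
                truth, manifest, config.track_overlap_rate,
                config.track_background_rate, seed=config.seed)
            core_io.write_track(track, out / "polycomb.bed")
            s = mvp_sets[("ALK_POS", "CONTROL")]
            report["enrichment"] = {}
            if s.hyper:
                row = enrichment_switching.overlap_enrichment(s.hyper, track, manifest)
                report["enrichment"]["hyper_polycomb"] = row.as_dict()
                switched, rollup = enrichment_switching.detect_switching(
                    s.hyper, manifest, track)
                rollup.to_csv(out / "switching_genes.tsv", sep="\t")
                report["enrichment"]["switching"] = {
                    "n_switched": len(switched),
                    "fraction_of_hyper": len(switched) / len(s.hyper),
                }

        if "motif" in config.stages and mvp_sets:
            genome = synth.generate_genome(
                manifest, truth, plant_rate=config.motif_plant_rate,
                window=config.window, seed=config.seed)
            s = mvp_sets[("ALK_POS", "CONTROL")]
            hypo = sorted(s.hypo)
            if hypo:
                fg = motif_enrichment.extract_windows(hypo, manifest, genome,
                                                      config.window)
                core_io.write_fasta(fg, out / "hypo_windows.fa")
                bg = motif_enrichment.shuffled_background(fg, seed=config.seed)
                hits = motif_enrichment.kmer_enrichment(fg, bg, k=config.k)
                hits.head(50).to_csv(out / "motifs.tsv", sep="\t", index=False,
                                     float_format="%.6g")
                top = hits.iloc[0]
                report["motif"] = {
                    "n_windows": len(fg),
                    "top_kmer": top["kmer"],
                    "top_e_value": float(top["e_value"]),
                    "top_ap1_similarity": float(top["ap1_similarity"]),
                }

        if "pmr" in config.stages:
            groups = {g: [f"{g}_{i+1}" for i in range(config.n_per_group)]
                      for g in ("ALK_POS", "ALK_NEG", "CONTROL")}
            targets = {"TCF7": {"ALK_POS": 60.0, "ALK_NEG": 55.0, "CONTROL": 5.0}}
            ct, group_df = synth.generate_ct_table(groups, targets, replicates=3,
                                                   ct_sd=0.1, seed=config.seed)
            core_io.write_ct_table(ct, out / "ct.tsv")
            pmr = pmr_quant.pmr_table(ct)
            pmr.to_csv(out / "pmr.tsv", sep="\t", index=False, float_format="%.6g")
            cmp_res = pmr_quant.compare_groups(pmr, group_df, "CONTROL")
            report["pmr"] = {
                "anova_f": cmp_res.anova_f,
                "anova_p": cmp_res.anova_p,
                "group_means": cmp_res.group_stats["mean"].to_dict(),
            }

        payload = json.dumps(_jsonable(report), indent=1, sort_keys=True)
        (out / "report.json").write_text(payload + "\n")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
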