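import pandas as pd
import pytest

from alclmeth import synthetic_data as synth
from alclmeth.core_io import ProbeAnnotationTable


@pytest.fixture(scope="session")
def small_cohort():
    """A compact tumor/control cohort with planted effects shared by both
    tumor groups (fast enough for per-module tests)."""
    cfg = synth.CohortConfig(
        n_probes=600,
        probes_per_region=(4, 4),
        fraction_hyper=0.05,
        fraction_hypo=0.05,
        shared_effect_rate=1.0,
        seed=13,
    )
    return cfg, synth.generate_cohort(cfg)


def make_manifest(rows):
    """Build a ProbeAnnotationTable from (pid, chrom, pos0, gene, cat, rel) tuples."""
    recs = pd.DataFrame(
        [dict(probe_id=p, chrom=c, pos=pos, strand="+", gene=g,
              region_category=cat, island_relation=rel)
         for p, c, pos, g, cat, rel in rows]
    )
    return ProbeAnnotationTable(recs)


@pytest.fixture
def tiny_manifest_file(tmp_path):
    path = tmp_path / "manifest.tsv"
    path.write_text(
        "probe_id\tchrom\tpos\tstrand\tgene\tregion_category\tisland_relation\n"
        "cg01\tchr1\t100\t+\tTCF7\tTSS200\tIsland\n"
        "cg02\tchr1\t500\t-\tTCF7\tBody\tShore\n"
        "cg03\tchr2\t50\t+\t\tIntergenic\tOpenSea\n"
    )
    return path
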