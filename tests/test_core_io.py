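import numpy as np
import pandas as pd
import pytest

from alclmeth import core_io, synthetic_data as synth
from alclmeth.core_io import (
    BetaMatrix,
    FormatError,
    IntervalTrack,
    ValidationError,
)


class TestManifest:
    def test_three_row_fixture_parses(self, tiny_manifest_file):
        tab = core_io.read_manifest(tiny_manifest_file)
        assert len(tab) == 3
        assert list(tab.probe_ids) == ["cg01", "cg02", "cg03"]
        # on-disk pos is 1-based, internal is 0-based
        assert tab.probes.loc["cg01", "pos"] == 99
        assert tab.probes.loc["cg02", "strand"] == "-"
        assert tab.records.loc[2, "gene"] == ""

    def test_duplicate_probe_id_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "probe_id\tchrom\tpos\tstrand\tgene\tregion_category\tisland_relation\n"
            "cg01\tchr1\t100\t+\tA\tBody\tIsland\n"
            "cg01\tchr1\t200\t+\tB\tBody\tIsland\n"
        )
        with pytest.raises(ValidationError, match="duplicate probe_id"):
            core_io.read_manifest(p)

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("probe_id\tchrom\tpos\tstrand\tgene\tregion_category\n"
                     "cg01\tchr1\t100\t+\tA\tBody\n")
        with pytest.raises(FormatError, match="island_relation"):
            core_io.read_manifest(p)

    def test_unknown_category_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "probe_id\tchrom\tpos\tstrand\tgene\tregion_category\tisland_relation\n"
            "cg01\tchr1\t100\t+\tA\tPromoter\tIsland\n"
        )
        with pytest.raises(ValidationError, match="region_category"):
            core_io.read_manifest(p)

    def test_intergenic_with_gene_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "probe_id\tchrom\tpos\tstrand\tgene\tregion_category\tisland_relation\n"
            "cg01\tchr1\t100\t+\tA\tIntergenic\tIsland\n"
        )
        with pytest.raises(ValidationError, match="Intergenic"):
            core_io.read_manifest(p)

    def test_multi_membership_expansion(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "probe_id\tchrom\tpos\tstrand\tgene\tregion_category\tisland_relation\n"
            "cg01\tchr1\t100\t+\tA;B\tTSS200;Body\tShore\n"
        )
        tab = core_io.read_manifest(p)
        assert len(tab) == 1  # one probe
        assert len(tab.records) == 2  # two memberships
        pairs = set(zip(tab.records["gene"], tab.records["region_category"]))
        assert pairs == {("A", "TSS200"), ("B", "Body")}

    def test_mismatched_multi_lists_rejected(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "probe_id\tchrom\tpos\tstrand\tgene\tregion_category\tisland_relation\n"
            "cg01\tchr1\t100\t+\tA;B;C\tTSS200;Body\tShore\n"
        )
        with pytest.raises(FormatError, match="different lengths"):
            core_io.read_manifest(p)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_synthetic_manifest(self, tmp_path, seed):
        cfg = synth.CohortConfig(n_probes=100, seed=seed)
        manifest, *_ = synth.generate_cohort(cfg)
        p = tmp_path / "m.tsv"
        core_io.write_manifest(manifest, p)
        back = core_io.read_manifest(p)
        pd.testing.assert_frame_equal(back.records, manifest.records)


class TestBetaMatrix:
    def test_toy_values(self, tmp_path, tiny_manifest_file):
        manifest = core_io.read_manifest(tiny_manifest_file)
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ts2\ncg01\t0.1\t0.9\ncg02\t0.5\t0.25\n")
        beta = core_io.read_beta_matrix(p, manifest)
        assert beta.df.loc["cg01", "s2"] == 0.9
        assert beta.df.shape == (2, 2)

    def test_out_of_range_rejected(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ncg01\t1.2\n")
        with pytest.raises(ValidationError, match=r"\[0, 1\]"):
            core_io.read_beta_matrix(p)

    def test_missing_value_policy(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ts2\ncg01\t0.2\t\ncg02\t0.5\t0.6\n")
        with pytest.raises(ValidationError, match="missing"):
            core_io.read_beta_matrix(p)
        beta = core_io.read_beta_matrix(p, on_missing="drop")
        assert list(beta.probe_ids) == ["cg02"]

    def test_probe_absent_from_manifest_rejected(self, tmp_path, tiny_manifest_file):
        manifest = core_io.read_manifest(tiny_manifest_file)
        p = tmp_path / "b.tsv"
        p.write_text("probe_id\ts1\ncg99\t0.5\n")
        with pytest.raises(ValidationError, match="absent from manifest"):
            core_io.read_beta_matrix(p, manifest)

    def test_round_trip_bitwise_text(self, tmp_path):
        cfg = synth.CohortConfig(n_probes=1000, seed=4)
        _, beta, _, _ = synth.generate_cohort(cfg)
        p1, p2 = tmp_path / "b1.tsv", tmp_path / "b2.tsv"
        core_io.write_beta_matrix(beta, p1)
        core_io.write_beta_matrix(core_io.read_beta_matrix(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestSampleSheet:
    def test_round_trip_and_lookup(self, tmp_path):
        cfg = synth.CohortConfig(n_probes=50, seed=0)
        _, beta, sheet, _ = synth.generate_cohort(cfg)
        p = tmp_path / "s.tsv"
        core_io.write_sample_sheet(sheet, p)
        back = core_io.read_sample_sheet(p)
        pd.testing.assert_frame_equal(back.df, sheet.df)
        assert back.group_of("ALK_POS_1") == "ALK_POS"
        assert len(back.samples("CONTROL")) == cfg.n_per_group
        back.validate_against(beta)

    def test_unknown_group_rejected(self):
        df = pd.DataFrame({"sample_id": ["s1"], "group": ["TUMOUR"]})
        with pytest.raises(ValidationError, match="group"):
            core_io.SampleSheet(df)

    def test_reference_stage_groups_accepted(self):
        df = pd.DataFrame({"sample_id": ["s1"], "group": ["REFERENCE_STAGE:ETP"]})
        assert core_io.SampleSheet(df).group_of("s1") == "REFERENCE_STAGE:ETP"


class TestIntervalTrack:
    def test_basic_bed_parse(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\n")
        track = core_io.read_track(p, "t")
        assert len(track) == 1
        assert tuple(track.intervals.iloc[0]) == ("chr1", 100, 200)

    def test_start_ge_end_rejected(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t200\t200\n")
        with pytest.raises(FormatError, match="start >= end"):
            core_io.read_track(p)

    def test_overlaps_preserved_raw_merged_on_demand(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t200\nchr1\t150\t300\n")
        track = core_io.read_track(p)
        assert len(track) == 2
        merged = track.merged()
        assert len(merged) == 1
        assert tuple(merged.intervals.iloc[0]) == ("chr1", 100, 300)

    def test_half_open_point_overlap(self):
        track = IntervalTrack("t", pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [200]}))
        hits = track.contains(np.array(["chr1"] * 4 + ["chr2"]),
                              np.array([99, 100, 199, 200, 150]))
        assert list(hits) == [False, True, True, False, False]

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_synthetic_track(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        starts = np.sort(rng.integers(0, 10_000, size=50))
        df = pd.DataFrame({"chrom": "chr1", "start": starts,
                           "end": starts + rng.integers(1, 500, size=50)})
        track = IntervalTrack("t", df)
        p = tmp_path / "t.bed"
        core_io.write_track(track, p)
        back = core_io.read_track(p, "t")
        pd.testing.assert_frame_equal(back.intervals, track.intervals)


class TestFastaAndCt:
    def test_fasta_round_trip(self, tmp_path):
        seqs = {"chr1": "ACGTACGTNN", "chr2": "TTTT"}
        p = tmp_path / "g.fa"
        core_io.write_fasta(seqs, p)
        assert core_io.read_fasta(p) == seqs

    def test_ct_round_trip_with_no_amplification(self, tmp_path):
        df = pd.DataFrame({
            "sample_id": ["s1", "s1", "s2"],
            "assay": ["TCF7", "Alu", "TCF7"],
            "ct": [24.5, 18.0, np.nan],
        })
        table = core_io.CtTable(df)
        p = tmp_path / "ct.tsv"
        core_io.write_ct_table(table, p)
        back = core_io.read_ct_table(p)
        assert np.isnan(back.replicates("s2", "TCF7")).all()
        assert back.replicates("s1", "Alu") == pytest.approx([18.0])
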