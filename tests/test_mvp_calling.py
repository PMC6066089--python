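import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from alclmeth import mvp_calling as mvp, synthetic_data as synth
from alclmeth.core_io import BetaMatrix, SampleSheet
from conftest import make_manifest


def _sheet(groups):
    return SampleSheet(pd.DataFrame(
        [(s, g) for g, samples in groups.items() for s in samples],
        columns=["sample_id", "group"],
    ))


class TestBetaToM:
    def test_closed_forms(self):
        assert mvp.beta_to_m(0.5, epsilon=1e-12) == pytest.approx(0.0, abs=1e-9)
        assert mvp.beta_to_m(0.8, epsilon=1e-12) == pytest.approx(2.0, abs=1e-9)

    def test_monotone(self):
        grid = np.linspace(0, 1, 101)
        m = mvp.beta_to_m(grid)
        assert (np.diff(m) > 0).all()

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_inverse_recovers_beta(self, beta):
        m = mvp.beta_to_m(beta)
        assert mvp.m_to_beta(m) == pytest.approx(beta, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mvp.beta_to_m(1.2)
        with pytest.raises(ValueError):
            mvp.beta_to_m(0.5, epsilon=0.0)


class TestCallMvps:
    def _toy(self):
        beta = BetaMatrix(pd.DataFrame(
            {"a1": [0.10, 0.50], "a2": [0.20, 0.52], "a3": [0.15, 0.48],
             "b1": [0.60, 0.50], "b2": [0.70, 0.52], "b3": [0.65, 0.48]},
            index=["cgA", "cgB"],
        ))
        sheet = _sheet({"ALK_POS": ["a1", "a2", "a3"], "CONTROL": ["b1", "b2", "b3"]})
        return beta, sheet

    def test_welch_matches_scipy_oracle(self):
        beta, sheet = self._toy()
        tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL", method="welch")
        m = mvp.beta_to_m(beta.df.to_numpy())
        for i, pid in enumerate(["cgA", "cgB"]):
            t_ref, p_ref = stats.ttest_ind(m[i, :3], m[i, 3:], equal_var=False)
            assert tab.loc[pid, "m_stat"] == pytest.approx(t_ref, abs=1e-12)
            assert tab.loc[pid, "p"] == pytest.approx(p_ref, abs=1e-12)

    def test_identical_groups_tie_rule(self):
        beta = BetaMatrix(pd.DataFrame(
            {"a1": [0.3], "a2": [0.3], "b1": [0.3], "b2": [0.3]}, index=["cgA"]))
        sheet = _sheet({"ALK_POS": ["a1", "a2"], "CONTROL": ["b1", "b2"]})
        for method in ("welch", "moderated"):
            tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL", method=method)
            assert tab.loc["cgA", "delta_beta"] == 0.0
            assert tab.loc["cgA", "p"] == 1.0
            assert tab.loc["cgA", "m_stat"] == 0.0

    def test_constant_but_different_groups_flagged(self):
        beta = BetaMatrix(pd.DataFrame(
            {"a1": [0.2], "a2": [0.2], "b1": [0.6], "b2": [0.6]}, index=["cgA"]))
        sheet = _sheet({"ALK_POS": ["a1", "a2"], "CONTROL": ["b1", "b2"]})
        tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL", method="welch")
        assert bool(tab.loc["cgA", "var_floored"])
        assert tab.loc["cgA", "p"] < 1e-6

    @pytest.mark.parametrize("method", ["welch", "moderated"])
    def test_label_symmetry(self, method, small_cohort):
        _, (_, beta, sheet, _) = small_cohort
        ab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL", method=method)
        ba = mvp.call_mvps(beta, sheet, "CONTROL", "ALK_POS", method=method)
        np.testing.assert_allclose(ab["delta_beta"], -ba["delta_beta"], atol=1e-15)
        np.testing.assert_allclose(ab["p"], ba["p"], rtol=1e-12)
        flip = ab["delta_beta"] != 0
        assert (ab.loc[flip, "direction"] != ba.loc[flip, "direction"]).all()

    def test_requires_two_samples_per_group(self):
        beta = BetaMatrix(pd.DataFrame({"a1": [0.3], "b1": [0.4], "b2": [0.5]},
                                       index=["cgA"]))
        sheet = _sheet({"ALK_POS": ["a1"], "CONTROL": ["b1", "b2"]})
        with pytest.raises(Exception, match=">= 2 samples"):
            mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL")

    def test_null_cohort_raw_p_roughly_uniform(self):
        fracs = []
        for seed in (0, 1, 2):
            cfg = synth.CohortConfig(n_probes=10_000, fraction_hyper=0,
                                     fraction_hypo=0, seed=seed)
            _, beta, sheet, _ = synth.generate_cohort(cfg)
            tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL")
            fracs.append((tab["p"] < 0.05).mean())
        assert all(0.04 <= f <= 0.06 for f in fracs)


class TestBH:
    def _brute_force_bh(self, p):
        """Textbook BH: p_adj(i) = min over j>=i of n*p(j)/j, at sorted ranks."""
        p = np.asarray(p, float)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj_sorted = p[order] * n / (np.arange(n) + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(adj_sorted, 1.0)
        return out

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_small_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(2, 21))
        np.testing.assert_allclose(mvp.bh_adjust(p), self._brute_force_bh(p), atol=1e-12)

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        adj = mvp.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()


class TestFilterMvps:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["p_adj", "delta_beta"],
            index=[f"cg{i}" for i in range(len(rows))],
        ).assign(direction=lambda d: np.where(d.delta_beta > 0, "hyper", "hypo"))

    def test_boundary_p_adj_is_strict(self):
        tab = self._table([(0.01, 0.5)])
        assert len(mvp.filter_mvps(tab)) == 0

    def test_boundary_delta_is_strict(self):
        tab = self._table([(0.001, 0.2), (0.001, -0.2)])
        assert len(mvp.filter_mvps(tab)) == 0

    def test_passing_record_partitioned_by_direction(self):
        tab = self._table([(0.001, 0.25), (0.001, -0.25), (0.5, 0.25)])
        s = mvp.filter_mvps(tab)
        assert s.hyper == {"cg0"} and s.hypo == {"cg1"}

    def test_idempotent(self, small_cohort):
        _, (_, beta, sheet, _) = small_cohort
        tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL")
        once = mvp.filter_mvps(tab)
        twice = mvp.filter_mvps(once.table)
        assert once.probe_ids == twice.probe_ids

    def test_recovers_planted_effects(self, small_cohort):
        _, (_, beta, sheet, truth) = small_cohort
        tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL")
        s = mvp.filter_mvps(tab)
        tp = len(s.probe_ids & set(truth.mvp_truth))
        assert tp / len(truth.mvp_truth) >= 0.8
        assert tp / len(s) >= 0.9


class TestVenn:
    def test_disjoint_sets(self):
        v = mvp.venn_counts({"1"}, {"2"}, {"3"})
        assert v["ab"] == v["ac"] == v["bc"] == v["abc"] == 0
        assert v["a_only"] == v["b_only"] == v["c_only"] == 1

    def test_identical_sets(self):
        s = {"1", "2", "3"}
        v = mvp.venn_counts(s, s, s)
        assert v["abc"] == 3
        assert v["a_only"] == v["ab"] == 0

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_matches_set_algebra_oracle(self, seed):
        rng = np.random.default_rng(seed)
        universe = np.arange(1000)
        a, b, c = (set(rng.choice(universe, size=rng.integers(0, 400), replace=False))
                   for _ in range(3))
        v = mvp.venn_counts(a, b, c)
        assert v["abc"] == len(a & b & c)
        assert v["a_only"] == len(a - b - c)
        assert v["ab"] == len((a & b) - c)
        total = (v["a_only"] + v["b_only"] + v["c_only"]
                 + v["ab"] + v["ac"] + v["bc"] + v["abc"])
        assert total == len(a | b | c)


class TestGenomicDistribution:
    def test_multi_membership_probe_counts_once_per_category(self):
        manifest = make_manifest([
            ("cg01", "chr1", 100, "A", "Body", "Shore"),
        ])
        s = mvp.MVPSet(table=pd.DataFrame(), hyper=set(), hypo={"cg01"})
        by_cat, by_rel = mvp.genomic_distribution(s, manifest)
        assert by_cat.loc["Body", "hypo"] == 1
        assert by_rel.loc["Shore", "hypo"] == 1
        assert by_cat["hyper"].sum() == 0

    def test_empty_set_gives_zero_table(self, small_cohort):
        _, (manifest, _, _, _) = small_cohort
        s = mvp.MVPSet(table=pd.DataFrame(), hyper=set(), hypo=set())
        by_cat, by_rel = mvp.genomic_distribution(s, manifest)
        assert (by_cat.to_numpy() == 0).all() and (by_rel.to_numpy() == 0).all()

    def test_matches_brute_force_groupby(self, small_cohort):
        _, (manifest, beta, sheet, _) = small_cohort
        tab = mvp.call_mvps(beta, sheet, "ALK_POS", "CONTROL")
        s = mvp.filter_mvps(tab)
        by_cat, _ = mvp.genomic_distribution(s, manifest)
        rec = manifest.records
        for direction, ids in (("hyper", s.hyper), ("hypo", s.hypo)):
            expected = rec[rec.probe_id.isin(ids)].groupby("region_category").size()
            for cat, cnt in expected.items():
                assert by_cat.loc[cat, direction] == cnt
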