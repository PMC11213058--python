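import math
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from exprland.expression_core import ExpressionProfile
from exprland.gwas_to_expression import (ScanConfig, anderson_darling_2sample,
                                         metric_values, permutation_test,
                                         results_to_wide, run_scan,
                                         select_relevant_tissues,
                                         sensitivity_exclude_top,
                                         t_test_higher, triangulate)
from exprland.synthetic_data import SyntheticConfig, synth_expression


class TestWelchT:
    def test_equal_groups_give_half(self, rng):
        x = rng.normal(size=50)
        t, p = t_test_higher(x, x.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_matches_hand_welch_computation(self):
        d, c = [3.0, 4.0, 5.0], [1.0, 2.0, 3.0]
        # hand Welch: means 4, 2; var 1 each; se = sqrt(2/3); df = 4
        t_hand = 2.0 / math.sqrt(2.0 / 3.0)
        p_hand = sps.t.sf(t_hand, df=4)
        t, p = t_test_higher(d, c)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_direction_one_sided(self, rng):
        x = rng.normal(size=30)
        _, p = t_test_higher(x - 10, x)
        assert p > 0.999

    def test_monotone_in_shift(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        ps = [t_test_higher(x + delta, y)[1] for delta in (0.0, 0.5, 1.0, 2.0)]
        assert ps == sorted(ps, reverse=True)

    def test_degenerate_equal_constants(self):
        with pytest.warns(UserWarning):
            _, p = t_test_higher([2.0, 2.0], [2.0, 2.0])
        assert p == 0.5


class TestAndersonDarling:
    def test_statistic_matches_independent_implementation(self, rng):
        """scipy's Scholz-Stephens implementation as the external oracle."""
        for _ in range(100):
            n1, n2 = rng.integers(4, 30, size=2)
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            if rng.random() < 0.4:
                x, y = np.round(x), np.round(y)  # force tie handling
            stat, _ = anderson_darling_2sample(x, y)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ref = sps.anderson_ksamp([x, y], midrank=True)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)

    def test_pvalue_matches_scipy_within_table_range(self, rng):
        x, y = rng.normal(size=40), rng.normal(0.4, 1.0, size=40)
        stat, p = anderson_darling_2sample(x, y)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sps.anderson_ksamp([x, y], midrank=True)
        if 0.001 < ref.significance_level < 0.25:
            assert p == pytest.approx(ref.significance_level, rel=1e-6)

    def test_identical_multisets_permutation_p_one(self, rng):
        x = rng.normal(size=8)
        _, p = anderson_darling_2sample(x, x.copy(), mode="permutation",
                                        n_perm=200, rng=rng)
        assert p > 0.5

    def test_rank_invariance_under_monotone_transform(self, rng):
        x, y = rng.uniform(1, 5, 25), rng.uniform(2, 6, 30)
        s1, _ = anderson_darling_2sample(x, y)
        s2, _ = anderson_darling_2sample(np.exp(x), np.exp(y))
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_all_identical_degenerate(self):
        with pytest.warns(UserWarning):
            _, p = anderson_darling_2sample([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0

    def test_tail_pvalues_decrease_monotonically(self):
        from exprland.gwas_to_expression import _ad_pvalue_asymptotic
        tms = [1.0, 3.0, 6.0, 12.0, 30.0, 80.0]
        ps = [_ad_pvalue_asymptotic(t) for t in tms]
        assert ps == sorted(ps, reverse=True)
        assert ps[-1] > 0.0


class TestPermutationTest:
    def test_exhaustive_four_gene_example(self):
        vals = pd.Series([5.0, 6.0, 1.0, 2.0], index=list("abcd"))
        assert permutation_test(vals, {"a", "b"}) == pytest.approx(1 / 6)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(1, n))
            vals = pd.Series(rng.normal(size=n),
                             index=[f"g{i}" for i in range(n)])
            disease = set(rng.choice(vals.index, k, replace=False))
            p = permutation_test(vals, disease)
            v = vals.to_numpy()
            d_idx = vals.index.isin(disease)
            obs = v[d_idx].mean() - v[~d_idx].mean()
            count = sum(
                1 for c in combinations(range(n), k)
                if (v[list(c)].mean()
                    - np.delete(v, list(c)).mean()) >= obs - 1e-12)
            assert p == pytest.approx(count / math.comb(n, k))

    def test_null_uniformity_monte_carlo(self, rng):
        """Under exchangeability the p-value is uniform over its grid."""
        ps = []
        for _ in range(300):
            vals = pd.Series(rng.normal(size=40),
                             index=[f"g{i}" for i in range(40)])
            disease = set(rng.choice(vals.index, 8, replace=False))
            ps.append(permutation_test(vals, disease, n_perm=99, seed=rng))
        assert abs(np.mean(ps) - 0.5) < 0.06

    def test_seed_determinism(self, rng):
        vals = pd.Series(rng.normal(size=60),
                         index=[f"g{i}" for i in range(60)])
        disease = set(vals.index[:10])
        p1 = permutation_test(vals, disease, n_perm=500, seed=7)
        p2 = permutation_test(vals, disease, n_perm=500, seed=7)
        assert p1 == p2

    def test_empty_disease_set_errors(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            permutation_test(vals, set())


class TestRunScan:
    def test_planted_context_attains_minimum_p(self):
        cfg = SyntheticConfig(seed=3)
        profile, truth = synth_expression(cfg)
        res = run_scan(profile, [set(truth["disease_genes"])],
                       ScanConfig(metrics=("absolute", "relative"),
                                  tests=("t",)))
        best = res.loc[res.groupby("metric")["p_value"].idxmin(), "context"]
        assert truth["target_contexts"][0] in set(best)

    def test_identical_contexts_identical_rows(self, rng):
        tpm = pd.DataFrame(
            np.tile(rng.uniform(0, 50, size=(100, 1)), (1, 2)),
            index=[f"g{i}" for i in range(100)], columns=["c0", "c1"])
        profile = ExpressionProfile(tpm)
        res = run_scan(profile, [set(tpm.index[:10])],
                       ScanConfig(metrics=("absolute",), tests=("t", "AD")))
        a = res[res.context == "c0"].drop(columns="context").reset_index(drop=True)
        b = res[res.context == "c1"].drop(columns="context").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_disease_genes_gives_na_with_reason(self, rng):
        tpm = pd.DataFrame(rng.uniform(1, 50, size=(50, 1)),
                           index=[f"g{i}" for i in range(50)], columns=["c0"])
        tpm.iloc[0, 0] = 0.0  # single disease gene, and it is unexpressed
        profile = ExpressionProfile(tpm)
        res = run_scan(profile, [{"g0", "g1"}],
                       ScanConfig(metrics=("absolute",), tests=("t",)))
        assert res["p_value"].isna().iloc[0] or res["n_disease"].iloc[0] >= 2

    def test_metric_values_log2_relative_finite(self, rng):
        tpm = pd.DataFrame(rng.uniform(0, 20, size=(60, 3)),
                           index=[f"g{i}" for i in range(60)],
                           columns=["c0", "c1", "c2"])
        tpm.iloc[:10, 0] = 0.0
        profile = ExpressionProfile(tpm)
        vals = metric_values(profile, "c0", "relative")
        assert np.isfinite(vals).all()
        assert len(vals) == 50


class TestSensitivityAndSelection:
    def test_exclude_top_removes_ten_percent(self, rng):
        tpm = pd.DataFrame(rng.uniform(1, 100, size=(100, 2)),
                           index=[f"g{i}" for i in range(100)],
                           columns=["c0", "c1"])
        profile = ExpressionProfile(tpm)
        out = sensitivity_exclude_top(profile, "c0", fraction=0.10)
        assert len(out.gene_ids) == 90
        dropped = set(profile.gene_ids) - set(out.gene_ids)
        assert dropped == set(profile.A["c0"].nlargest(10).index)

    def test_threshold_formula(self):
        res = pd.DataFrame({
            "context": ["c0"] * 4,
            "gene_list": ["l1", "l1", "l2", "l2"],
            "metric": ["absolute"] * 4,
            "test": ["t", "AD", "t", "AD"],
            "p_value": [1e-6] * 4,
        })
        thr = 0.05 / (45 * 3 * 2)
        assert thr == pytest.approx(1.8518518e-4, rel=1e-6)
        assert select_relevant_tissues(res, 45, 3, 2) == ["c0"]

    def test_single_failing_test_excludes_context(self):
        res = pd.DataFrame({
            "context": ["c0"] * 2, "gene_list": ["l1"] * 2,
            "metric": ["absolute"] * 2, "test": ["t", "AD"],
            "p_value": [1e-10, 0.01],
        })
        assert select_relevant_tissues(res, 45, 3, 2) == []

    def test_all_zero_p_included(self):
        res = pd.DataFrame({
            "context": ["c0"], "gene_list": ["l1"],
            "metric": ["absolute"], "test": ["t"], "p_value": [0.0]})
        assert select_relevant_tissues(res, 45, 3, 2) == ["c0"]


class TestTriangulate:
    def _table(self, ps):
        return pd.DataFrame({
            "context": [f"c{i}" for i in range(len(ps))],
            "metric": "absolute", "p_value": ps})

    def test_identical_vectors_r_one(self, rng):
        ps = rng.uniform(1e-8, 1, 10)
        rep = triangulate({"t": self._table(ps), "AD": self._table(ps)})
        assert rep["r"].iloc[0] == pytest.approx(1.0)

    def test_reversed_vector_r_minus_one(self):
        lp = np.array([1.0, 2.0, 3.0, 4.0])
        rep = triangulate({"a": self._table(10.0 ** -lp),
                           "b": self._table(10.0 ** -lp[::-1])})
        assert rep["r"].iloc[0] == pytest.approx(-1.0)

    def test_planted_signal_correlates_t_and_ad(self):
        cfg = SyntheticConfig(seed=11)
        profile, truth = synth_expression(cfg)
        res = run_scan(profile, [set(truth["disease_genes"])],
                       ScanConfig(metrics=("absolute",), tests=("t", "AD")))
        rep = triangulate({
            "t": res[res.test == "t"], "AD": res[res.test == "AD"]})
        assert rep["r"].iloc[0] > 0.8

    def test_too_few_rows_warns_na(self):
        rep_in = {"a": self._table([0.1, 0.2]), "b": self._table([0.3, 0.1])}
        with pytest.warns(UserWarning):
            rep = triangulate(rep_in)
        assert np.isnan(rep["r"].iloc[0])


def test_wide_matrix_shape():
    cfg = SyntheticConfig(seed=0, n_genes=300, n_contexts=3,
                          n_disease_genes=30, target_contexts=(0,))
    profile, truth = synth_expression(cfg)
    res = run_scan(profile, [set(truth["disease_genes"])],
                   ScanConfig(metrics=("absolute", "relative"),
                              tests=("t", "AD")))
    wide = results_to_wide(res)
    assert wide.shape == (3, 4)
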