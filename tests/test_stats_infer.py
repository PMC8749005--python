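"""Inferential battery: hand computations, independent oracles, calibration."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import neurotraj as nt
from neurotraj.exceptions import ContractError


class TestPairedT:
    def test_hand_computed_example(self):
        # d = (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3))
        res = nt.paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.statistic == pytest.approx(2.0 * np.sqrt(3.0), rel=1e-12)
        assert res.df == 2

    def test_zero_mean_difference_gives_t_zero_p_one(self):
        res = nt.paired_t(np.array([1.0, 2.0, 3.0]), np.array([3.0, 2.0, 1.0]))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy(self, rng):
        a = rng.standard_normal(17)
        b = rng.standard_normal(17)
        res = nt.paired_t(a, b)
        ref = sps.ttest_rel(a, b)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ContractError, match="variance"):
            nt.paired_t(np.array([1.0, 2.0]), np.array([0.0, 1.0]))


class TestRMAnova:
    def test_identical_condition_means_give_f_zero(self, rng):
        Y = rng.standard_normal((8, 3))
        Y -= Y.mean(axis=0, keepdims=True)  # force equal condition means
        res = nt.rm_anova(Y)
        assert res.statistic == pytest.approx(0.0, abs=1e-20)

    def test_matches_brute_force_loops_on_toy_table(self):
        Y = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0]])
        n, k = Y.shape
        grand = Y.mean()
        ss_cond = sum(n * (Y[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subj = sum(k * (Y[i].mean() - grand) ** 2 for i in range(n))
        ss_err = sum(
            (Y[i, j] - Y[i].mean() - Y[:, j].mean() + grand) ** 2
            for i in range(n) for j in range(k)
        )
        F_ref = (ss_cond / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
        res = nt.rm_anova(Y)
        assert res.statistic == pytest.approx(F_ref, rel=1e-12)
        assert res.df == (1.0, 2.0)

    def test_matches_statsmodels_anovarm(self, rng):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        Y = rng.standard_normal((8, 3)) + rng.standard_normal((8, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(8), 3),
                "condition": np.tile(np.arange(3), 8),
                "value": Y.ravel(),
            }
        )
        ref = AnovaRM(long, "value", "subject", within=["condition"]).fit()
        res = nt.rm_anova(Y)
        assert res.statistic == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-9)

    def test_two_way_matches_statsmodels(self, rng):
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM

        Y = rng.standard_normal((10, 3, 2))
        rows = []
        for s in range(10):
            for a in range(3):
                for b in range(2):
                    rows.append({"subject": s, "A": a, "B": b, "value": Y[s, a, b]})
        ref = AnovaRM(pd.DataFrame(rows), "value", "subject", within=["A", "B"]).fit()
        res = nt.rm_anova_two_way(Y)
        table = ref.anova_table["F Value"]
        assert res["A"].statistic == pytest.approx(float(table.loc["A"]), rel=1e-9)
        assert res["B"].statistic == pytest.approx(float(table.loc["B"]), rel=1e-9)
        assert res["AxB"].statistic == pytest.approx(float(table.loc["A:B"]), rel=1e-9)

    def test_missing_cells_rejected(self):
        Y = np.ones((4, 3))
        Y[1, 2] = np.nan
        with pytest.raises(ContractError, match="missing|non-finite"):
            nt.rm_anova(Y)


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(5.0)
        assert nt.pearson(x, 3 * x + 1).statistic == pytest.approx(1.0)
        assert nt.pearson(x, -x).statistic == pytest.approx(-1.0)

    def test_matches_scipy_pearsonr(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        res = nt.pearson(x, y)
        ref = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(ContractError):
            nt.pearson(np.ones(6), np.arange(6.0))


class TestDependentCorrelations:
    def test_equal_correlations_give_z_zero(self):
        cross = {"r13": 0.2, "r14": 0.1, "r23": 0.1, "r24": 0.2}
        res = nt.compare_dependent_correlations(0.5, 0.5, cross, n=20)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_zero_cross_terms_hand_evaluation(self):
        # c = 0, so z = (atanh(.5) - atanh(-.5)) * sqrt((17-3)/2)
        cross = dict(r13=0.0, r14=0.0, r23=0.0, r24=0.0)
        res = nt.compare_dependent_correlations(0.5, -0.5, cross, n=17)
        expected = (np.arctanh(0.5) - np.arctanh(-0.5)) * np.sqrt(14.0 / 2.0)
        assert res.statistic == pytest.approx(expected, rel=1e-12)

    def test_incomplete_cross_terms_rejected(self):
        with pytest.raises(ContractError, match="missing"):
            nt.compare_dependent_correlations(0.3, 0.1, {"r13": 0.1}, n=20)

    def test_degenerate_correlation_rejected(self):
        cross = dict(r13=0.0, r14=0.0, r23=0.0, r24=0.0)
        with pytest.raises(ContractError):
            nt.compare_dependent_correlations(1.0, 0.5, cross, n=20)
        with pytest.raises(ContractError):
            nt.compare_dependent_correlations(0.5, 0.3, cross, n=5)


class TestBHFDR:
    def test_printed_style_example_all_adjusted_to_004(self):
        adjusted = nt.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, 0.04)

    def test_single_p_unchanged(self):
        assert nt.bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_ones(self):
        assert np.allclose(nt.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            nt.bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    def test_monotone_and_permutation_equivariant(self, ps):
        ps = np.asarray(ps)
        adj = nt.bh_fdr(ps)
        assert np.all(adj >= ps - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        assert np.allclose(nt.bh_fdr(ps[perm]), adj[perm])

    def test_adjust_family_attaches_qvalues(self):
        results = [
            nt.paired_t(np.array([1.0, 2.0, 4.0]), np.array([0.0, 1.0, 2.0])),
            nt.pearson(np.arange(5.0), np.array([1.0, 2.0, 1.5, 3.0, 2.5])),
        ]
        nt.adjust_family(results, family_id="demo")
        for r in results:
            assert r.p_fdr is not None and r.p_fdr >= r.p
            assert r.family_id == "demo"
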