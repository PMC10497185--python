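"""Inferential layer: t-tests, Bayes factors, FDR, chi-square, decision rule.

Published-table reference values (t, r, n, P, pFDR, BF10 combinations from
the study being reproduced) serve as high-precision oracles for the
analytic recomputations; pingouin and statsmodels provide independent
implementations for cross-checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from intinhib.group_stats import (
    PriorSettings,
    bf_correlation,
    bh_fdr,
    chi_square_independence,
    correlation_test,
    jzs_bf_ttest,
    p_from_r,
    p_from_t,
    rejects_null,
    split_by_comparison_max,
    t_test_independent,
)


class TestPFromT:
    def test_zero_statistic(self):
        assert p_from_t(0.0, 10) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "t,dof,expected",
        [
            (3.062, 42, 0.004),   # group NoGo vs Choose-NoGo
            (2.721, 42, 0.009),   # group Choose-Go vs Choose-NoGo
            (2.647, 42, 0.011),   # group Go vs Choose-Go
            (2.616, 42, 0.012),   # group Go vs NoGo
            (0.356, 42, 0.724),   # age comparison
            (-2.423, 42, 0.020),  # Go omissions
        ],
    )
    def test_reproduces_published_p_values(self, t, dof, expected):
        assert p_from_t(t, dof) == pytest.approx(expected, abs=5e-4)

    def test_monte_carlo_consistency(self):
        # p_from_t agrees with the empirical tail of simulated t draws
        rng = np.random.default_rng(0)
        n = 10**6
        draws = rng.standard_t(df=12, size=n)
        for t in (1.0, 2.0):
            emp = np.mean(np.abs(draws) >= t)
            se = np.sqrt(emp * (1 - emp) / n)
            assert abs(p_from_t(t, 12) - emp) < 3 * se + 1e-12

    def test_invalid_dof(self):
        with pytest.raises(ValueError):
            p_from_t(1.0, 0)


class TestTTest:
    def test_identical_means(self):
        res = t_test_independent([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_pooled_formula_oracle(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        res = t_test_independent(x, y)
        sp = np.sqrt(((2) * x.var(ddof=1) + (2) * y.var(ddof=1)) / 4)
        expected = (x.mean() - y.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        assert res.t == pytest.approx(expected)
        assert res.dof == 4

    def test_matches_scipy_student(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        x, y = rng.normal(size=21), rng.normal(0.5, 1, size=23)
        res = t_test_independent(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.dof == 42

    def test_engineered_group_difference_reproduces_p(self):
        # groups of 21 and 23 engineered to |t| = 3.062 -> p = 0.004
        rng = np.random.default_rng(1)
        x = rng.normal(size=21)
        y = rng.normal(size=23)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        # with unit pooled variance, shift y by t * sqrt(1/21 + 1/23)
        y = y + 3.062 * np.sqrt(1 / 21 + 1 / 23)
        res = t_test_independent(y, x)
        assert abs(res.t) == pytest.approx(3.062, abs=1e-9)
        assert res.p_two_tailed == pytest.approx(0.004, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test_independent([1.0, 1.0], [1.0, 1.0])


class TestJZSBayesFactor:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (2.616, 4.185),
            (2.721, 5.141),
            (2.647, 4.445),
            (3.062, 10.466),
        ],
    )
    def test_reproduces_published_bf10(self, t, expected):
        bf = jzs_bf_ttest(t, 21, 23, scale=0.707)
        assert bf == pytest.approx(expected, rel=0.005)

    def test_sign_symmetric(self):
        assert jzs_bf_ttest(-3.062, 21, 23) == pytest.approx(
            jzs_bf_ttest(3.062, 21, 23), rel=1e-8
        )

    def test_reciprocal_identity(self):
        for t in (0.0, 1.3, 3.0):
            bf10 = jzs_bf_ttest(t, 12, 15)
            bf01 = 1.0 / bf10
            assert bf10 * bf01 == pytest.approx(1.0)

    def test_null_favoured_at_zero(self):
        assert jzs_bf_ttest(0.0, 21, 23) < 1.0

    def test_monotone_in_abs_t(self):
        ts = np.linspace(0, 5, 11)
        bfs = [jzs_bf_ttest(t, 21, 23) for t in ts]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n1, n2 in [(2.0, 10, 12), (3.062, 21, 23)]:
            ref = float(pingouin.bayesfactor_ttest(t, n1, n2, paired=False,
                                                   r=0.707))
            assert jzs_bf_ttest(t, n1, n2) == pytest.approx(ref, rel=1e-3)


class TestCorrelation:
    @pytest.mark.parametrize(
        "r,n,expected_p",
        [
            (0.513, 23, 0.012),
            (0.485, 23, 0.019),
            (0.427, 23, 0.042),
        ],
    )
    def test_reproduces_published_correlation_p(self, r, n, expected_p):
        assert p_from_r(r, n) == pytest.approx(expected_p, abs=5e-4)

    def test_perfect_linear_data(self):
        x = np.arange(10.0)
        res = correlation_test(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_two_tailed < 1e-10

    def test_matches_scipy_pearsonr(self):
        from scipy import stats

        rng = np.random.default_rng(2)
        x, y = rng.normal(size=23), rng.normal(size=23)
        res = correlation_test(x, y)
        ref = stats.pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-8)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationBayesFactor:
    @pytest.mark.parametrize(
        "r,expected",
        [
            (0.513, 4.943),
            (0.485, 3.447),
            (0.427, 1.817),
        ],
    )
    def test_reproduces_published_bf10(self, r, expected):
        assert bf_correlation(r, 23, width=1.0) == pytest.approx(expected,
                                                                 rel=0.01)

    def test_null_favoured_and_symmetric_at_zero(self):
        assert bf_correlation(0.0, 23) < 1.0
        for r in (0.2, 0.5, 0.8):
            assert bf_correlation(r, 23) == pytest.approx(
                bf_correlation(-r, 23), rel=1e-8
            )

    def test_monotone_in_abs_r(self):
        rs = np.linspace(0, 0.9, 10)
        bfs = [bf_correlation(r, 23) for r in rs]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for r, n in [(0.513, 23), (0.3, 40)]:
            ref = float(pingouin.bayesfactor_pearson(r, n))
            assert bf_correlation(r, n) == pytest.approx(ref, rel=0.01)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            bf_correlation(1.0, 23)


def brute_force_bh(p):
    """Literal min-over-tail definition of BH adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = np.empty(m)
    for i in range(m):
        adj[i] = min(min(ranked[j] * m / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBHFDR:
    def test_all_equal_p_unchanged(self):
        p = np.full(6, 0.03)
        np.testing.assert_allclose(bh_fdr(p), p)

    def test_published_family_adjustments(self):
        # NoGo vs Choose-NoGo family: six per-ROI p's derived from the
        # printed t's at 42 dof; the smallest adjusts to 0.023
        ts = [3.062, 0.114, 1.766, 0.634, 1.697, 2.193]
        p = np.array([p_from_t(t, 42) for t in ts])
        adj = bh_fdr(p)
        assert adj[0] == pytest.approx(0.023, abs=5e-4)
        # Go vs NoGo family: preSMA adjusts to 0.074
        ts2 = [2.616, 0.063, 1.249, 0.878, 1.244, 0.187]
        adj2 = bh_fdr(np.array([p_from_t(t, 42) for t in ts2]))
        assert adj2[0] == pytest.approx(0.074, abs=5e-4)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(np.array(p)), brute_force_bh(p),
                                   atol=1e-12)

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_monotone_and_bounded(self, p):
        p = np.array(p)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(4)
        p = rng.uniform(size=12)
        _, ref, _, _ = sm.multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), ref, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, 1.2]))


class TestChiSquare:
    def test_balanced_table_null(self):
        stat, p = chi_square_independence([[10, 10], [10, 10]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_expected_count_oracle(self):
        # direct arithmetic on the 11/10 vs 13/10 sex table
        obs = np.array([[11.0, 10.0], [13.0, 10.0]])
        row, col, tot = obs.sum(1), obs.sum(0), obs.sum()
        exp = np.outer(row, col) / tot
        oracle = ((obs - exp) ** 2 / exp).sum()
        stat, p = chi_square_independence(obs)
        assert stat == pytest.approx(oracle, abs=1e-12)
        assert 0 < p <= 1

    def test_doubling_counts_doubles_statistic(self):
        t1, _ = chi_square_independence([[12, 7], [5, 16]])
        t2, _ = chi_square_independence([[24, 14], [10, 32]])
        assert t2 == pytest.approx(2 * t1)

    def test_matches_scipy_uncorrected(self):
        from scipy import stats

        table = [[11, 10], [13, 10]]
        ref = stats.chi2_contingency(table, correction=False)
        stat, p = chi_square_independence(table)
        assert stat == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [5, 3]])


class TestSubgroupSplit:
    def test_boundary_is_inclusive_for_overlapping(self):
        parts = split_by_comparison_max([1.9, 2.0, 2.1], [1.0, 2.0])
        np.testing.assert_array_equal(parts["greater"], [2.1])
        np.testing.assert_array_equal(sorted(parts["overlapping"]), [1.9, 2.0])

    def test_all_below_max(self):
        parts = split_by_comparison_max([0.1, 0.2], [1.0, 0.5])
        assert len(parts["greater"]) == 0
        assert len(parts["overlapping"]) == 2

    @given(
        ts=st.lists(st.floats(-5, 5), min_size=1, max_size=20),
        cn=st.lists(st.floats(-5, 5), min_size=1, max_size=20),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_explicit_loop(self, ts, cn):
        parts = split_by_comparison_max(ts, cn)
        cut = max(cn)
        greater = [x for x in ts if x > cut]
        overlap = [x for x in ts if x <= cut]
        assert sorted(parts["greater"]) == sorted(greater)
        assert sorted(parts["overlapping"]) == sorted(overlap)
        assert len(parts["greater"]) + len(parts["overlapping"]) == len(ts)


class TestDecisionRule:
    @pytest.mark.parametrize(
        "p,bf,expected",
        [
            (0.004, 10.466, True),   # significant and well-supported
            (0.012, 4.185, True),
            (0.034, 1.956, False),   # significant but BF inconclusive
            (0.06, 5.0, False),      # supported but not significant
            (0.5, 0.3, False),
        ],
    )
    def test_joint_rule(self, p, bf, expected):
        assert rejects_null(p, bf) is expected

    def test_prior_settings_validated(self):
        with pytest.raises(ValueError):
            PriorSettings(t_test_cauchy_scale=0.0)
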