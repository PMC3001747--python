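"""Statistical kernels against independent oracles and hand-computed values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from protadapt.stats import (
    ContingencyTable2x2,
    anova_group_effect,
    benjamini_yekutieli,
    chi_square_2x2,
    cumulative_mann_kendall,
    fisher_exact_2x2,
    mann_kendall,
    mantel_haenszel,
    mid_p_fisher,
    ols_trend,
    wilcoxon_paired,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def brute_force_s(x, y):
    s = 0
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            s += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    return int(s)


def mk_permutation_p(x, y):
    """Exact two-sided p of |S| by full enumeration of y permutations."""
    s_obs = abs(brute_force_s(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        count += abs(brute_force_s(x, perm)) >= s_obs
    return count / total


def wilcoxon_sign_enumeration_p(d):
    """Exact two-sided signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(d, float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for bits in itertools.product([0, 1], repeat=n):
        ws.append(sum(r for b, r in zip(bits, ranks) if b))
    ws = np.asarray(ws)
    p_low = np.mean(ws <= w_obs)
    p_high = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(p_low, p_high))


def hypergeom_enumeration(a, b, c, d):
    """(exact two-sided p, mid-p) by direct hypergeometric enumeration."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in range(lo, hi + 1)}
    p_obs = probs[a]
    exact = sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))
    tied = sum(p for p in probs.values() if abs(p / p_obs - 1) <= 1e-7)
    return min(1.0, exact), min(1.0, exact - 0.5 * tied)


# ---------------------------------------------------------------------------
# Mann-Kendall
# ---------------------------------------------------------------------------


class TestMannKendall:
    def test_perfect_concordance(self):
        r = mann_kendall([1, 2, 3], [1.0, 2.0, 3.0])
        assert r.S == 3 and r.p_two_sided < 1

    def test_constant_y_degenerate(self):
        with pytest.warns(UserWarning):
            r = mann_kendall([1, 2, 3], [5.0, 5.0, 5.0])
        assert r.S == 0 and r.p_two_sided == 1.0 and r.degenerate

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 1, 2, 2], [0.1, 0.2, 0.5, 0.4]),
            ([1, 2, 3, 1, 2, 3], [0.3, 0.1, 0.9, 0.2, 0.8, 0.7]),
            ([1, 1, 2, 2, 3, 3], [1.0, 3.0, 2.0, 5.0, 4.0, 6.0]),
            ([1, 1, 1, 2, 2, 2, 3, 3], [3, 1, 4, 1, 5, 9, 2, 6]),
        ],
    )
    def test_s_matches_brute_force_and_p_near_exact(self, x, y):
        r = mann_kendall(x, y)
        assert r.S == brute_force_s(x, y)
        p_exact = mk_permutation_p(x, y)
        assert abs(r.p_two_sided - p_exact) < 0.15

    def test_variance_matches_kendalltau_formulation(self):
        # cross-check the tie-corrected var against scipy's kendalltau z
        rng = np.random.default_rng(2)
        x = np.repeat([1, 2, 3], 5)
        y = rng.normal(size=15)
        r = mann_kendall(x, y)
        tau = sps.kendalltau(x, y)
        # scipy's normal-approximation p uses the same variance, without
        # the continuity correction; recompute z from our S and variance
        z_nocc = r.S / math.sqrt(r.var_S)
        p_nocc = 2 * sps.norm.sf(abs(z_nocc))
        assert p_nocc == pytest.approx(
            sps.kendalltau(x, y, method="asymptotic").pvalue, rel=1e-6
        )

    def test_negating_y_negates_s_preserves_p(self):
        x = [1, 1, 2, 2, 3, 3]
        y = [0.3, 0.5, 0.2, 0.9, 1.0, 0.8]
        r1 = mann_kendall(x, y)
        r2 = mann_kendall(x, [-v for v in y])
        assert r2.S == -r1.S
        assert r2.p_two_sided == pytest.approx(r1.p_two_sided)

    @given(st.lists(st.integers(-100, 100), min_size=4, max_size=10, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, y):
        x = list(range(1, len(y) + 1))
        r1 = mann_kendall(x, y)
        r2 = mann_kendall(x, [math.atan(v / 100) + 5 for v in y])
        assert r1.S == r2.S
        assert r1.p_two_sided == pytest.approx(r2.p_two_sided)


class TestCumulativeMannKendall:
    def test_single_block_reduction(self):
        x, y = [1, 1, 2, 2, 3, 3], [0.1, 0.4, 0.2, 0.6, 0.5, 0.9]
        single = mann_kendall(x, y)
        cum = cumulative_mann_kendall([(x, y)])
        assert cum.S == single.S
        assert cum.var_S == pytest.approx(single.var_S)
        assert cum.p_two_sided == pytest.approx(single.p_two_sided)

    def test_two_copies_hand_variance(self):
        block = ([1, 2, 3], [1.0, 2.0, 3.0])
        cum = cumulative_mann_kendall([block, block])
        assert cum.S == 6
        assert cum.var_S == pytest.approx(2 * (3 * 2 * 11 / 18))

    def test_identical_blocks_scale_linearly(self):
        x, y = [1, 1, 2, 2, 3, 3], [0.5, 0.1, 0.9, 0.4, 0.3, 1.0]
        one = cumulative_mann_kendall([(x, y)])
        five = cumulative_mann_kendall([(x, y)] * 5)
        assert five.S == 5 * one.S
        assert five.var_S == pytest.approx(5 * one.var_S)

    def test_degenerate_blocks_skipped(self):
        good = ([1, 2, 3], [1.0, 3.0, 2.0])
        bad = ([1, 1, 1], [1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="skipped"):
            cum = cumulative_mann_kendall([good, bad])
        assert cum.n_blocks == 1 and cum.n_skipped == 1

    def test_all_blocks_degenerate_is_error(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                cumulative_mann_kendall([([1, 1, 1], [1.0, 2.0, 3.0])])


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------


class TestWilcoxon:
    def test_six_positive_deltas(self):
        r = wilcoxon_paired([0.5, 1.5, 2.5, 3.5, 4.5, 5.5])
        assert r.exact
        assert r.p == pytest.approx(2 / 2**6)

    def test_symmetric_pairs_p_one(self):
        r = wilcoxon_paired([1, 2, 3, -1, -2, -3])
        assert r.p == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        r = wilcoxon_paired([0.0, 0.0])
        assert r.p == 1.0 and r.degenerate

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_branch_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, size=10)
        while len(np.unique(np.abs(d))) < len(d):
            d = rng.normal(0.3, 1.0, size=10)
        r = wilcoxon_paired(d)
        assert r.exact
        assert r.p == pytest.approx(wilcoxon_sign_enumeration_p(d), abs=1e-12)

    def test_small_n_flag(self):
        r = wilcoxon_paired([1.0, 2.0, 3.0])
        assert r.small_n


# ---------------------------------------------------------------------------
# ANOVA and regression
# ---------------------------------------------------------------------------


class TestAnova:
    def test_hand_computed_f(self):
        F, p = anova_group_effect([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert F == pytest.approx(13.5)
        assert p == pytest.approx(1 - sps.f.cdf(13.5, 1, 4))

    def test_identical_groups(self):
        F, p = anova_group_effect([1, 2, 1, 2], [0, 0, 1, 1])
        assert F == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError, match="exactly 2"):
            anova_group_effect([1, 2, 3], [0, 1, 2])

    def test_stratified_equals_centered_oneway_on_balanced_design(self):
        # constant stratum shift, balanced 2x2 design
        rng = np.random.default_rng(4)
        base = rng.normal(size=8)
        y = base + np.array([0, 0, 0, 0, 10, 10, 10, 10])
        g = np.array([0, 0, 1, 1, 0, 0, 1, 1])
        s = np.array(["A"] * 4 + ["B"] * 4)
        F2, p2 = anova_group_effect(y, g, s)
        # center each stratum, then adjust the one-way test to the same
        # residual df (two-way loses one df to the stratum term)
        yc = y.copy()
        for lab in ("A", "B"):
            yc[s == lab] -= yc[s == lab].mean()
        ssb = sum(
            len(yc[g == k]) * yc[g == k].mean() ** 2 for k in (0, 1)
        )
        ssw = sum(((yc[g == k] - yc[g == k].mean()) ** 2).sum() for k in (0, 1))
        F_hand = ssb / 1 / (ssw / 5)
        assert F2 == pytest.approx(F_hand, rel=1e-10)


class TestOlsTrend:
    def test_exact_line(self):
        r = ols_trend([1.0, 2.0, 3.0], [1, 2, 3])
        assert r.beta1 == pytest.approx(1.0) and r.beta0 == pytest.approx(0.0)

    def test_strata_offsets_exact(self):
        x = [1, 2, 3, 1, 2, 3]
        strata = ["A", "A", "A", "B", "B", "B"]
        y = [xi + (10 if s == "B" else 0) for xi, s in zip(x, strata)]
        r = ols_trend(y, x, strata)
        assert r.beta1 == pytest.approx(1.0)
        assert r.strata_offsets["B"] == pytest.approx(10.0)
        assert r.baseline_stratum == "A"
        assert r.strata_offsets.keys() == {"B"}

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(11)
        x = np.tile([1, 2, 3], 10)
        y = 2 + 0.5 * x + rng.normal(0, 0.1, size=30)
        r = ols_trend(y, x)
        assert abs(r.beta1 - 0.5) < 3 * r.se_slope

    def test_confounded_stratum_named(self):
        # x constant within each stratum => dummy collinear with x
        with pytest.raises(ValueError, match="B"):
            ols_trend([1, 2, 3, 4], [1, 1, 2, 2], ["A", "A", "B", "B"])

    def test_single_stratum_offsets_empty(self):
        r = ols_trend([1.0, 2.1, 2.9], [1, 2, 3], ["A", "A", "A"])
        assert r.strata_offsets == {}


# ---------------------------------------------------------------------------
# 2x2 exact and asymptotic tests
# ---------------------------------------------------------------------------


class TestMidPFisher:
    def test_balanced_table_two_thirds(self):
        r = mid_p_fisher(ContingencyTable2x2(1, 1, 1, 1))
        assert r.p == pytest.approx(2 / 3)

    def test_large_table_midp_below_conventional(self):
        t = ContingencyTable2x2(89, 1754, 14, 514)
        midp = mid_p_fisher(t).p
        exact = fisher_exact_2x2(t).p
        assert midp < exact

    def test_midp_identity(self):
        # mid-p = conventional exact p - half the tied probability mass
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
            exact, midp = hypergeom_enumeration(int(a), int(b), int(c), int(d))
            assert mid_p_fisher(t).p == pytest.approx(midp, abs=1e-12)
            assert fisher_exact_2x2(t).p == pytest.approx(exact, abs=1e-12)

    def test_conventional_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 20, size=4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            t = ContingencyTable2x2(a, b, c, d)
            assert fisher_exact_2x2(t).p == pytest.approx(
                sps.fisher_exact([[a, b], [c, d]])[1], rel=1e-6
            )

    def test_empty_margin_flag(self):
        r = mid_p_fisher(ContingencyTable2x2(0, 0, 3, 4))
        assert r.p == 1.0 and r.not_testable

    def test_one_sided(self):
        # P(A > a) + 0.5 P(A = a) under the hypergeometric null
        t = ContingencyTable2x2(3, 1, 1, 3)
        n, r1, c1 = 8, 4, 4
        pmf = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in range(5)}
        expected = pmf[4] + 0.5 * pmf[3]
        assert mid_p_fisher(t, "greater").p == pytest.approx(expected)


class TestChiSquare:
    def test_null_table(self):
        r = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert r.chi2 == pytest.approx(0.0) and r.p == pytest.approx(1.0)

    def test_hand_formula(self):
        r = chi_square_2x2(ContingencyTable2x2(20, 10, 10, 20))
        assert r.chi2 == pytest.approx(20 / 3)

    def test_zero_margin_flag(self):
        assert chi_square_2x2(ContingencyTable2x2(0, 0, 5, 5)).not_testable

    def test_asymptotic_agreement_with_midp(self):
        t = ContingencyTable2x2(1100, 900, 1000, 1000)
        assert chi_square_2x2(t).p == pytest.approx(mid_p_fisher(t).p, abs=0.01)


class TestMantelHaenszel:
    def test_single_stratum_or(self):
        r = mantel_haenszel([ContingencyTable2x2(8, 2, 2, 8)])
        assert r.common_or == pytest.approx(8 * 8 / (2 * 2))

    def test_identical_null_tables(self):
        r = mantel_haenszel([ContingencyTable2x2(5, 5, 5, 5)] * 2)
        assert r.common_or == pytest.approx(1.0)
        assert r.chi2 < 0.1 and r.p > 0.5

    def test_hand_evaluated_estimator(self):
        r = mantel_haenszel(
            [ContingencyTable2x2(8, 2, 2, 8), ContingencyTable2x2(16, 4, 4, 16)]
        )
        assert r.common_or == pytest.approx(16.0)

    def test_degenerate_flag(self):
        r = mantel_haenszel([ContingencyTable2x2(0, 0, 0, 0)])
        assert r.not_testable and r.p == 1.0


# ---------------------------------------------------------------------------
# Benjamini-Yekutieli
# ---------------------------------------------------------------------------


class TestBenjaminiYekutieli:
    def test_hand_case(self):
        adj = benjamini_yekutieli([0.01, 0.02, 0.03])
        assert np.allclose(adj, 0.055)

    def test_single_one(self):
        assert benjamini_yekutieli([1.0]) == pytest.approx([1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_yekutieli([0.5, 1.5])

    def test_nan_propagated_and_excluded(self):
        adj = benjamini_yekutieli([0.01, np.nan, 0.02])
        assert np.isnan(adj[1])
        # m = 2, c(2) = 1.5
        assert adj[0] == pytest.approx(min(1, 0.02 * 2 * 1.5 / 2))

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_by_dominates_bh(self, pvals):
        by = benjamini_yekutieli(pvals)
        bh = multipletests(pvals, method="fdr_bh")[1]
        assert np.all(by >= bh - 1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=40)
        adj = benjamini_yekutieli(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
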