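"""Statistical kernels for trend detection in grouped alignment data.

The module collects every test the toolbox dispatches to:

* Mann-Kendall trend test with tie-corrected variance, and its
  *cumulative* (blocked) form that sums the S statistics and variances
  over many alignments — the workhorse for detecting a common monotone
  trend across protein families;
* Wilcoxon signed-rank test for paired per-family deltas;
* one-way and two-way additive ANOVA for the 2-group composition design;
* ordinary least squares with ordinal predictor and optional
  stratum-specific intercepts (the "parallelism" model);
* mid-p Fisher exact test and Pearson chi-square for 2x2 tables;
* Mantel-Haenszel stratified 2x2 test with the pooled odds-ratio
  estimator;
* Benjamini-Yekutieli step-up FDR adjustment (valid under arbitrary
  dependence).

Degenerate inputs (constant responses, empty table margins) are reported
as p = 1 with a flag rather than raising, because they occur routinely in
sparse substitution matrices during proteome-wide scans.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TrendResult",
    "ContingencyTable2x2",
    "RegressionResult",
    "FisherResult",
    "Chi2Result",
    "MHResult",
    "WilcoxonResult",
    "mann_kendall",
    "cumulative_mann_kendall",
    "wilcoxon_paired",
    "anova_group_effect",
    "ols_trend",
    "mid_p_fisher",
    "fisher_exact_2x2",
    "chi_square_2x2",
    "mantel_haenszel",
    "benjamini_yekutieli",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendResult:
    """Outcome of a (cumulative) Mann-Kendall trend test.

    ``S`` is the sum of concordance signs, ``var_S`` its tie-corrected
    variance, ``Z`` the continuity-corrected normal deviate and
    ``p_two_sided`` the two-sided normal p-value.
    """

    S: float
    var_S: float
    Z: float
    p_two_sided: float
    n_blocks: int
    n_obs_total: int
    degenerate: bool = False
    n_skipped: int = 0

    @property
    def p(self) -> float:
        return self.p_two_sided


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table: row 1 = adaptation (between-group, directional) counts,
    row 2 = background (within-group) counts; column 1 = the target
    outcome, column 2 = everything else."""

    a: float
    b: float
    c: float
    d: float
    row_labels: tuple = ("adaptation", "background")
    col_labels: tuple = ("y", "not_y")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class RegressionResult:
    beta0: float
    beta1: float
    strata_offsets: dict
    p_slope: float
    se_slope: float
    n: int
    baseline_stratum: Optional[str] = None


@dataclass(frozen=True)
class FisherResult:
    p: float
    not_testable: bool = False


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    p: float
    not_testable: bool = False


@dataclass(frozen=True)
class MHResult:
    chi2: float
    p: float
    common_or: float
    not_testable: bool = False


@dataclass(frozen=True)
class WilcoxonResult:
    p: float
    w_plus: float
    n_nonzero: int
    exact: bool
    small_n: bool = False
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Mann-Kendall
# ---------------------------------------------------------------------------


def _tie_sums(v: np.ndarray) -> Tuple[float, float, float]:
    """Return (sum t(t-1)(2t+5), sum t(t-1)(t-2), sum t(t-1)) over tie groups."""
    _, counts = np.unique(v, return_counts=True)
    t = counts[counts > 1].astype(float)
    return (
        float(np.sum(t * (t - 1) * (2 * t + 5))),
        float(np.sum(t * (t - 1) * (t - 2))),
        float(np.sum(t * (t - 1))),
    )


def _mk_s(x: np.ndarray, y: np.ndarray) -> int:
    dx = np.sign(x[:, None] - x[None, :])
    dy = np.sign(y[:, None] - y[None, :])
    iu = np.triu_indices(len(x), k=1)
    return int(np.sum(dx[iu] * dy[iu]))


def _mk_var(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected variance of S with ties in both x and y (the standard
    Kendall treatment, including the cross-product terms)."""
    n = len(x)
    tx1, tx2, tx3 = _tie_sums(x)
    ty1, ty2, ty3 = _tie_sums(y)
    v = (n * (n - 1) * (2 * n + 5) - tx1 - ty1) / 18.0
    if n > 2:
        v += tx2 * ty2 / (9.0 * n * (n - 1) * (n - 2))
    v += tx3 * ty3 / (2.0 * n * (n - 1))
    return max(v, 0.0)


def _mk_z_p(S: float, var_S: float) -> Tuple[float, float]:
    if var_S <= 0 or S == 0:
        return 0.0, 1.0
    z = (S - math.copysign(1.0, S)) / math.sqrt(var_S)
    return z, float(2.0 * sps.norm.sf(abs(z)))


def mann_kendall(x: Sequence[float], y: Sequence[float]) -> TrendResult:
    """Mann-Kendall trend test of ``y`` against the ordinal codes ``x``.

    S = sum over pairs i<j of sgn(x_j - x_i) * sgn(y_j - y_i); the
    variance is tie-corrected for ties in both variables (group codes
    guarantee heavy ties in x), and Z applies the continuity correction
    (S minus its sign).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Mann-Kendall needs at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("degenerate Mann-Kendall input (constant x or y)", stacklevel=2)
        return TrendResult(0, 0.0, 0.0, 1.0, 1, n, degenerate=True)
    S = _mk_s(x, y)
    var_S = _mk_var(x, y)
    z, p = _mk_z_p(S, var_S)
    return TrendResult(S, var_S, z, p, 1, n)


def cumulative_mann_kendall(blocks: Iterable[Tuple[Sequence, Sequence]]) -> TrendResult:
    """Blocked (cumulative) Mann-Kendall test over many alignments.

    Each block contributes its own S and tie-corrected variance; the
    totals are summed and a single continuity-corrected Z is formed —
    the seasonal-Kendall construction.  Blocks that are degenerate
    (constant x or y) or too small are skipped with a warning.
    """
    S_tot = 0.0
    var_tot = 0.0
    n_obs = 0
    n_blocks = 0
    n_skipped = 0
    for x, y in blocks:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if (
            len(x) < 3
            or len(x) != len(y)
            or np.all(x == x[0])
            or np.all(y == y[0])
        ):
            n_skipped += 1
            continue
        S_tot += _mk_s(x, y)
        var_tot += _mk_var(x, y)
        n_obs += len(x)
        n_blocks += 1
    if n_skipped:
        warnings.warn(
            f"{n_skipped} block(s) skipped in cumulative Mann-Kendall",
            stacklevel=2,
        )
    if n_blocks == 0:
        raise ValueError("no block contributes to the cumulative Mann-Kendall test")
    z, p = _mk_z_p(S_tot, var_tot)
    return TrendResult(
        S_tot, var_tot, z, p, n_blocks, n_obs, n_skipped=n_skipped
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _wilcoxon_exact_p(d: np.ndarray) -> Tuple[float, float]:
    """Exact two-sided signed-rank p (no tied magnitudes, no zeros)."""
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    # distribution of W+ over all 2^n sign assignments, by convolution
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    total = counts.sum()
    w = int(round(w_plus))
    p_low = counts[: w + 1].sum() / total
    p_high = counts[w:].sum() / total
    return min(1.0, 2.0 * min(p_low, p_high)), w_plus


def wilcoxon_paired(deltas: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped (Wilcoxon's convention).  The exact distribution is
    used for n <= 25 when magnitudes are untied; otherwise the normal
    approximation with tie correction.  Fewer than 5 nonzero deltas set
    the ``small_n`` flag.
    """
    d = np.asarray(deltas, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, exact=True, degenerate=True)
    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 25 and not has_ties:
        p, w_plus = _wilcoxon_exact_p(d)
        return WilcoxonResult(p, w_plus, n, exact=True, small_n=n < 5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
    return WilcoxonResult(float(res.pvalue), float(res.statistic), n, exact=False,
                          small_n=n < 5)


# ---------------------------------------------------------------------------
# ANOVA and regression
# ---------------------------------------------------------------------------


def anova_group_effect(
    y: Sequence[float],
    group: Sequence,
    stratum: Optional[Sequence] = None,
) -> Tuple[float, float]:
    """F test of a 2-level group effect on ``y``.

    Without ``stratum``: one-way ANOVA.  With ``stratum``: additive
    two-way ANOVA (no interaction), Type II sums of squares; the returned
    F and p are for the group effect.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    levels, counts = np.unique(group, return_counts=True)
    if len(levels) != 2:
        raise ValueError(
            f"ANOVA requires exactly 2 groups, got {len(levels)}; use "
            f"regression or cumulative Mann-Kendall for more groups"
        )
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 observations")
    if stratum is None:
        g0 = y[group == levels[0]]
        g1 = y[group == levels[1]]
        if np.isclose(g0.mean(), g1.mean()) and np.allclose(
            np.concatenate([g0, g1]).var(), 0.0
        ):
            return 0.0, 1.0
        F, p = sps.f_oneway(g0, g1)
        if not np.isfinite(F):  # zero within-group variance
            return (0.0, 1.0) if np.isclose(g0.mean(), g1.mean()) else (np.inf, 0.0)
        return float(F), float(p)
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame(
        {"y": y, "g": pd.Categorical(group), "s": pd.Categorical(np.asarray(stratum))}
    )
    fit = smf.ols("y ~ C(g) + C(s)", data=df).fit()
    tab = anova_lm(fit, typ=2)
    F = float(tab.loc["C(g)", "F"])
    p = float(tab.loc["C(g)", "PR(>F)"])
    if not np.isfinite(F):
        return 0.0, 1.0
    return F, p


def ols_trend(
    y: Sequence[float],
    x: Sequence[float],
    strata: Optional[Sequence] = None,
) -> RegressionResult:
    """Least-squares fit of the parallelism model.

    Y = b0 + b1*X (+ stratum-specific intercept offsets).  The baseline
    stratum is the lexicographically first label; ``p_slope`` comes from
    the t statistic of b1.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("x needs at least 2 distinct values")
    cols = {"const": np.ones_like(x), "x": x}
    baseline = None
    labels: list = []
    if strata is not None:
        strata = np.asarray([str(s) for s in strata])
        labels = sorted(np.unique(strata))
        if len(labels) > 1:
            baseline = labels[0]
            for lab in labels[1:]:
                cols[f"stratum[{lab}]"] = (strata == lab).astype(float)
    exog = pd.DataFrame(cols)
    n, k = exog.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} observations for {k} parameters")
    if np.linalg.matrix_rank(exog.to_numpy()) < k:
        bad = []
        if strata is not None:
            for lab in labels:
                xs = x[strata == lab]
                if len(xs) and np.all(xs == xs[0]):
                    bad.append(lab)
        raise ValueError(
            "rank-deficient design"
            + (f": x is constant within stratum/strata {bad}" if bad else "")
        )
    fit = sm.OLS(y, exog).fit()
    offsets = {
        lab: float(fit.params[f"stratum[{lab}]"])
        for lab in labels[1:]
    } if baseline is not None else {}
    return RegressionResult(
        beta0=float(fit.params["const"]),
        beta1=float(fit.params["x"]),
        strata_offsets=offsets,
        p_slope=float(fit.pvalues["x"]),
        se_slope=float(fit.bse["x"]),
        n=int(n),
        baseline_stratum=baseline,
    )


# ---------------------------------------------------------------------------
# 2x2 tables
# ---------------------------------------------------------------------------

_TIE_RTOL = 1e-7


def _hypergeom_profile(t: ContingencyTable2x2):
    """Support and pmf of the cell-a count under fixed margins."""
    a, b, c, d = (int(round(v)) for v in (t.a, t.b, t.c, t.d))
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    return a, support, pmf


def _midp_parts(t: ContingencyTable2x2, alternative: str):
    a, support, pmf = _hypergeom_profile(t)
    p_obs = float(pmf[support == a][0])
    if alternative == "greater":
        less = float(pmf[support > a].sum())
        tied = p_obs
    elif alternative == "less":
        less = float(pmf[support < a].sum())
        tied = p_obs
    elif alternative == "two_sided":
        ratio = pmf / p_obs if p_obs > 0 else np.full_like(pmf, np.inf)
        tied_mask = np.abs(ratio - 1.0) <= _TIE_RTOL
        less_mask = (~tied_mask) & (ratio < 1.0)
        less = float(pmf[less_mask].sum())
        tied = float(pmf[tied_mask].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return less, tied


def mid_p_fisher(
    t: ContingencyTable2x2, alternative: str = "two_sided"
) -> FisherResult:
    """Fisher exact test with the mid-p adjustment for discreteness.

    The hypergeometric null with fixed margins is enumerated; the
    two-sided p sums tables strictly less probable than the observed one
    plus *half* the probability of tables tied with it (probability
    ordering, ties detected at relative tolerance 1e-7).  This is less
    conservative than the conventional exact test while keeping the
    error probability close to nominal.
    """
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        return FisherResult(1.0, not_testable=True)
    less, tied = _midp_parts(t, alternative)
    return FisherResult(min(1.0, less + 0.5 * tied))


def fisher_exact_2x2(
    t: ContingencyTable2x2, alternative: str = "two_sided"
) -> FisherResult:
    """Conventional Fisher exact p under the same probability ordering
    (the mid-p equals this minus half the tied probability mass)."""
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        return FisherResult(1.0, not_testable=True)
    less, tied = _midp_parts(t, alternative)
    return FisherResult(min(1.0, less + tied))


def chi_square_2x2(t: ContingencyTable2x2) -> Chi2Result:
    """Pearson chi-square (1 df, no continuity correction) on a 2x2 table;
    the large-count alternative to the exact test."""
    arr = t.as_array()
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = arr.sum()
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return Chi2Result(0.0, 1.0, not_testable=True)
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return Chi2Result(float(chi2), float(p))


def mantel_haenszel(tables: Sequence[ContingencyTable2x2]) -> MHResult:
    """Mantel-Haenszel stratified 2x2 test.

    Returns the continuity-corrected MH chi-square (1 df), its p-value,
    and the MH common odds-ratio estimator
    sum_k(a_k d_k / n_k) / sum_k(b_k c_k / n_k).
    """
    arrs = [t.as_array() for t in tables if t.n > 0]
    if not arrs:
        return MHResult(0.0, 1.0, np.nan, not_testable=True)
    num = sum(a[0, 0] * a[1, 1] / a.sum() for a in arrs)
    den = sum(a[0, 1] * a[1, 0] / a.sum() for a in arrs)
    common_or = num / den if den > 0 else np.inf
    try:
        st = StratifiedTable(np.stack(arrs, axis=-1))
        res = st.test_null_odds(correction=True)
        chi2, p = float(res.statistic), float(res.pvalue)
    except Exception:
        return MHResult(0.0, 1.0, common_or, not_testable=True)
    if not np.isfinite(chi2):
        return MHResult(0.0, 1.0, common_or, not_testable=True)
    return MHResult(chi2, p, common_or)


# ---------------------------------------------------------------------------
# False discovery rate
# ---------------------------------------------------------------------------


def benjamini_yekutieli(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up FDR adjustment.

    Valid under arbitrary dependence via the harmonic-number inflation
    c(m) = sum_{k=1..m} 1/k.  NaN inputs are excluded from m and
    propagated; output order matches input order.
    """
    p = np.asarray(pvals, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.sum() == 0:
        return out
    out[finite] = multipletests(p[finite], method="fdr_by")[1]
    return out
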