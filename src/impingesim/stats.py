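"""Cohort statistics: regression with prediction intervals, rank tests,
reliability coefficients, and a-priori power analysis.

The regression layer relates per-region osteophyte widths to the
pre-operative range of motion (ordinary least squares with t-based 95%
prediction intervals for a single new case, the quantity a surgeon would
consult for one patient).  Rank tests compare widths between regions;
intraclass correlations quantify rater reliability of the width
measurements; the power routines reproduce a-priori sample-size
calculations for the two-sample Mann-Whitney test (asymptotic relative
efficiency adjustment of the noncentral-t calculation, normal parent) and
one-way fixed-effects ANOVA (noncentral F).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: ARE of the Mann-Whitney test vs the t test for a normal parent
ARE_NORMAL = 3.0 / math.pi
#: total sample size at or below which rank-test p-values are enumerated exactly
EXACT_ENUMERATION_N = 10


# ---------------------------------------------------------------------------
# regression and prediction intervals


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of width (mm) on angle (deg) with PI machinery."""

    slope: float
    intercept: float
    r: float
    p_value: float
    n: int
    residual_sd: float
    x_mean: float
    sxx: float

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r out of range")
        if self.n < 3:
            raise ValueError("need n >= 3")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.slope * self.r < 0 and abs(self.r) > 1e-12:
            raise ValueError("slope and r must share a sign")

    def predict(self, x0) -> np.ndarray | float:
        return self.slope * np.asarray(x0, float) + self.intercept


def pearson_regression(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with Pearson r and two-sided p.

    The p-value is from the t distribution with n - 2 degrees of freedom;
    the fitted line passes through the centroid (x-bar, y-bar) exactly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    if np.ptp(y) == 0:
        raise ValueError("y is constant")
    res = sps.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    residual_sd = float(np.sqrt((resid @ resid) / (n - 2)))
    sxx = float(((x - x.mean()) ** 2).sum())
    return RegressionResult(float(res.slope), float(res.intercept),
                            float(res.rvalue), float(res.pvalue), n,
                            residual_sd, float(x.mean()), sxx)


def prediction_interval(regr: RegressionResult, x0: float, level: float = 0.95) -> tuple:
    """t-based level prediction interval for one new observation at x0.

    half-width = t_{n-2,(1+level)/2} * s * sqrt(1 + 1/n + (x0 - x_mean)^2 / Sxx);
    minimized at x0 = x_mean.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if regr.n <= 2:
        raise ValueError("prediction interval needs n > 2")
    tcrit = sps.t.ppf(0.5 + level / 2.0, regr.n - 2)
    yhat = regr.predict(x0)
    half = tcrit * regr.residual_sd * math.sqrt(
        1.0 + 1.0 / regr.n + (x0 - regr.x_mean) ** 2 / regr.sxx)
    return (yhat - half, yhat + half)


def pi_coverage_sim(n: int = 92, level: float = 0.95, reps: int = 10_000,
                    seed: int = 0, noise: str = "normal") -> dict:
    """Empirical coverage of the one-new-observation prediction interval.

    Each replicate draws a linear-Gaussian data set, fits OLS, builds the
    level-PI at a random new x and checks whether a new observation falls
    inside.  Returns the inclusion fraction and its Monte-Carlo SE.
    `noise='t3'` swaps in heavy-tailed residuals to show the degradation
    under misspecification.
    """
    if reps < 1000:
        raise ValueError("need reps >= 1000 for a stable estimate")
    rng = np.random.default_rng(seed)
    a, b, sigma = -0.16, 2.52, 2.9   # any fixed linear model works
    x = rng.uniform(-45.0, -5.0, size=(reps, n))
    if noise == "normal":
        eps = rng.normal(0.0, sigma, size=(reps, n + 1))
    elif noise == "t3":
        eps = sigma * rng.standard_t(3, size=(reps, n + 1))
    else:
        raise ValueError("noise must be 'normal' or 't3'")
    y = a * x + b + eps[:, :n]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    slope = ((x - xm) * (y - ym)).sum(axis=1) / sxx
    intercept = ym[:, 0] - slope * xm[:, 0]
    resid = y - (slope[:, None] * x + intercept[:, None])
    s2 = (resid**2).sum(axis=1) / (n - 2)
    x_new = rng.uniform(-45.0, -5.0, size=reps)
    y_new = a * x_new + b + eps[:, n]
    tcrit = sps.t.ppf(0.5 + level / 2.0, n - 2)
    half = tcrit * np.sqrt(s2 * (1.0 + 1.0 / n + (x_new - xm[:, 0]) ** 2 / sxx))
    yhat = slope * x_new + intercept
    covered = np.abs(y_new - yhat) <= half
    frac = float(covered.mean())
    se = math.sqrt(frac * (1.0 - frac) / reps)
    return {"coverage": frac, "mc_se": se, "level": level, "n": n, "reps": reps}


# ---------------------------------------------------------------------------
# rank tests


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple
    exact: bool

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _mann_whitney_u(x, y) -> float:
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _mw_exact_p(x, y) -> float:
    """Two-sided exact p by enumerating all group assignments (mid-ranks)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = _midranks(pooled)
    u_obs = _mann_whitney_u(x, y)
    mean_u = n1 * len(y) / 2.0
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        r1 = ranks[list(comb)].sum()
        us.append(r1 - n1 * (n1 + 1) / 2.0)
    us = np.asarray(us)
    lo = float(np.mean(us <= u_obs))
    hi = float(np.mean(us >= u_obs))
    if math.isclose(u_obs, mean_u):
        return 1.0
    return min(1.0, 2.0 * min(lo, hi))


def _kruskal_h(groups) -> float:
    pooled = np.concatenate(groups)
    ranks = _midranks(pooled)
    n = len(pooled)
    h = 0.0
    i = 0
    for g in groups:
        r = ranks[i:i + len(g)]
        h += r.sum() ** 2 / len(g)
        i += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie if tie > 0 else 0.0


def _kw_exact_p(groups) -> float:
    """Exact p for Kruskal-Wallis by enumerating group assignments."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    h_obs = _kruskal_h(groups)
    idx = list(range(len(pooled)))
    count = 0
    total = 0
    for assignment in _assignments(idx, sizes):
        gs = [pooled[list(a)] for a in assignment]
        total += 1
        if _kruskal_h(gs) >= h_obs - 1e-12:
            count += 1
    return count / total


def _assignments(idx, sizes):
    if len(sizes) == 1:
        yield (tuple(idx),)
        return
    for first in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in first]
        for tail in _assignments(rest, sizes[1:]):
            yield (first,) + tail


def _friedman_chi2(matrix: np.ndarray) -> float:
    n, k = matrix.shape
    ranks = np.apply_along_axis(_midranks, 1, matrix)
    rj = ranks.sum(axis=0)
    return float(12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3 * n * (k + 1))


def _friedman_exact_p(matrix: np.ndarray) -> float:
    n, k = matrix.shape
    chi_obs = _friedman_chi2(matrix)
    perms = list(itertools.permutations(range(k)))
    count = 0
    total = 0
    for combo in itertools.product(perms, repeat=n):
        m = np.vstack([matrix[i, list(combo[i])] for i in range(n)])
        total += 1
        if _friedman_chi2(m) >= chi_obs - 1e-12:
            count += 1
    return count / total


def rank_test(groups, method: str, paired_matrix=None) -> RankTestResult:
    """Rank-based group comparison with mid-rank ties.

    For total n <= 10 observations the p-value is computed by exact
    enumeration of group assignments (Friedman: of within-block orderings);
    above that the normal / chi-square approximation is used, and the
    choice is recorded in the result.
    """
    if method == "friedman":
        m = np.asarray(paired_matrix if paired_matrix is not None else groups, float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise ValueError("friedman requires an n x k matrix with k >= 2")
        n, k = m.shape
        chi = _friedman_chi2(m)
        exact = n * k <= EXACT_ENUMERATION_N
        if exact:
            p = _friedman_exact_p(m)
        else:
            p = float(sps.chi2.sf(chi, k - 1))
        return RankTestResult(chi, p, "friedman", (n,) * k, exact)

    groups = [np.asarray(g, float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    total = sum(len(g) for g in groups)
    if method == "mann_whitney":
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly 2 groups")
        x, y = groups
        u = _mann_whitney_u(x, y)
        exact = total <= EXACT_ENUMERATION_N
        if exact:
            p = _mw_exact_p(x, y)
        else:
            p = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic").pvalue)
        return RankTestResult(u, p, "mann_whitney", (len(x), len(y)), exact)
    if method == "kruskal_wallis":
        if len(groups) < 2:
            raise ValueError("kruskal_wallis requires >= 2 groups")
        h = _kruskal_h(groups)
        exact = total <= EXACT_ENUMERATION_N
        if exact:
            p = _kw_exact_p(groups)
        else:
            p = float(sps.chi2.sf(h, len(groups) - 1))
        return RankTestResult(h, p, "kruskal_wallis",
                              tuple(len(g) for g in groups), exact)
    raise ValueError("method must be mann_whitney, kruskal_wallis or friedman")


# ---------------------------------------------------------------------------
# intraclass correlation


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    n_targets: int
    k_raters: int

    def __post_init__(self):
        if not (self.ci_low <= self.icc <= self.ci_high and self.icc <= 1.0):
            raise ValueError("inconsistent ICC confidence bounds")


def icc(ratings, model: str, alpha: float = 0.05) -> ICCResult:
    """Single-measure intraclass correlation.

    `model='two_way_random_absolute_single'` is ICC(2,1): two-way random
    effects, absolute agreement; `model='one_way_random_single'` is
    ICC(1,1).  Confidence limits follow the F-based formulas of the
    McGraw-Wong / Shrout-Fleiss ANOVA framework.
    """
    m = np.asarray(ratings, float)
    if m.ndim != 2:
        raise ValueError("ratings must be an n_targets x k_raters matrix")
    if np.isnan(m).any():
        raise ValueError("ratings matrix must be complete")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need n_targets >= 5 and k_raters >= 2")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    msr = ss_rows / (n - 1)

    if model == "one_way_random_single":
        ss_within = ss_total - ss_rows
        msw = ss_within / (n * (k - 1))
        val = (msr - msw) / (msr + (k - 1) * msw) if msr + (k - 1) * msw > 0 else 0.0
        fobs = msr / msw if msw > 0 else np.inf
        df1, df2 = n - 1, n * (k - 1)
        fl = fobs / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = fobs * sps.f.ppf(1 - alpha / 2, df2, df1)
        lo = (fl - 1) / (fl + k - 1)
        hi = (fu - 1) / (fu + k - 1)
    elif model == "two_way_random_absolute_single":
        ss_err = ss_total - ss_rows - ss_cols
        msc = ss_cols / (k - 1)
        mse = ss_err / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        val = (msr - mse) / denom if denom > 0 else 0.0
        if mse > 0 and val < 1:
            # Satterthwaite df for the absolute-agreement CI (McGraw-Wong 2A)
            a = k * val / (n * (1 - val))
            b = 1 + k * val * (n - 1) / (n * (1 - val))
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_lo * mse) / (
                f_lo * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_hi * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_hi * msr)
        else:
            lo = hi = val
    else:
        raise ValueError("model must be 'two_way_random_absolute_single' or "
                         "'one_way_random_single'")
    val = min(float(val), 1.0)
    lo = float(min(lo, val))
    hi = float(max(hi, val)) if hi is not None else 1.0
    return ICCResult(val, lo, min(hi, 1.0), model, n, k)


# ---------------------------------------------------------------------------
# a-priori power analysis


@dataclass(frozen=True)
class PowerSpec:
    test: str                  # 'mann_whitney' or 'one_way_anova'
    effect_size: float         # Cohen d (mann_whitney) or f (anova)
    alpha: float = 0.05
    power: float = 0.80
    k_groups: int = 2

    def __post_init__(self):
        if self.test not in ("mann_whitney", "one_way_anova"):
            raise ValueError("test must be 'mann_whitney' or 'one_way_anova'")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.k_groups < 2:
            raise ValueError("k_groups must be >= 2")


def mann_whitney_power(n_per_group: int, d: float, alpha: float = 0.05,
                       are: float = ARE_NORMAL) -> float:
    """Two-sided Mann-Whitney power by the ARE-adjusted noncentral-t method.

    The two-sample t-test power calculation is evaluated with the degrees
    of freedom and noncentrality scaled by the asymptotic relative
    efficiency of the rank test (3/pi for a normal parent).
    """
    if n_per_group < 2:
        return 0.0
    df = are * (2 * n_per_group - 2)
    ncp = d * math.sqrt(are * n_per_group / 2.0)
    crit = sps.t.isf(alpha / 2.0, df)
    return float(sps.nct.sf(crit, df, ncp) + sps.nct.cdf(-crit, df, ncp))


def anova_power(n_total: int, f: float, k_groups: int, alpha: float = 0.05) -> float:
    """One-way fixed-effects ANOVA power from the noncentral F distribution
    with noncentrality lambda = f^2 * N."""
    df2 = n_total - k_groups
    if df2 < 1:
        return 0.0
    lam = f * f * n_total
    crit = sps.f.isf(alpha, k_groups - 1, df2)
    return float(sps.ncf.sf(crit, k_groups - 1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 100_000) -> int:
    """Smallest sample size achieving the requested power.

    Returns participants per group for the Mann-Whitney test and the total
    (equal groups, so a multiple of k) for one-way ANOVA.
    """
    if spec.test == "mann_whitney":
        for n in range(2, n_max):
            if mann_whitney_power(n, spec.effect_size, spec.alpha) >= spec.power:
                return n
    else:
        for n in range(2, n_max):
            total = n * spec.k_groups
            if anova_power(total, spec.effect_size, spec.k_groups,
                           spec.alpha) >= spec.power:
                return total
    raise RuntimeError("sample-size search did not terminate")
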