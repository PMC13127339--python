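import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from impingesim.stats import (PowerSpec, anova_power, icc, mann_whitney_power,
                              pearson_regression, pi_coverage_sim,
                              prediction_interval, rank_test,
                              required_sample_size)


# --------------------------------------------------------------- regression

@pytest.mark.parametrize("x,y,slope,intercept,r", [
    ((1, 2, 3), (2, 4, 6), 2.0, 0.0, 1.0),
    ((0, 1, 2), (1, 1, 4), 1.5, 0.5, math.sqrt(3) / 2),
])
def test_pearson_regression_hand_computed(x, y, slope, intercept, r):
    fit = pearson_regression(x, y)
    assert fit.slope == pytest.approx(slope, abs=1e-9)
    assert fit.intercept == pytest.approx(intercept, abs=1e-9)
    assert fit.r == pytest.approx(r, abs=1e-9)
    # the line passes through the centroid exactly
    assert fit.predict(np.mean(x)) == pytest.approx(np.mean(y), abs=1e-12)


def test_pearson_regression_rejects_constant_input():
    with pytest.raises(ValueError, match="constant"):
        pearson_regression((1, 1, 1), (1, 2, 3))
    with pytest.raises(ValueError, match="constant"):
        pearson_regression((1, 2, 3), (5, 5, 5))


def test_r_squared_identity(rng):
    x = rng.normal(0, 3, 50)
    y = 1.3 * x + rng.normal(0, 2, 50)
    fit = pearson_regression(x, y)
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    syy = ((y - y.mean()) ** 2).sum()
    assert fit.r**2 == pytest.approx(fit.slope * sxy / syy, abs=1e-9)


def test_prediction_interval_matches_statsmodels():
    """Independent oracle: statsmodels' one-observation PI on a toy set."""
    import statsmodels.api as sm

    x = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
    y = np.array([2.1, 2.9, 4.2, 5.4, 6.6])
    fit = pearson_regression(x, y)
    for x0 in (0.0, 3.0, 8.0):
        lo, hi = prediction_interval(fit, x0, 0.95)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        frame = ols.get_prediction([1.0, x0]).summary_frame(alpha=0.05)
        assert lo == pytest.approx(frame["obs_ci_lower"].iloc[0], abs=1e-9)
        assert hi == pytest.approx(frame["obs_ci_upper"].iloc[0], abs=1e-9)


def test_prediction_interval_width_minimized_at_x_mean():
    x = np.arange(10.0)
    y = 0.5 * x + np.sin(x)
    fit = pearson_regression(x, y)
    widths = [np.diff(prediction_interval(fit, x0, 0.95))[0]
              for x0 in (0.0, fit.x_mean, 9.0)]
    assert widths[1] < widths[0] and widths[1] < widths[2]


def test_prediction_interval_collapses_as_level_shrinks():
    fit = pearson_regression((0, 1, 2, 3), (0.1, 1.0, 2.1, 2.9))
    lo, hi = prediction_interval(fit, 1.5, 1e-12)
    assert hi - lo == pytest.approx(0.0, abs=1e-6)


def test_pi_coverage_at_half_level(rng):
    out = pi_coverage_sim(n=30, level=0.5, reps=2000, seed=1)
    assert out["coverage"] == pytest.approx(0.5, abs=4 * out["mc_se"] + 0.01)


def test_pi_coverage_degrades_under_heavy_tails():
    normal = pi_coverage_sim(n=92, level=0.95, reps=4000, seed=2)
    heavy = pi_coverage_sim(n=92, level=0.95, reps=4000, seed=2, noise="t3")
    assert heavy["coverage"] < normal["coverage"]


# --------------------------------------------------------------- rank tests

def test_mann_whitney_exact_small_sample():
    res = rank_test([(1.0, 2.0), (3.0, 4.0)], "mann_whitney")
    assert res.exact
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1 / 3, abs=1e-12)


def test_identical_groups_give_p_one():
    res = rank_test([(1.0, 2.0, 3.0), (1.0, 2.0, 3.0)], "mann_whitney")
    assert res.p_value == 1.0


def test_mann_whitney_exact_matches_scipy_without_ties(rng):
    x = rng.normal(0, 1, 5)
    y = rng.normal(0.8, 1, 4)
    mine = rank_test([x, y], "mann_whitney")
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    assert mine.exact
    assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_kruskal_exact_matches_brute_force_enumeration():
    groups = [np.array([1.0, 5.0, 8.0]), np.array([2.0, 7.0]),
              np.array([3.0, 4.0, 9.0])]
    res = rank_test(groups, "kruskal_wallis")
    assert res.exact

    # independent brute force over all distinct label assignments
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def h_stat(gs):
        return sps.kruskal(*gs).statistic

    h_obs = h_stat(groups)
    count = total = 0
    idx = range(len(pooled))
    for first in itertools.combinations(idx, sizes[0]):
        rest = [i for i in idx if i not in first]
        for second in itertools.combinations(rest, sizes[1]):
            third = [i for i in rest if i not in second]
            gs = [pooled[list(first)], pooled[list(second)], pooled[third]]
            total += 1
            if h_stat(gs) >= h_obs - 1e-12:
                count += 1
    assert res.p_value == pytest.approx(count / total, abs=1e-9)


def test_friedman_exact_and_approximate_agree_on_strong_effect():
    m = np.array([[1.0, 2.0, 3.0], [1.1, 2.1, 3.1], [0.9, 2.2, 3.3]])
    exact = rank_test(None, "friedman", paired_matrix=m)
    assert exact.exact
    big = np.tile(m, (5, 1))
    approx = rank_test(None, "friedman", paired_matrix=big)
    assert not approx.exact
    assert approx.p_value < 0.01


def test_rank_test_rejects_empty_group():
    with pytest.raises(ValueError, match="non-empty"):
        rank_test([[1.0], []], "mann_whitney")


def test_exact_and_asymptotic_p_close_at_enumeration_boundary(rng):
    x = rng.normal(0, 1, 5)
    y = rng.normal(0.5, 1, 5)
    exact = rank_test([x, y], "mann_whitney").p_value
    approx = float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic").pvalue)
    assert abs(exact - approx) < 0.05


# ---------------------------------------------------------------------- ICC

def test_icc_perfect_agreement_is_one(rng):
    a = rng.normal(5, 2, 10)
    m = np.column_stack([a, a])
    for model in ("two_way_random_absolute_single", "one_way_random_single"):
        assert icc(m, model).icc == pytest.approx(1.0, abs=1e-9)


def test_icc_absolute_agreement_penalizes_constant_shift(rng):
    a = rng.normal(5, 2, 20)
    m = np.column_stack([a, a + 1.0])
    assert icc(m, "two_way_random_absolute_single").icc < 1.0


def test_icc_invariant_under_common_shift(rng):
    m = rng.normal(5, 2, (12, 3)) + rng.normal(0, 0.4, (12, 1))
    for model in ("two_way_random_absolute_single", "one_way_random_single"):
        a = icc(m, model)
        b = icc(m + 7.5, model)
        assert a.icc == pytest.approx(b.icc, abs=1e-12)


def test_icc_matches_pingouin_oracle(rng):
    import pandas as pd
    import pingouin as pg

    n, k = 40, 2
    m = rng.normal(5, 2, n)[:, None] + rng.normal(0, 0.3, (n, k))
    df = pd.DataFrame({"targets": np.repeat(np.arange(n), k),
                       "raters": np.tile(np.arange(k), n),
                       "scores": m.ravel()})
    ref = pg.intraclass_corr(df, "targets", "raters", "scores").set_index("Type")
    mine21 = icc(m, "two_way_random_absolute_single")
    mine11 = icc(m, "one_way_random_single")
    assert mine21.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-9)
    assert mine11.icc == pytest.approx(ref.loc["ICC(1,1)", "ICC"], abs=1e-9)
    lo, hi = ref.loc["ICC(A,1)", "CI95"]
    assert mine21.ci_low == pytest.approx(lo, abs=0.01)
    assert mine21.ci_high == pytest.approx(hi, abs=0.01)


def test_icc_requires_complete_matrix():
    m = np.ones((6, 2))
    m[0, 0] = np.nan
    with pytest.raises(ValueError, match="complete"):
        icc(m, "one_way_random_single")


# -------------------------------------------------------------------- power

def test_required_n_monotone_in_effect_and_power():
    base = required_sample_size(PowerSpec("mann_whitney", 1.56))
    bigger_effect = required_sample_size(PowerSpec("mann_whitney", 3.12))
    more_power = required_sample_size(PowerSpec("mann_whitney", 1.56, power=0.95))
    assert bigger_effect < base <= more_power


def test_power_functions_increase_with_n():
    p = [mann_whitney_power(n, 1.0) for n in (5, 10, 20)]
    assert p[0] < p[1] < p[2]
    q = [anova_power(n, 0.25, 3) for n in (30, 90, 240)]
    assert q[0] < q[1] < q[2]


def test_power_spec_validation():
    with pytest.raises(ValueError, match="effect_size"):
        PowerSpec("mann_whitney", 0.0)
    with pytest.raises(ValueError, match="test"):
        PowerSpec("wilcoxon", 1.0)
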