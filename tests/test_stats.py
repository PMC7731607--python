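"""Statistical kernel against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as spstats

from vbacscore import (ConvergenceError, SeparationError, auc_bootstrap_ci,
                       chi_square, fit_logistic, roc_auc, two_sample_t)


# --- logistic regression -----------------------------------------------------

def test_symmetric_data_forces_null_fit():
    x = np.array([-1.0, -1.0, 1.0, 1.0])[:, None]
    y = np.array([0.0, 1.0, 0.0, 1.0])
    fit = fit_logistic(x, y)
    assert np.allclose(fit.coefficients, 0.0, atol=1e-8)
    assert fit.converged


def _grid_search_mle(x, y, half_width=4.0, rounds=4, grid=41):
    """Brute-force likelihood maximiser over (intercept, slope).

    Nested grid refinement; final resolution well below 1e-3.  Shares no
    code with the IRLS path.
    """
    def loglik(b0, b1):
        eta = b0 + b1 * x
        return np.sum(y * eta - np.log1p(np.exp(eta)))

    c0, c1, w = 0.0, 0.0, half_width
    for _ in range(rounds):
        b0s = np.linspace(c0 - w, c0 + w, grid)
        b1s = np.linspace(c1 - w, c1 + w, grid)
        ll = np.array([[loglik(b0, b1) for b1 in b1s] for b0 in b0s])
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        c0, c1 = b0s[i], b1s[j]
        w = 2.0 * w / (grid - 1)  # zoom in around the best cell
    return c0, c1


def test_logistic_mle_matches_grid_search_oracle():
    x = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 3.0])
    y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
    fit = fit_logistic(x[:, None], y)
    b0, b1 = _grid_search_mle(x, y)
    assert fit.coefficients[0] == pytest.approx(b0, abs=1e-3)
    assert fit.coefficients[1] == pytest.approx(b1, abs=1e-3)


def test_logistic_matches_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.api")
    n = 500
    X = rng.normal(size=(n, 3))
    eta = 0.4 + X @ np.array([0.8, -0.5, 0.0])
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y, names=["a", "b", "c"])
    ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, rtol=1e-5)
    np.testing.assert_allclose(fit.wald_p_values, ref.pvalues, atol=1e-6)


def test_parameter_recovery_on_simulated_data(rng):
    """Known generating coefficients are recovered within 3 Wald SE."""
    n = 50_000
    truth = np.array([0.5, 0.7, -0.2])
    X = np.column_stack([rng.normal(0, 1.2, n), rng.normal(0, 4, n)])
    eta = truth[0] + X @ truth[1:]
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y, names=["ga", "bmi"])
    for est, se, tr in zip(fit.coefficients, fit.standard_errors, truth):
        assert abs(est - tr) < 3 * se


def test_perfect_separation_names_covariate():
    X = np.column_stack([np.array([1.0, 2.0, 3.0, 4.0]),
                         np.array([0.3, 0.1, 0.4, 0.2])])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    with pytest.raises(SeparationError, match="x0"):
        fit_logistic(X, y)


def test_logistic_input_contracts():
    with pytest.raises(ValueError, match="single class"):
        fit_logistic(np.array([[1.0], [2.0]]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="collinear"):
        fit_logistic(np.column_stack([np.array([0.2, 0.9, 0.8, 0.1]),
                                      np.ones(4)]),
                     np.array([0.0, 1.0, 0.0, 1.0]), names=["x", "const"])


def test_odds_ratio_accessors():
    x = np.array([0.0, 1.0, 1.0, 2.0, 3.0, 3.0])[:, None]
    y = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
    fit = fit_logistic(x, y, names=["score"])
    assert fit.odds_ratio("score") == pytest.approx(np.exp(fit.coef("score")))
    lo, hi = fit.or_conf_int[fit.names.index("score")]
    assert lo < fit.odds_ratio("score") < hi


# --- ROC / AUC ---------------------------------------------------------------

@pytest.mark.parametrize("scores,outcomes,expected", [
    ([1, 2, 3, 4], [0, 0, 1, 1], 1.0),
    ([5, 5, 5, 5], [0, 1, 0, 1], 0.5),
    ([1, 2, 2, 3], [0, 1, 0, 1], 0.875),
])
def test_auc_worked_examples(scores, outcomes, expected):
    assert roc_auc(scores, outcomes).auc == pytest.approx(expected)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def _trapezoid_auc(res):
    fpr = 1.0 - res.specificities
    return float(np.trapezoid(res.sensitivities, fpr))


@settings(max_examples=150, derandomize=True, database=None)
@given(st.lists(st.tuples(st.integers(0, 12), st.booleans()), min_size=4, max_size=60))
def test_trapezoid_integral_equals_mann_whitney(pairs):
    scores = np.array([s for s, _ in pairs], dtype=float)
    y = np.array([o for _, o in pairs], dtype=float)
    if y.min() == y.max():
        return
    res = roc_auc(scores, y)
    assert _trapezoid_auc(res) == pytest.approx(res.auc, abs=1e-12)


@settings(max_examples=100, derandomize=True, database=None)
@given(st.lists(st.tuples(st.integers(-500, 500), st.booleans()), min_size=4, max_size=40))
def test_auc_invariant_under_monotone_transform(pairs):
    scores = np.array([s for s, _ in pairs], dtype=float) / 10.0
    y = np.array([o for _, o in pairs], dtype=float)
    if y.min() == y.max():
        return
    base = roc_auc(scores, y).auc
    assert roc_auc(np.exp(scores / 25.0), y).auc == pytest.approx(base)
    assert roc_auc(3.0 * scores + 7.0, y).auc == pytest.approx(base)


def test_curve_endpoints_and_monotonicity(medium_cohort):
    y = (medium_cohort["outcome"] == "SUCCESS").astype(float)
    res = roc_auc(medium_cohort["total"], y)
    assert res.sensitivities[0] == 0.0 and res.specificities[0] == 1.0
    assert res.sensitivities[-1] == 1.0 and res.specificities[-1] == 0.0
    assert np.all(np.diff(res.sensitivities) >= 0)
    assert np.all(np.diff(res.specificities) <= 0)


def test_bootstrap_ci_perfect_separation_degenerates():
    scores = np.array([1, 2, 3, 10, 11, 12], dtype=float)
    y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
    assert auc_bootstrap_ci(scores, y, n_boot=300, seed=0) == (1.0, 1.0)


def test_bootstrap_ci_seeded_determinism(small_cohort):
    y = (small_cohort["outcome"] == "SUCCESS").astype(float)
    s = small_cohort["total"].to_numpy(float)
    a = auc_bootstrap_ci(s, y, n_boot=500, seed=11)
    b = auc_bootstrap_ci(s, y, n_boot=500, seed=11)
    assert a == b
    assert a != auc_bootstrap_ci(s, y, n_boot=500, seed=12)


def test_bootstrap_ci_width_stable_against_larger_resample_oracle(small_cohort):
    y = (small_cohort["outcome"] == "SUCCESS").astype(float)
    s = small_cohort["total"].to_numpy(float)
    lo, hi = auc_bootstrap_ci(s, y, n_boot=2000, seed=1)
    lo_ref, hi_ref = auc_bootstrap_ci(s, y, n_boot=10_000, seed=2)
    assert abs((hi - lo) - (hi_ref - lo_ref)) < 0.25 * (hi_ref - lo_ref)


def test_bootstrap_requires_enough_resamples(small_cohort):
    y = (small_cohort["outcome"] == "SUCCESS").astype(float)
    with pytest.raises(ValueError):
        auc_bootstrap_ci(small_cohort["total"], y, n_boot=50, seed=0)


# --- two-sample t ------------------------------------------------------------

def test_identical_groups_give_zero_centred_interval():
    res = two_sample_t(5.0, 1.0, 30, 5.0, 1.0, 30)
    assert res.mean_diff == 0.0
    assert res.ci_low == pytest.approx(-res.ci_high)
    assert res.p_value == pytest.approx(1.0)


def test_pooled_ci_reproduces_published_summary_comparison():
    """Mean admission score, successful (7.01±1.77, n=117) vs failed
    (5.03±1.82, n=33) TOLAC: pooled 95% CI upper bound prints as 2.67."""
    res = two_sample_t(7.01, 1.77, 117, 5.03, 1.82, 33)
    assert round(res.ci_high, 2) == 2.67
    assert round(res.ci_low, 2) == 1.29
    assert res.p_value < 0.001


def test_t_matches_scipy_from_stats():
    ours = two_sample_t(7.01, 1.77, 117, 5.03, 1.82, 33)
    ref = spstats.ttest_ind_from_stats(7.01, 1.77, 117, 5.03, 1.82, 33)
    assert ours.t_stat == pytest.approx(ref.statistic)
    assert ours.p_value == pytest.approx(ref.pvalue)
    welch = two_sample_t(7.01, 1.77, 117, 5.03, 1.82, 33, method="welch")
    ref_w = spstats.ttest_ind_from_stats(7.01, 1.77, 117, 5.03, 1.82, 33,
                                         equal_var=False)
    assert welch.t_stat == pytest.approx(ref_w.statistic)
    assert welch.p_value == pytest.approx(ref_w.pvalue)


def test_interval_always_contains_estimate(rng):
    for _ in range(20):
        m1, m2 = rng.normal(size=2) * 5
        s1, s2 = rng.uniform(0.5, 3, size=2)
        n1, n2 = rng.integers(2, 50, size=2)
        for method in ("pooled", "welch"):
            res = two_sample_t(m1, s1, int(n1), m2, s2, int(n2), method=method)
            assert res.ci_low < res.mean_diff < res.ci_high


def test_t_degenerate_inputs_rejected():
    with pytest.raises(ValueError):
        two_sample_t(1, 1, 1, 2, 1, 30)
    with pytest.raises(ValueError):
        two_sample_t(1, 0, 30, 2, 1, 30)


# --- chi-square --------------------------------------------------------------

def test_chi_square_homogeneous_table():
    res = chi_square([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_hand_computed_example():
    # all expected counts are 15; statistic = 4 * 5^2 / 15
    res = chi_square([[20, 10], [10, 20]])
    assert res.statistic == pytest.approx(20.0 / 3.0)
    assert res.df == 1


def test_chi_square_scales_with_counts(rng):
    table = rng.integers(5, 40, size=(3, 4))
    assert chi_square(2 * table).statistic == pytest.approx(
        2 * chi_square(table).statistic)


def test_chi_square_matches_scipy():
    table = [[20, 10, 5], [10, 20, 15]]
    res = chi_square(table)
    ref = spstats.chi2_contingency(table, correction=False)
    assert res.statistic == pytest.approx(ref.statistic)
    assert res.p_value == pytest.approx(ref.pvalue)
    assert res.df == ref.dof
    res_y = chi_square([[20, 10], [10, 20]], yates=True)
    ref_y = spstats.chi2_contingency([[20, 10], [10, 20]], correction=True)
    assert res_y.statistic == pytest.approx(ref_y.statistic)


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(ValueError):
        chi_square([[0, 0], [5, 10]])
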