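"""Unit and property tests for the moderated-statistics core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special
from scipy import stats as sps

from fedabund import stats

# ---------------------------------------------------------------- helpers


def full_mask(n, v, n_obs):
    struct = stats.DesignStructure(columns=tuple(f"c{i}" for i in range(v)), class_cols=(0, 1))
    return stats.DesignMask(
        active=np.ones((n, v), bool),
        reference=np.zeros(n, int),
        n_obs=np.full(n, n_obs),
        n_params=np.full(n, v),
    )


# ---------------------------------------------------------------- moments


def test_local_moments_intercept_only():
    y = np.array([[1.0, 2.0, 3.0]])
    X = np.ones((3, 1))
    xtx, xty = stats.local_moments(y, X)
    assert xtx[0, 0, 0] == 3.0
    assert xty[0, 0] == 6.0


def test_local_moments_two_class_one_hot():
    y = np.array([[1.0, 2.0, 10.0]])
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    xtx, xty = stats.local_moments(y, X)
    np.testing.assert_array_equal(xtx[0], np.diag([2.0, 1.0]))
    np.testing.assert_array_equal(xty[0], [3.0, 10.0])


def test_local_moments_all_missing_gives_zero_blocks():
    y = np.full((1, 3), np.nan)
    X = np.ones((3, 2))
    xtx, xty = stats.local_moments(y, X)
    assert not xtx.any() and not xty.any()


@given(st.integers(0, 10_000))
@settings(max_examples=20, deadline=None)
def test_moment_aggregation_invariant_to_repartition(seed):
    """Summed client blocks equal pooled moments for any sample split."""
    rng = np.random.default_rng(seed)
    m, v, n = 30, 3, 8
    X = rng.normal(size=(m, v))
    Y = rng.normal(size=(n, m))
    Y[rng.random(size=Y.shape) < 0.2] = np.nan
    cuts = sorted(rng.choice(np.arange(1, m), size=2, replace=False))
    parts = np.split(np.arange(m), cuts)
    xtx_p, xty_p = stats.local_moments(Y, X)
    xtx_s = sum(stats.local_moments(Y[:, idx], X[idx])[0] for idx in parts)
    xty_s = sum(stats.local_moments(Y[:, idx], X[idx])[1] for idx in parts)
    np.testing.assert_allclose(xtx_s, xtx_p, atol=1e-10)
    np.testing.assert_allclose(xty_s, xty_p, atol=1e-10)


# ---------------------------------------------------------------- solving


def test_two_group_solution_is_group_means():
    y = np.array([[1.0, 3.0, 10.0, 14.0]])
    X = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
    xtx, xty = stats.local_moments(y, X)
    beta, stdev, cov, sing = stats.solve_global_lm(xtx, xty, full_mask(1, 2, 4))
    np.testing.assert_allclose(beta[0], [2.0, 12.0])
    np.testing.assert_allclose(stdev[0], [1 / math.sqrt(2), 1 / math.sqrt(2)])
    assert not sing[0]


def test_random_system_matches_lstsq_oracle():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(50, 3))
    y = rng.normal(size=(4, 50))
    xtx, xty = stats.local_moments(y, X)
    beta, _, _, sing = stats.solve_global_lm(xtx, xty, full_mask(4, 3, 50))
    expected = np.linalg.lstsq(X, y.T, rcond=None)[0].T
    np.testing.assert_allclose(beta, expected, atol=1e-10)
    assert not sing.any()


def test_duplicated_column_flagged_singular():
    X = np.column_stack([np.ones(10), np.ones(10)])
    y = np.random.default_rng(0).normal(size=(1, 10))
    xtx, xty = stats.local_moments(y, X)
    _, _, _, sing = stats.solve_global_lm(xtx, xty, full_mask(1, 2, 10))
    assert sing[0]


def test_residual_sse_hand_cases():
    X = np.ones((2, 1))
    y = np.array([[1.0, 3.0]])
    beta = np.array([[2.0]])
    sse = stats.residual_sse(y, X, beta)
    np.testing.assert_allclose(sse, [2.0])
    sigma = stats.pooled_sigma(sse, np.array([1.0]))
    np.testing.assert_allclose(sigma, [math.sqrt(2.0)])
    # perfect fit
    np.testing.assert_allclose(stats.residual_sse(np.array([[2.0, 2.0]]), X, beta), [0.0])


def test_split_sse_equals_pooled_sse():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 3))
    y = rng.normal(size=(6, 30))
    xtx, xty = stats.local_moments(y, X)
    beta, *_ = stats.solve_global_lm(xtx, xty, full_mask(6, 3, 30))
    pooled = stats.residual_sse(y, X, beta)
    parts = np.split(np.arange(30), [11, 23])
    split = sum(stats.residual_sse(y[:, i], X[i], beta) for i in parts)
    np.testing.assert_allclose(split, pooled, rtol=1e-12)


# ---------------------------------------------------------------- design mask


def _three_cohort_structure():
    return stats.DesignStructure(
        columns=("A", "B", "cohort_2", "cohort_3"),
        class_cols=(0, 1),
        cohort_of_col={2: 1, 3: 2},
        n_cohorts=3,
        reference_cohort=0,
    )


def test_mask_drops_unobserved_cohort_column():
    obs = np.array([[5, 5, 0]])
    sup = np.array([[3, 7, 5, 0]])
    mask = stats.build_design_mask(obs, sup, _three_cohort_structure())
    assert list(mask.active[0]) == [True, True, True, False]
    assert mask.n_params[0] == 3 and mask.n_obs[0] == 10


def test_mask_switches_reference_when_first_cohort_empty():
    obs = np.array([[0, 5, 5]])
    sup = np.array([[4, 6, 5, 5]])
    mask = stats.build_design_mask(obs, sup, _three_cohort_structure())
    # cohort 2 becomes the protein's reference and its column is masked too
    assert list(mask.active[0]) == [True, True, False, True]
    assert mask.reference[0] == 1


def test_mask_full_rank_when_fully_observed():
    obs = np.array([[4, 4, 4]])
    sup = np.array([[6, 6, 4, 4]])
    mask = stats.build_design_mask(obs, sup, _three_cohort_structure())
    assert mask.active[0].all() and mask.n_params[0] == 4


def test_mask_rejects_protein_with_no_observations():
    with pytest.raises(ValueError, match="no observations"):
        stats.build_design_mask(
            np.array([[0, 0, 0]]), np.zeros((1, 4)), _three_cohort_structure()
        )


# ---------------------------------------------------------------- contrasts


def test_two_group_contrast_closed_form():
    y = np.array([[1.0, 3.0, 10.0, 14.0, 12.0]])
    X = np.zeros((5, 2))
    X[:2, 0] = 1.0
    X[2:, 1] = 1.0
    xtx, xty = stats.local_moments(y, X)
    mask = full_mask(1, 2, 5)
    beta, _, cov, _ = stats.solve_global_lm(xtx, xty, mask)
    bc, sc = stats.fit_contrast(beta, cov, mask, np.array([1.0, -1.0]))
    np.testing.assert_allclose(bc, [2.0 - 12.0])
    np.testing.assert_allclose(sc, [math.sqrt(1 / 2 + 1 / 3)])


def test_unit_contrast_reproduces_coefficient():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=(3, 20))
    xtx, xty = stats.local_moments(y, X)
    mask = full_mask(3, 3, 20)
    beta, stdev, cov, _ = stats.solve_global_lm(xtx, xty, mask)
    for j in range(3):
        K = np.zeros(3)
        K[j] = 1.0
        bc, sc = stats.fit_contrast(beta, cov, mask, K)
        np.testing.assert_allclose(bc, beta[:, j], rtol=1e-12)
        np.testing.assert_allclose(sc, stdev[:, j], rtol=1e-12)


def test_arbitrary_contrast_matches_quadratic_form():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(25, 3))
    y = rng.normal(size=(5, 25))
    xtx, xty = stats.local_moments(y, X)
    mask = full_mask(5, 3, 25)
    beta, _, cov, _ = stats.solve_global_lm(xtx, xty, mask)
    K = np.array([0.7, -1.3, 0.4])
    bc, sc = stats.fit_contrast(beta, cov, mask, K)
    for p in range(5):
        np.testing.assert_allclose(sc[p], math.sqrt(K @ cov[p] @ K), rtol=1e-12)
        np.testing.assert_allclose(bc[p], beta[p] @ K, rtol=1e-12)


def test_contrast_on_masked_coefficient_is_missing():
    mask = full_mask(1, 2, 5)
    mask.active[0, 1] = False
    beta = np.array([[1.0, np.nan]])
    cov = np.full((1, 2, 2), np.nan)
    cov[0, 0, 0] = 0.5
    bc, sc = stats.fit_contrast(beta, cov, mask, np.array([1.0, -1.0]))
    assert np.isnan(bc[0]) and np.isnan(sc[0])


# ---------------------------------------------------------------- prior fit


@given(st.floats(1e-5, 1e6))
@settings(max_examples=100, deadline=None)
def test_trigamma_inverse_roundtrip(y):
    x = stats.trigamma_inverse(y)
    assert math.isclose(float(special.polygamma(1, x)), y, rel_tol=1e-6)


def test_f_dist_parameter_recovery():
    """Recover (df_prior, s2_prior) from scaled inverse-chi-square draws."""
    rng = np.random.default_rng(10)
    n, d0, s02, df = 20000, 4.0, 2.0, 5
    true_var = s02 * d0 / rng.chisquare(d0, size=n)
    s2 = true_var * rng.chisquare(df, size=n) / df
    df_prior, s2_prior = stats.fit_f_dist(s2, np.full(n, float(df)))
    assert abs(df_prior - d0) / d0 < 0.05
    assert abs(s2_prior - s02) / s02 < 0.05


def test_f_dist_identical_variances_gives_infinite_prior_df():
    df_prior, s2_prior = stats.fit_f_dist(np.full(50, 2.5), np.full(50, 4.0))
    assert math.isinf(df_prior)
    assert s2_prior == pytest.approx(2.5)


def test_f_dist_single_feature_rejected():
    with pytest.raises(ValueError, match="insufficient"):
        stats.fit_f_dist(np.array([1.0]), np.array([3.0]))


# ---------------------------------------------------------------- moderation


def _simple_fit(n=50, seed=0):
    rng = np.random.default_rng(seed)
    beta_c = rng.normal(size=n)
    stdev_c = np.full(n, 0.5)
    sigma2 = 3.0 / rng.gamma(2.0, 1.0, size=n)
    df = np.full(n, 6.0)
    return beta_c, stdev_c, sigma2, df


def test_zero_prior_df_gives_ordinary_t():
    beta_c, stdev_c, sigma2, df = _simple_fit()
    mod = stats.moderate(beta_c, stdev_c, sigma2, df, 0.0, 1.0)
    np.testing.assert_allclose(mod.s2_post, sigma2)
    np.testing.assert_allclose(mod.t, beta_c / (stdev_c * np.sqrt(sigma2)))


def test_infinite_prior_df_collapses_to_prior_variance():
    beta_c, stdev_c, sigma2, df = _simple_fit()
    mod = stats.moderate(beta_c, stdev_c, sigma2, df, math.inf, 1.7)
    np.testing.assert_allclose(mod.s2_post, 1.7)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_posterior_variance_is_convex_combination(seed):
    beta_c, stdev_c, sigma2, df = _simple_fit(seed=seed)
    d0, s20 = 3.0, 1.5
    mod = stats.moderate(beta_c, stdev_c, sigma2, df, d0, s20)
    lo = np.minimum(sigma2, s20)
    hi = np.maximum(sigma2, s20)
    assert np.all(mod.s2_post >= lo - 1e-12) and np.all(mod.s2_post <= hi + 1e-12)


def test_confidence_interval_contains_logfc():
    beta_c, stdev_c, sigma2, df = _simple_fit()
    mod = stats.moderate(beta_c, stdev_c, sigma2, df, 3.0, 1.5)
    assert np.all(mod.ci_low <= mod.logfc) and np.all(mod.logfc <= mod.ci_high)


def test_null_type_one_error_calibrated():
    """Moderated p values are uniform under the null to binomial accuracy."""
    rng = np.random.default_rng(77)
    n, m = 6000, 20
    sig = np.sqrt(3.0 / rng.gamma(2.0, 1.0, size=n))
    y = rng.normal(size=(n, m)) * sig[:, None]
    X = np.zeros((m, 2))
    X[: m // 2, 0] = 1.0
    X[m // 2 :, 1] = 1.0
    xtx, xty = stats.local_moments(y, X)
    mask = full_mask(n, 2, m)
    beta, _, cov, _ = stats.solve_global_lm(xtx, xty, mask)
    sse = stats.residual_sse(y, X, beta)
    df = np.full(n, float(m - 2))
    s2 = sse / df
    bc, sc = stats.fit_contrast(beta, cov, mask, np.array([1.0, -1.0]))
    d0, s20 = stats.fit_f_dist(s2, df)
    mod = stats.moderate(bc, sc, s2, df, d0, s20)
    rate = float(np.mean(mod.p < 0.05))
    assert 0.04 <= rate <= 0.06


# ---------------------------------------------------------------- BH


def test_bh_hand_examples():
    np.testing.assert_allclose(
        stats.bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(stats.bh_adjust(np.array([0.03])), [0.03])


def _bh_bruteforce(p):
    n = len(p)
    order = np.argsort(p)
    out = np.empty(n)
    for rank_pos, i in enumerate(order):
        out[i] = min(
            min(p[j] * n / (list(order).index(j) + 1) for j in order[rank_pos:]), 1.0
        )
    return out


@given(st.integers(0, 10_000), st.integers(1, 25))
@settings(max_examples=30, deadline=None)
def test_bh_matches_bruteforce_definition(seed, n):
    p = np.random.default_rng(seed).random(n)
    np.testing.assert_allclose(stats.bh_adjust(p), _bh_bruteforce(p), rtol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    p = np.random.default_rng(4).random(200)
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(stats.bh_adjust(p), expected, rtol=1e-12)


def test_bh_nan_handling_and_permutation_invariance():
    p = np.array([0.01, np.nan, 0.5, 0.02])
    adj = stats.bh_adjust(p)
    assert np.isnan(adj[1])
    np.testing.assert_allclose(
        np.delete(adj, 1), stats.bh_adjust(np.array([0.01, 0.5, 0.02]))
    )
    perm = np.array([3, 0, 2, 1])
    adj_perm = stats.bh_adjust(p[perm])
    np.testing.assert_allclose(adj_perm, adj[perm], equal_nan=True)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        stats.bh_adjust(np.array([0.5, 1.5]))


# ---------------------------------------------------------------- counts


def _moderated_base(beta_c, stdev_c, sigma2, df):
    d0, s20 = stats.fit_f_dist(sigma2, df)
    return stats.moderate(beta_c, stdev_c, sigma2, df, d0, s20)


def test_equal_counts_reduce_to_count_free_moderation():
    beta_c, stdev_c, sigma2, df = _simple_fit(n=100, seed=8)
    base = _moderated_base(beta_c, stdev_c, sigma2, df)
    res = stats.count_adjust(
        beta_c, stdev_c, sigma2, df, np.full(100, 4.0), base
    )
    np.testing.assert_allclose(res.sca_t, base.t, equal_nan=True)
    np.testing.assert_allclose(res.sca_p, base.p, equal_nan=True)


def test_count_trend_is_decreasing_when_variance_scales_inversely():
    rng = np.random.default_rng(12)
    n = 2000
    counts = 1.0 + rng.poisson(6, size=n)
    true_var = 2.0 / counts
    df = np.full(n, 8.0)
    sigma2 = true_var * rng.chisquare(8, size=n) / 8.0
    beta_c = rng.normal(size=n)
    stdev_c = np.full(n, 0.5)
    base = _moderated_base(beta_c, stdev_c, sigma2, df)
    res = stats.count_adjust(beta_c, stdev_c, sigma2, df, counts, base)
    lo = res.sca_s2_prior[counts <= 3]
    hi = res.sca_s2_prior[counts >= 10]
    assert np.nanmean(hi) < np.nanmean(lo)


def test_missing_count_keeps_nan_sca_fields():
    beta_c, stdev_c, sigma2, df = _simple_fit(n=60, seed=9)
    counts = 1.0 + np.arange(60.0) % 7
    counts[5] = np.nan
    base = _moderated_base(beta_c, stdev_c, sigma2, df)
    res = stats.count_adjust(beta_c, stdev_c, sigma2, df, counts, base)
    assert np.isnan(res.sca_t[5]) and np.isnan(res.sca_p[5])
    assert np.isfinite(res.sca_t[6])


def test_loess_trend_recovers_smooth_signal():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 4, size=400)
    y = 1.0 + 0.5 * x - 0.2 * x**2 + rng.normal(scale=0.05, size=400)
    fit = stats.loess_trend(x, y, span=0.5)
    truth = 1.0 + 0.5 * x - 0.2 * x**2
    assert np.max(np.abs(fit - truth)) < 0.1
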