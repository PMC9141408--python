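"""Unit and property tests for the aggregation rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp
from scipy.optimize import minimize

from robustagg.aggregators import (
    DegenerateWeightsError,
    GammaConfig,
    SingularScatterError,
    gamma_mean,
    gamma_rule,
    gamma_weights,
    geometric_median,
    marginal_median,
    mean_aggregate,
    simple_gamma_mean,
    trimmed_mean,
    weighted_quantile,
    weiszfeld,
)

# Element range is kept moderate: with gamma = 0.5 the fixed-point map of the
# gamma-mean is only a contraction when gamma * spread^2 is moderate; for two
# widely separated clusters the symmetric midpoint is an unstable fixed point
# and float rounding selects a basin, which breaks bitwise equivariance even
# though the estimator is equivariant in exact arithmetic.
batches = hnp.arrays(
    float,
    st.tuples(st.integers(2, 12), st.integers(1, 4)),
    elements=st.floats(-3, 3, allow_nan=False, allow_infinity=False, width=32),
)


# --------------------------------------------------------------------------
# gamma weights
# --------------------------------------------------------------------------

class TestGammaWeights:
    def test_equidistant_points_share_weight(self):
        w = gamma_weights(np.array([[1.0], [-1.0]]), [0.0], [1.0], gamma=2.0)
        np.testing.assert_allclose(w, [0.5, 0.5])

    def test_gamma_zero_gives_uniform_weights(self, random_batch):
        w = gamma_weights(random_batch, random_batch.mean(0), np.ones(4), gamma=0.0)
        np.testing.assert_allclose(w, np.full(len(random_batch), 1 / len(random_batch)))

    def test_scalar_example_matches_hand_computation(self):
        # d = (exp(0), exp(-1)) for points {0, 1} at mu=0, gamma=2
        w = gamma_weights(np.array([[0.0], [1.0]]), [0.0], [1.0], gamma=2.0)
        expected = np.array([1.0, np.exp(-1.0)])
        np.testing.assert_allclose(w, expected / expected.sum(), rtol=1e-12)

    def test_weights_decrease_with_distance(self, rng):
        x = np.sort(rng.standard_normal(20))[:, None]
        w = gamma_weights(x, [0.0], [1.0], gamma=1.0)
        d2 = x.ravel() ** 2
        order = np.argsort(d2)
        assert np.all(np.diff(w[order]) <= 1e-15)

    def test_all_underflowed_raises_with_distance(self):
        x = np.full((3, 1), 1e6)
        with pytest.raises(DegenerateWeightsError, match="Mahalanobis"):
            gamma_weights(x, [0.0], [1.0], gamma=1.0)

    def test_simplex_invariant(self, rng):
        for _ in range(20):
            x = rng.standard_normal((15, 3)) * 3
            w = gamma_weights(x, rng.standard_normal(3), np.ones(3), gamma=rng.uniform(0, 3))
            assert abs(w.sum() - 1.0) < 1e-12
            assert np.all(w >= 0)


# --------------------------------------------------------------------------
# gamma-mean (full Gaussian working model)
# --------------------------------------------------------------------------

class TestGammaMean:
    def test_symmetric_batch_fixed_point(self):
        c = np.array([2.0, -1.0])
        x = np.array([[1.0, 0.0], [3.0, -2.0], [2.5, 3.0], [1.5, -5.0]])
        batch = np.vstack([x, 2 * c - x])
        cfg = GammaConfig(gamma=0.8, init_policy="user_supplied", mu0=c, max_iters=50)
        est = gamma_mean(batch, cfg)
        np.testing.assert_allclose(est.mu, c, atol=1e-10)

    def test_gamma_to_zero_recovers_mean_and_ml_covariance(self, rng):
        x = rng.standard_normal((60, 3)) * 2 + 1
        est = gamma_mean(x, GammaConfig(gamma=1e-10))
        np.testing.assert_allclose(est.mu, x.mean(0), rtol=1e-6)
        np.testing.assert_allclose(est.sigma, np.cov(x.T, bias=True), rtol=1e-6)

    def test_stationarity_plugback(self, rng):
        x = rng.standard_normal((200, 2))
        est = gamma_mean(x, GammaConfig(gamma=1.0, tol=1e-10, max_iters=500))
        assert est.converged
        # independent plug-back of the stationary equations
        diff = x - est.mu
        sigma_inv = np.linalg.inv(est.sigma)
        d = np.exp(-0.5 * 1.0 * np.einsum("ij,jk,ik->i", diff, sigma_inv, diff))
        w = d / d.sum()
        np.testing.assert_allclose(est.mu, w @ x, atol=1e-8)
        cent = x - est.mu
        sigma_rhs = 2.0 * (w[:, None] * cent).T @ cent
        np.testing.assert_allclose(est.sigma, sigma_rhs, atol=1e-8)
        assert est.stationarity_residual < 1e-8

    def test_byzantine_rows_get_negligible_weight(self, contaminated_batch):
        x, mask = contaminated_batch
        est = gamma_mean(x, GammaConfig(gamma=0.5, scatter_policy="diagonal_fallback"))
        assert est.weights[mask].max() < 1e-10
        assert np.linalg.norm(est.mu) < 1.0

    def test_diagonal_fallback_below_threshold(self, rng):
        # m = 8 < 5p = 15 triggers the diagonal inverse; sigma is stored diagonal
        x = rng.standard_normal((8, 3))
        est = gamma_mean(x, GammaConfig(gamma=0.3))
        assert est.sigma.ndim == 1

    def test_singular_full_scatter_advises_fallback(self):
        # collinear points make the full scatter rank deficient
        t = np.linspace(-1, 1, 30)
        x = np.column_stack([t, 2 * t])
        with pytest.raises(SingularScatterError, match="diagonal_fallback"):
            gamma_mean(x, GammaConfig(gamma=0.5, diagonal_fallback_threshold=2))

    def test_nonconvergence_flagged_not_raised(self, rng):
        x = rng.standard_normal((50, 2))
        est = gamma_mean(x, GammaConfig(gamma=1.0, max_iters=1, tol=1e-14))
        assert not est.converged

    def test_weight_simplex(self, rng):
        x = rng.standard_normal((30, 2))
        est = gamma_mean(x, GammaConfig(gamma=0.7))
        assert abs(est.weights.sum() - 1.0) < 1e-12


class TestSimpleGammaMean:
    def test_single_row_returns_the_row(self):
        x = np.array([[3.0, -2.0, 7.0]])
        est = simple_gamma_mean(x, GammaConfig(gamma=1.0, working_model="standard_gaussian"))
        np.testing.assert_allclose(est.mu, x[0])

    def test_symmetric_pair_fixed_at_zero(self):
        a = np.array([2.0, -3.0])
        cfg = GammaConfig(gamma=0.5, working_model="standard_gaussian",
                          init_policy="user_supplied", mu0=np.zeros(2))
        est = simple_gamma_mean(np.vstack([a, -a]), cfg)
        np.testing.assert_allclose(est.mu, np.zeros(2), atol=1e-12)

    def test_outlier_downweighted_exponentially(self):
        # {0, 0, 10}: starting from the median, the outlier weight is e^{-50}
        x = np.array([[0.0], [0.0], [10.0]])
        est = simple_gamma_mean(x, GammaConfig(gamma=1.0, working_model="standard_gaussian"))
        expected = 10 * np.exp(-50) / (2 + np.exp(-50))
        np.testing.assert_allclose(est.mu, [expected], atol=1e-25)
        assert abs(est.mu[0]) < 1e-20  # far from the sample mean 10/3

    def test_gamma_to_zero_is_sample_mean(self, random_batch):
        cfg = GammaConfig(gamma=1e-10, working_model="standard_gaussian")
        est = simple_gamma_mean(random_batch, cfg)
        np.testing.assert_allclose(est.mu, random_batch.mean(0), rtol=1e-6)

    def test_sigma_reported_as_identity(self, random_batch):
        cfg = GammaConfig(gamma=0.5, working_model="standard_gaussian")
        est = simple_gamma_mean(random_batch, cfg)
        np.testing.assert_array_equal(est.sigma, np.ones(random_batch.shape[1]))


# --------------------------------------------------------------------------
# classical aggregators
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fn,batch,expected",
    [
        (mean_aggregate, [[1.0], [2.0], [3.0]], [2.0]),
        (mean_aggregate, [[0.0], [0.0], [10.0]], [10.0 / 3.0]),
        (marginal_median, [[1.0], [2.0], [100.0]], [2.0]),
        (marginal_median, [[1.0], [2.0], [3.0], [100.0]], [2.5]),
        (marginal_median, [[0.0, 100.0], [1.0, 0.0], [2.0, 50.0]], [1.0, 50.0]),
    ],
)
def test_location_examples(fn, batch, expected):
    np.testing.assert_allclose(fn(np.array(batch)), expected)


class TestTrimmedMean:
    def test_beta_zero_is_mean(self, random_batch):
        np.testing.assert_allclose(trimmed_mean(random_batch, 0.0),
                                   mean_aggregate(random_batch))

    def test_two_sided_trim_removes_outlier(self):
        x = np.arange(1.0, 10.0).tolist() + [100.0]
        assert trimmed_mean(np.array(x)[:, None], 0.1)[0] == pytest.approx(5.5)

    def test_one_sided_outliers_survive_symmetric_trim(self):
        x = np.array([0.0] * 8 + [50.0, 60.0])[:, None]
        assert trimmed_mean(x, 0.1)[0] == pytest.approx(50.0 / 8.0)

    def test_beta_out_of_range_rejected(self):
        # with k = floor(beta*m) per tail, beta < 0.5 can never remove all
        # rows, so the only invalid inputs are beta outside [0, 0.5)
        with pytest.raises(ValueError):
            trimmed_mean(np.ones((4, 1)), 0.5)
        with pytest.raises(ValueError):
            trimmed_mean(np.ones((4, 1)), -0.1)


class TestGeometricMedian:
    def test_square_symmetry(self):
        x = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        np.testing.assert_allclose(geometric_median(x), [0.5, 0.5], atol=1e-8)

    def test_univariate_reduces_to_median(self, rng):
        for _ in range(5):
            x = rng.standard_normal((11, 1)) * 3
            np.testing.assert_allclose(geometric_median(x), np.median(x, axis=0), atol=1e-7)

    def test_matches_convex_optimizer(self, rng):
        x = rng.standard_normal((20, 3))
        obj = lambda y: np.linalg.norm(x - y, axis=1).sum()
        res = minimize(obj, x.mean(0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
        np.testing.assert_allclose(geometric_median(x, tol=1e-12), res.x, atol=1e-6)

    def test_objective_monotone(self, rng):
        x = rng.standard_normal((30, 2))
        _, info = weiszfeld(x)
        obj = np.array(info.objective)
        assert np.all(np.diff(obj) <= 1e-12)

    def test_two_points_midpoint_flagged_nonunique(self):
        y, info = weiszfeld(np.array([[0.0, 0.0], [2.0, 2.0]]))
        np.testing.assert_allclose(y, [1.0, 1.0])
        assert info.nonunique

    def test_anchor_point_optimality(self):
        # the central point of a star dominates: iterates must stop on it
        x = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        np.testing.assert_allclose(geometric_median(x), [0.0, 0.0], atol=1e-10)


# --------------------------------------------------------------------------
# shared invariance properties
# --------------------------------------------------------------------------

_AGGS = {
    "mean": mean_aggregate,
    "marginal_median": marginal_median,
    "trimmed_mean": lambda x: trimmed_mean(x, 0.1),
    "geometric_median": lambda x: geometric_median(x, tol=1e-12),
    # gamma = 0.1 keeps gamma * spread^2 < 1 on the strategy's element range,
    # i.e. inside the stable (contractive) regime of the fixed-point map
    "simple_gamma_mean": lambda x: simple_gamma_mean(
        x, GammaConfig(gamma=0.1, working_model="standard_gaussian", tol=1e-12)).mu,
}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(batches, st.integers(0, 2**31 - 1))
def test_permutation_invariance(batch, perm_seed):
    perm = np.random.default_rng(perm_seed).permutation(batch.shape[0])
    for name, fn in _AGGS.items():
        np.testing.assert_allclose(fn(batch[perm]), fn(batch), atol=1e-7,
                                   err_msg=f"aggregator {name}")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(batches, st.floats(-20, 20, allow_nan=False))
def test_translation_equivariance(batch, shift):
    c = np.full(batch.shape[1], shift)
    for name, fn in _AGGS.items():
        np.testing.assert_allclose(fn(batch + c), fn(batch) + c, atol=1e-6,
                                   err_msg=f"aggregator {name}")


def test_gamma_rule():
    assert gamma_rule(2.0, 100) == pytest.approx(0.02)
    with pytest.raises(ValueError):
        gamma_rule(2.0, 0)


def test_weighted_quantile_matches_numpy_median(rng):
    for m in (5, 6, 9, 10):
        v = rng.standard_normal(m)
        assert weighted_quantile(v, 0.5) == pytest.approx(np.median(v))
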