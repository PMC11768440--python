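"""t-SNE internals: affinity calibration, KL objective, gradient, descent."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dustrisk import (
    TSNE,
    TsneParams,
    conditional_affinities,
    joint_probabilities,
    kl_divergence,
    kl_gradient,
    low_dim_affinities,
    tsne_run,
)


def brute_force_sigma(d2_row: np.ndarray, perplexity: float) -> float:
    """Grid search over sigma matching 2^H to the target perplexity."""
    target = np.log2(perplexity)
    best, best_err = None, np.inf
    for sigma in np.geomspace(1e-3, 1e3, 20000):
        w = np.exp(-d2_row / (2 * sigma**2))
        if w.sum() <= 0:
            continue
        p = w / w.sum()
        h = -(p[p > 0] * np.log2(p[p > 0])).sum()
        if abs(h - target) < best_err:
            best, best_err = sigma, abs(h - target)
    return best


class TestConditionalAffinities:
    def test_equidistant_neighbors_split_evenly(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        aff = conditional_affinities(X, perplexity=2)
        np.testing.assert_allclose(aff.conditional[0], [0.0, 0.5, 0.5], atol=1e-12)

    def test_rows_are_distributions_with_zero_diagonal(self):
        rng = np.random.default_rng(0)
        aff = conditional_affinities(rng.standard_normal((12, 4)), perplexity=4)
        np.testing.assert_allclose(aff.conditional.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.diag(aff.conditional), 0.0)

    def test_achieved_entropy_matches_target(self):
        X = np.array([[0.0], [1.0], [3.0]])
        aff = conditional_affinities(X, perplexity=2, tol=1e-6)
        np.testing.assert_allclose(aff.entropy_bits, 1.0, atol=1e-5)

    def test_bisection_agrees_with_grid_search(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((10, 3))
        perp = 4.0
        aff = conditional_affinities(X, perplexity=perp, tol=1e-7)
        from scipy.spatial.distance import pdist, squareform
        D2 = squareform(pdist(X, "sqeuclidean"))
        for i in range(10):
            d2 = D2[i, np.arange(10) != i]
            assert aff.sigma[i] == pytest.approx(brute_force_sigma(d2, perp), rel=1e-3)

    def test_duplicate_points_named_in_error(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="0 and 1"):
            conditional_affinities(X, perplexity=2)

    def test_perplexity_bounds_enforced(self):
        X = np.random.default_rng(2).standard_normal((5, 2))
        with pytest.raises(ValueError):
            conditional_affinities(X, perplexity=5)
        with pytest.raises(ValueError):
            conditional_affinities(X, perplexity=1.0)


class TestJointDistribution:
    def test_symmetric_and_normalized(self):
        rng = np.random.default_rng(3)
        aff = conditional_affinities(rng.standard_normal((9, 3)), perplexity=3)
        P = joint_probabilities(aff)
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert P.sum() == pytest.approx(1.0, abs=1e-10)
        assert (P >= 0).all()

    def test_hand_computed_three_points(self):
        X = np.array([[0.0], [1.0], [3.0]])
        aff = conditional_affinities(X, perplexity=2, tol=1e-8)
        expect = (aff.conditional + aff.conditional.T) / 6.0
        np.testing.assert_allclose(aff.joint, expect, atol=1e-15)


class TestLowDimAffinities:
    def test_coincident_points_are_uniform(self):
        Q = low_dim_affinities(np.zeros((3, 2)))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(Q[off], 1.0 / 6.0, atol=1e-15)

    def test_three_point_direct_formula(self):
        Y = np.array([[0.0], [1.0], [3.0]])
        kern = lambda a, b: 1.0 / (1.0 + (a - b) ** 2)
        k01, k02, k12 = kern(0, 1), kern(0, 3), kern(1, 3)
        total = 2 * (k01 + k02 + k12)
        Q = low_dim_affinities(Y)
        np.testing.assert_allclose(Q[0, 1], k01 / total, atol=1e-12)
        np.testing.assert_allclose(Q[0, 2], k02 / total, atol=1e-12)
        np.testing.assert_allclose(Q[1, 2], k12 / total, atol=1e-12)


class TestKlDivergence:
    def test_identical_distributions_give_zero(self):
        rng = np.random.default_rng(4)
        P = rng.random((6, 6))
        np.fill_diagonal(P, 0)
        P /= P.sum()
        assert kl_divergence(P, P) == pytest.approx(0.0, abs=1e-14)

    def test_hand_value_two_cells(self):
        P = np.array([[0.0, 0.5], [0.5, 0.0]])
        Q = np.array([[0.0, 0.9], [0.1, 0.0]])
        expect = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        assert kl_divergence(P, Q) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.5108, abs=1e-4)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_nonnegative_on_random_pairs(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        P, Q = rng.random((n, n)) + 1e-9, rng.random((n, n)) + 1e-9
        np.fill_diagonal(P, 0)
        np.fill_diagonal(Q, 0)
        P /= P.sum()
        Q /= Q.sum()
        assert kl_divergence(P, Q) >= -1e-12

    def test_zero_q_with_mass_is_error(self):
        P = np.array([[0.0, 1.0], [0.0, 0.0]])
        Q = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            kl_divergence(P, Q)


class TestGradient:
    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 4))
        aff = conditional_affinities(X, perplexity=3)
        P = aff.joint
        Y = rng.standard_normal((6, 2))
        grad = kl_gradient(P, Y)
        eps = 1e-6
        num = np.zeros_like(Y)
        for i in range(6):
            for d in range(2):
                Yp, Ym = Y.copy(), Y.copy()
                Yp[i, d] += eps
                Ym[i, d] -= eps
                num[i, d] = (
                    kl_divergence(P, low_dim_affinities(Yp))
                    - kl_divergence(P, low_dim_affinities(Ym))
                ) / (2 * eps)
        np.testing.assert_allclose(grad, num, rtol=1e-5, atol=1e-8)


class TestOptimization:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 5))
        a = tsne_run(X, TsneParams(seed=3, max_iter=50))
        b = tsne_run(X, TsneParams(seed=3, max_iter=50))
        np.testing.assert_array_equal(a.Y, b.Y)
        np.testing.assert_array_equal(a.kl_trace, b.kl_trace)

    def test_kl_decreases_from_start(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((12, 4))
            result = tsne_run(X, TsneParams(seed=seed))
            assert result.final_kl <= result.kl_trace[0]
            assert np.isfinite(result.kl_trace).all()

    def test_separated_groups_stay_separated(self):
        rng = np.random.default_rng(7)
        X = np.vstack([
            rng.standard_normal((7, 3)) * 0.1,
            rng.standard_normal((7, 3)) * 0.1 + 5.0,
        ])
        result = tsne_run(X, TsneParams(seed=0))
        from scipy.spatial.distance import pdist, squareform
        D = squareform(pdist(result.Y))
        same = np.zeros((14, 14), dtype=bool)
        same[:7, :7] = same[7:, 7:] = True
        np.fill_diagonal(same, False)
        assert D[same].mean() < D[~same].mean()

    def test_rotation_equivariance_of_trace(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((10, 3))
        theta = 0.7
        R3 = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1.0],
        ])
        a = tsne_run(X, TsneParams(seed=1, max_iter=100))
        b = tsne_run(X @ R3.T, TsneParams(seed=1, max_iter=100))
        np.testing.assert_allclose(a.kl_trace, b.kl_trace, atol=1e-9)

    def test_estimator_interface(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((10, 4))
        est = TSNE(max_iter=50, seed=2)
        Y = est.fit_transform(X)
        assert Y.shape == (10, 2)
        assert est.final_kl_ == est.kl_trace_[-1]
        assert est.get_params()["perplexity"] == 3.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TsneParams(momentum=1.5).validate()
        with pytest.raises(ValueError):
            TsneParams(learning_rate=-1).validate()
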