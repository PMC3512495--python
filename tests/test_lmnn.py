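import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from margincad.lmnn import (LinearTransform, LmnnConfig, find_target_neighbors,
                            fit_klmnn, lmnn_gradient, lmnn_loss,
                            make_mahalanobis, optimize_L, squared_distance_L)
from margincad.reduction import fit_kpca, project


def loss_loop(L, X, targets, labels, mu):
    """Exhaustive triple-loop reference for the LMNN loss."""
    n = len(X)
    pull = push = 0.0
    for i in range(n):
        for j in targets[i]:
            dij = np.sum((L @ (X[i] - X[j])) ** 2)
            pull += dij
            for l in range(n):
                if labels[l] != labels[i]:
                    dil = np.sum((L @ (X[i] - X[l])) ** 2)
                    push += max(0.0, 1.0 + dij - dil)
    return (1.0 - mu) * pull + mu * push, pull, push


def toy(rng, n=8, d=3):
    X = rng.normal(size=(n, d))
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return X, y


class TestTargetNeighbors:
    def test_two_clusters_nearest_mate(self):
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        y = np.array([0, 0, 1, 1])
        ns = find_target_neighbors(X, y, 1)
        np.testing.assert_array_equal(ns.target_neighbors.ravel(), [1, 0, 3, 2])

    def test_duplicate_points_self_excluded(self):
        X = np.array([[1.0], [1.0], [9.0]])
        y = np.array([0, 0, 0])
        ns = find_target_neighbors(X, y, 1)
        assert ns.target_neighbors[0, 0] == 1
        assert ns.target_neighbors[1, 0] == 0

    def test_matches_exhaustive_search(self, rng):
        X, y = toy(rng, n=6, d=2)
        ns = find_target_neighbors(X, y, 2)
        for i in range(6):
            same = [j for j in range(6) if y[j] == y[i] and j != i]
            dist = sorted(same, key=lambda j: (np.sum((X[i] - X[j]) ** 2), j))
            assert set(ns.target_neighbors[i]) == set(dist[:2])

    def test_small_class_rejected(self):
        X = np.zeros((4, 2))
        y = np.array([0, 0, 0, 1])
        with pytest.raises(ValueError, match="members"):
            find_target_neighbors(X, y, 1)


class TestDistances:
    def test_identity_is_euclidean(self, rng):
        xi, xj = rng.normal(size=3), rng.normal(size=3)
        L = LinearTransform(np.eye(3))
        assert squared_distance_L(L, xi, xj) == pytest.approx(
            np.sum((xi - xj) ** 2))

    def test_zero_for_equal_points(self, rng):
        x = rng.normal(size=4)
        assert squared_distance_L(LinearTransform(np.eye(4)), x, x) == 0.0

    def test_worked_matrix_example(self):
        L = LinearTransform(np.array([[1.0, 0.0], [1.0, 1.0]]))
        assert squared_distance_L(L, np.array([1.0, 1.0]),
                                  np.array([0.0, 0.0])) == pytest.approx(5.0)

    def test_mahalanobis_equals_transform_distance(self, rng):
        L = LinearTransform(rng.normal(size=(2, 5)))
        M = make_mahalanobis(L)
        for _ in range(10):
            xi, xj = rng.normal(size=5), rng.normal(size=5)
            assert M.squared_distance(xi, xj) == pytest.approx(
                squared_distance_L(L, xi, xj), abs=1e-10)

    def test_mahalanobis_psd_and_identity(self):
        assert np.allclose(make_mahalanobis(LinearTransform(np.eye(3))).M,
                           np.eye(3))
        L = LinearTransform(np.random.default_rng(0).normal(size=(4, 4)))
        evals = np.linalg.eigvalsh(make_mahalanobis(L).M)
        assert evals.min() >= -1e-10


class TestLoss:
    def test_single_class_no_push(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.zeros(6, dtype=int)
        ns = find_target_neighbors(X, y, 2)
        _, _, push = lmnn_loss(LinearTransform(np.eye(2)), X, ns, 0.5)
        assert push == 0.0

    def test_mu_endpoints(self, rng):
        X, y = toy(rng)
        ns = find_target_neighbors(X, y, 1)
        L = LinearTransform(np.eye(3))
        t0, pull, _ = lmnn_loss(L, X, ns, 0.0)
        t1, _, push = lmnn_loss(L, X, ns, 1.0)
        assert t0 == pytest.approx(pull) and t1 == pytest.approx(push)

    def test_matches_triple_loop_oracle(self, rng):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([0, 0, 1, 1])
        ns = find_target_neighbors(X, y, 1)
        L = LinearTransform(np.eye(2))
        got = lmnn_loss(L, X, ns, 0.5)
        want = loss_loop(L.L, X, ns.target_neighbors, y, 0.5)
        np.testing.assert_allclose(got, want, atol=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.0, 1.0, allow_nan=False))
    def test_oracle_equivalence_random(self, seed, mu):
        r = np.random.default_rng(seed)
        X, y = toy(r, n=8, d=3)
        ns = find_target_neighbors(X, y, 2)
        L = LinearTransform(r.normal(size=(3, 3)))
        got = lmnn_loss(L, X, ns, mu)
        want = loss_loop(L.L, X, ns.target_neighbors, y, mu)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_decomposition_on_mu_grid(self, rng):
        X, y = toy(rng)
        ns = find_target_neighbors(X, y, 2)
        L = LinearTransform(rng.normal(size=(3, 3)))
        for mu in np.linspace(0, 1, 11):
            total, pull, push = lmnn_loss(L, X, ns, mu)
            assert total == pytest.approx((1 - mu) * pull + mu * push, rel=1e-12)

    def test_pull_scales_quadratically(self, rng):
        X, y = toy(rng)
        ns = find_target_neighbors(X, y, 1)
        L = LinearTransform(rng.normal(size=(3, 3)))
        _, pull1, _ = lmnn_loss(L, X, ns, 0.5)
        _, pull3, _ = lmnn_loss(LinearTransform(3.0 * L.L), X, ns, 0.5)
        assert pull3 == pytest.approx(9.0 * pull1, rel=1e-10)


class TestGradient:
    def test_finite_difference(self, rng):
        X, y = toy(rng, n=8, d=3)
        ns = find_target_neighbors(X, y, 2)
        L0 = rng.normal(size=(3, 3)) * 0.7
        mu = 0.4
        grad = lmnn_gradient(LinearTransform(L0), X, ns, mu)
        eps = 1e-6
        fd = np.zeros_like(L0)
        for a in range(3):
            for b in range(3):
                Lp, Lm = L0.copy(), L0.copy()
                Lp[a, b] += eps
                Lm[a, b] -= eps
                fp, _, _ = lmnn_loss(LinearTransform(Lp), X, ns, mu)
                fm, _, _ = lmnn_loss(LinearTransform(Lm), X, ns, mu)
                fd[a, b] = (fp - fm) / (2 * eps)
        assert np.max(np.abs(grad - fd)) < 1e-5

    def test_single_class_push_gradient_zero(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.zeros(6, dtype=int)
        ns = find_target_neighbors(X, y, 2)
        grad = lmnn_gradient(LinearTransform(np.eye(2)), X, ns, 1.0)
        np.testing.assert_allclose(grad, 0.0, atol=1e-14)

    def test_pull_gradient_closed_form(self, rng):
        X, y = toy(rng)
        ns = find_target_neighbors(X, y, 2)
        L = LinearTransform(rng.normal(size=(3, 3)))
        grad = lmnn_gradient(L, X, ns, 0.0)
        C = np.zeros((3, 3))
        for i in range(len(X)):
            for j in ns.target_neighbors[i]:
                d = X[i] - X[j]
                C += np.outer(d, d)
        np.testing.assert_allclose(grad, 2.0 * L.L @ C, atol=1e-10)


class TestOptimizer:
    def test_loss_decreases_on_separable_classes(self, rng):
        X = np.vstack([rng.normal(size=(10, 2)) * [1, 5] + [0, 0],
                       rng.normal(size=(10, 2)) * [1, 5] + [4, 0]])
        y = np.repeat([0, 1], 10)
        cfg = LmnnConfig(k_targets=3, max_iter=100, seed=0)
        L, trace = optimize_L(X, y, cfg)
        assert trace[-1] < trace[0]

    def test_trace_non_increasing_many_seeds(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(size=(12, 3))
            y = np.repeat([0, 1], 6)
            cfg = LmnnConfig(k_targets=2, max_iter=60, seed=seed)
            _, trace = optimize_L(X, y, cfg)
            assert np.all(np.diff(trace) <= 0)

    def test_huge_tol_returns_initialization(self, rng):
        X, y = toy(rng, n=10)
        cfg = LmnnConfig(k_targets=2, tol=1e12)
        L, trace = optimize_L(X, y, cfg)
        assert len(trace) <= 2

    def test_rectangular_weights_informative_feature(self, rng):
        n = 20
        y = np.repeat([0, 1], n // 2)
        informative = np.where(y == 0, -1.0, 1.0) + rng.normal(size=n) * 0.1
        noise = rng.normal(size=n) * 1.0
        X = np.column_stack([informative, noise])
        cfg = LmnnConfig(k_targets=3, max_iter=150, seed=1)
        L, _ = optimize_L(X, y, cfg, output_dim=1)
        w = np.abs(L.L[0])
        assert w[0] > w[1]

    def test_output_dim_validation(self, rng):
        X, y = toy(rng)
        with pytest.raises(ValueError, match="output_dim"):
            optimize_L(X, y, LmnnConfig(k_targets=1), output_dim=7)


class TestKlmnn:
    def test_linear_kernel_matches_plain_lmnn(self, rng):
        X, y = toy(rng, n=12, d=4)
        cfg = LmnnConfig(k_targets=2, max_iter=50, seed=3)
        kpca = fit_kpca(X, 4, kernel="linear")
        Lk, trace_k = fit_klmnn(X, y, cfg, kpca)
        # linear-kernel KPCA coordinates are a rotation of centered X, and
        # the identity-initialized descent is rotation-equivariant, so the
        # loss trajectory matches plain LMNN on the raw inputs
        Lp, trace_p = optimize_L(X, y, cfg)
        np.testing.assert_allclose(trace_k, trace_p, atol=1e-6)

    def test_identity_transform_preserves_kpca_distances(self, rng):
        X, y = toy(rng, n=10, d=3)
        kpca = fit_kpca(X, 3, sigma=2.0)
        Z = project(kpca, X)
        L = LinearTransform(np.eye(3))
        d1 = squared_distance_L(L, Z[0], Z[1])
        assert d1 == pytest.approx(np.sum((Z[0] - Z[1]) ** 2))

    def test_concentric_circles_kernel_beats_linear(self):
        r = np.random.default_rng(5)
        n = 24
        theta = r.uniform(0, 2 * np.pi, n)
        radius = np.repeat([1.0, 3.0], n // 2)
        X = np.column_stack([radius * np.cos(theta), radius * np.sin(theta)])
        X += r.normal(size=X.shape) * 0.05
        y = np.repeat([0, 1], n // 2)
        cfg = LmnnConfig(k_targets=2, max_iter=120, seed=5)
        _, trace_lin = optimize_L(X, y, cfg)
        kpca = fit_kpca(X, 6, sigma=1.0)
        _, trace_k = fit_klmnn(X, y, cfg, kpca)
        # kernelized coordinates allow a lower final (push-dominated) loss
        assert trace_k[-1] < trace_lin[-1]
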