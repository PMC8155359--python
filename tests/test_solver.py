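import itertools

import numpy as np
import pytest

from maci import solver
from maci.datasets_io import DomainDataset, ProblemConfig, ValidationError
from maci.model import pseudo_label
from maci.solver import (SolverState, SourceOperators, irls_diag_l21,
                         l21_norm, objective, trace_norm, trace_norm_weight,
                         update_eta, update_theta, update_W, update_W0,
                         window_stop)
from maci.synth import SyntheticConfig, generate


class TestIrlsDiag:
    def test_row_norm_three(self):
        z = irls_diag_l21(np.array([[3.0, 0.0]]))
        assert z[0] == pytest.approx(1.0 / 6.0, rel=1e-10)

    def test_zero_row_guarded(self):
        z = irls_diag_l21(np.zeros((1, 2)), eps=1e-12)
        assert np.isfinite(z[0])
        assert z[0] == pytest.approx(1e12)

    def test_surrogate_identity(self, rng):
        # 2 tr(T^T Z T) = ||T||_{2,1} at the linearization point
        T = rng.standard_normal((6, 3))
        z = irls_diag_l21(T, eps=1e-15)
        assert 2 * np.sum(z[:, None] * T * T) == pytest.approx(
            l21_norm(T), rel=1e-10)

    def test_bad_eps(self):
        with pytest.raises(ValidationError):
            irls_diag_l21(np.ones((2, 2)), eps=0)


class TestTraceNormWeight:
    def test_scalar(self):
        U = trace_norm_weight(np.array([[2.0]]))
        assert U[0, 0] == pytest.approx(0.25, rel=1e-9)

    def test_spectral_identity(self, rng):
        # tr(W^T U W) = 0.5 ||W||_* for full-rank W, eps -> 0
        W = rng.standard_normal((4, 6))
        U = trace_norm_weight(W, eps=1e-15)
        assert np.trace(W.T @ U @ W) == pytest.approx(
            0.5 * trace_norm(W), rel=1e-6)

    def test_zero_matrix_finite_symmetric(self):
        U = trace_norm_weight(np.zeros((3, 2)), eps=1e-12)
        assert np.all(np.isfinite(U))
        np.testing.assert_allclose(U, U.T)


class TestSimplexUpdates:
    def test_theta_symmetric(self):
        np.testing.assert_allclose(update_theta([1.0, 1.0], 2.0), [0.5, 0.5])

    def test_theta_example(self):
        np.testing.assert_allclose(update_theta([1.0, 3.0], 2.0),
                                   [0.75, 0.25])

    def test_eta_example(self):
        np.testing.assert_allclose(update_eta([4.0, 1.0], 2.0), [0.2, 0.8])

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            update_theta([-1.0, 2.0], 2.0)

    def test_zero_losses_share_uniformly(self):
        np.testing.assert_allclose(update_theta([0.0, 0.0, 5.0], 2.0),
                                   [0.5, 0.5, 0.0])

    @pytest.mark.parametrize("g", [(1.0, 2.0, 4.0), (0.3, 0.9, 2.7)])
    def test_theta_matches_grid_search(self, g):
        # brute-force simplex oracle for min sum theta^2 * g
        best, best_val = None, np.inf
        steps = np.linspace(0, 1, 201)
        for t1, t2 in itertools.product(steps, steps):
            if t1 + t2 > 1:
                continue
            t = np.array([t1, t2, 1 - t1 - t2])
            val = np.sum(t ** 2 * np.asarray(g))
            if val < best_val:
                best, best_val = t, val
        np.testing.assert_allclose(update_theta(g, 2.0), best, atol=1e-2)

    def test_eta_matches_grid_search(self, rng):
        h = rng.uniform(0.5, 3.0, size=3)
        best, best_val = None, np.inf
        steps = np.linspace(0, 1, 201)
        for t1, t2 in itertools.product(steps, steps):
            if t1 + t2 > 1:
                continue
            t = np.array([t1, t2, 1 - t1 - t2])
            val = np.sum(t ** 2 * h)
            if val < best_val:
                best, best_val = t, val
        np.testing.assert_allclose(update_eta(h, 2.0), best, atol=1e-2)


class TestUpdateW0:
    def test_single_source(self, rng):
        W = rng.standard_normal((3, 2))
        np.testing.assert_allclose(update_W0([W], [1.0], 2.0), W)

    def test_equal_weights_mean(self, rng):
        Ws = [rng.standard_normal((3, 2)) for _ in range(3)]
        np.testing.assert_allclose(update_W0(Ws, [1 / 3] * 3, 2.0),
                                   np.mean(Ws, axis=0))

    def test_gradient_zero(self, rng):
        Ws = [rng.standard_normal((4, 2)) for _ in range(3)]
        eta = np.array([0.5, 0.3, 0.2])
        W0 = update_W0(Ws, eta, 2.0)
        grad = sum(2 * e ** 2 * (W0 - W) for e, W in zip(eta, Ws))
        assert np.abs(grad).max() < 1e-10


class TestWindowStop:
    def test_constant_trace_stops(self):
        assert window_stop([5.0] * 6, window=6, tol=1e-5)

    def test_short_trace_continues(self):
        assert not window_stop([1.0, 1.0, 1.0], window=6, tol=1e-5)

    def test_spread_above_tol_continues(self):
        assert not window_stop([1.0, 1.1, 1.0, 1.0, 1.0, 1.0],
                               window=6, tol=1e-5)


def _toy_problem(seed=0, S=2, n_per_class=8, c=2, d=3, **cfg_kw):
    cfg = SyntheticConfig(S=S, c=c, d=d, n_per_class=n_per_class,
                          source_shift=0.5, rotation_max=0.2, seed=seed,
                          **cfg_kw)
    sources, target, truth = generate(cfg)
    return sources, target, truth


class TestUpdateW:
    def _ops(self, seed=0):
        sources, target, _ = _toy_problem(seed)
        params = ProblemConfig(max_iter=3, seed=seed, k_neighbors=3)
        pl = pseudo_label(sources, target)
        ops = solver.build_source_operators(sources, target, pl, params, 2)
        return ops, params

    def test_reduction_to_weighted_least_squares(self, rng):
        ops, params = self._ops()
        op = ops[0]
        R = op.kmap.shape[0]
        F = rng.standard_normal((op.kmap.shape[1], 2))
        z = rng.uniform(0.5, 2.0, size=op.kmap.shape[1])
        W = update_W(1.0, np.zeros((R, R)), op.kmap, z, F, 0.0,
                     np.zeros(R), 0.0, np.zeros((R, 2)), 0.0,
                     np.zeros((R, R)), 2.0, 2.0, ridge=1e-14)
        KZ = op.kmap * z
        np.testing.assert_allclose(KZ @ op.kmap.T @ W, KZ @ F, atol=1e-6)

    def test_surrogate_decreases(self, rng):
        ops, params = self._ops()
        op = ops[0]
        R, N = op.kmap.shape
        W_old = rng.standard_normal((R, 2))
        F = rng.standard_normal((N, 2))
        z = irls_diag_l21(op.kmap.T @ W_old - F)
        g = irls_diag_l21(W_old)
        U = trace_norm_weight(W_old)
        W0 = rng.standard_normal((R, 2))

        def surrogate(W):
            T = op.kmap.T @ W - F
            return (0.25 * (np.sum(z[:, None] * T * T)
                            + np.einsum("ij,ik,jk->", op.C, W, W))
                    + 0.5 * np.sum(g[:, None] * W * W)
                    + 0.25 * np.sum((W - W0) ** 2)
                    + 2.0 * np.trace(W.T @ U @ W))

        W_new = update_W(0.5, op.C, op.kmap, z, F, 0.5, g, 0.5, W0, 2.0, U,
                         2.0, 2.0)
        assert surrogate(W_new) <= surrogate(W_old) + 1e-10


class TestUpdateF:
    def _setup(self, seed=1):
        sources, target, _ = _toy_problem(seed)
        params = ProblemConfig(max_iter=3, seed=seed, k_neighbors=3)
        pl = pseudo_label(sources, target)
        ops = solver.build_source_operators(sources, target, pl, params, 2)
        return ops[0], params

    def test_nonnegativity_preserved(self, rng):
        op, params = self._setup()
        N = op.kmap.shape[1]
        F = np.abs(rng.standard_normal((N, 2))) + 0.01
        W = rng.standard_normal((op.kmap.shape[0], 2))
        KtW = op.kmap.T @ W
        z = irls_diag_l21(KtW - F)
        F_new = solver.update_F(F, KtW, z, 0.5, op, params)
        assert np.all(F_new >= 0)

    def test_fixed_point_stays(self, rng):
        # At a KKT point the multiplicative factor is 1 for active entries:
        # verify a converged F barely moves under a further update.
        op, params = self._setup()
        N = op.kmap.shape[1]
        F = np.abs(rng.standard_normal((N, 2))) + 0.1
        W = rng.standard_normal((op.kmap.shape[0], 2))
        KtW = op.kmap.T @ W
        for _ in range(400):
            z = irls_diag_l21(KtW - F)
            F = solver.update_F(F, KtW, z, 0.5, op, params)
        z = irls_diag_l21(KtW - F)
        F_next = solver.update_F(F, KtW, z, 0.5, op, params)
        denom = np.abs(F).max()
        assert np.abs(F_next - F).max() / denom < 1e-4

    def test_descent_over_inner_repeats(self, rng):
        op, params = self._setup()
        N = op.kmap.shape[1]
        F = np.abs(rng.standard_normal((N, 2))) + 0.01
        W = rng.standard_normal((op.kmap.shape[0], 2))
        KtW = op.kmap.T @ W
        prev = np.inf
        for _ in range(5):
            z = irls_diag_l21(KtW - F)
            F_cand = solver.update_F(F, KtW, z, 0.5, op, params)
            F = solver._accept_F(F, F_cand, KtW, 0.5, op, params)
            val = solver._f_block_objective(F, KtW, 0.5, op, params)
            assert val <= prev * (1 + 1e-10) + 1e-12
            prev = val


class TestObjective:
    def test_all_zero(self):
        N, c, R = 4, 2, 4
        op = SourceOperators(
            kmap=np.eye(R), C=np.zeros((R, R)), Pi=np.zeros((N, N)),
            lap_degree=np.zeros(N), Y=np.zeros((N, c)), uconf=np.zeros(N))
        state = SolverState(W_list=[np.zeros((R, c))],
                            F_list=[np.zeros((N, c))],
                            W0=np.zeros((R, c)), theta=np.array([1.0]),
                            eta=np.array([1.0]))
        total, parts = objective(state, [op], ProblemConfig())
        assert total == 0.0

    def test_perfect_fit_zero(self, rng):
        # single source, all penalties off, K^T W = F
        N = 5
        K = rng.standard_normal((N, N))
        W = rng.standard_normal((N, 2))
        F = K.T @ W
        op = SourceOperators(
            kmap=K, C=np.zeros((N, N)), Pi=np.zeros((N, N)),
            lap_degree=np.zeros(N), Y=np.zeros((N, 2)), uconf=np.zeros(N))
        state = SolverState(W_list=[W], F_list=[F], W0=W,
                            theta=np.array([1.0]), eta=np.array([0.0]))
        params = ProblemConfig(alpha=0.0, beta=0.0, lam=0.0)
        total, _ = objective(state, [op], params)
        assert total == pytest.approx(0.0, abs=1e-10)

    def test_parts_sum(self, rng):
        sources, target, _ = _toy_problem(2)
        params = ProblemConfig(max_iter=2, seed=2, k_neighbors=3)
        pl = pseudo_label(sources, target)
        ops = solver.build_source_operators(sources, target, pl, params, 2)
        R = ops[0].kmap.shape[0]
        N = ops[0].kmap.shape[1]
        state = SolverState(
            W_list=[rng.standard_normal((R, 2)) for _ in ops],
            F_list=[np.abs(rng.standard_normal((N, 2))) for _ in ops],
            W0=rng.standard_normal((R, 2)),
            theta=np.array([0.4, 0.6]), eta=np.array([0.7, 0.3]))
        total, parts = objective(state, ops, params)
        assert total == pytest.approx(parts.total, rel=1e-12)
        # independently recompute the sparsity part
        sparse = params.beta * sum(l21_norm(W) for W in state.W_list)
        assert parts.sparsity == pytest.approx(sparse, rel=1e-12)
        tn = 0.5 * params.lam * trace_norm(np.hstack(state.W_list))
        assert parts.trace == pytest.approx(tn, rel=1e-12)


class TestFit:
    def test_separable_single_source_perfect_train(self):
        # S=1, target identical to the source, linearly separable classes
        rng = np.random.default_rng(7)
        y = np.repeat([1, 2], 10)
        X = rng.standard_normal((20, 2))
        X[y == 1, 0] += 4.0
        src = DomainDataset(X, y, name="s")
        tgt = DomainDataset(X.copy(), name="t")
        params = ProblemConfig(lam=0.0, max_iter=30, seed=7, k_neighbors=3)
        state = solver.fit([src], tgt, params, y, n_classes=2)
        op = solver.build_source_operators([src], tgt, y, params, 2)[0]
        scores = op.kmap.T @ state.W_list[0]
        pred = np.argmax(scores[:20], axis=1) + 1
        assert np.mean(pred == y) == 1.0

    def test_trace_monotone(self):
        sources, target, _ = _toy_problem(3, S=2)
        params = ProblemConfig(max_iter=10, seed=3, k_neighbors=3)
        pl = pseudo_label(sources, target)
        state = solver.fit(sources, target, params, pl, n_classes=2)
        tr = np.array(state.objective_trace)
        assert np.all(np.diff(tr) <= 1e-8 * np.abs(tr[:-1]))

    def test_deterministic(self):
        sources, target, _ = _toy_problem(4, S=2)
        params = ProblemConfig(max_iter=5, seed=11, k_neighbors=3)
        pl = pseudo_label(sources, target)
        s1 = solver.fit(sources, target, params, pl, n_classes=2)
        s2 = solver.fit(sources, target, params, pl, n_classes=2)
        assert s1.objective_trace == s2.objective_trace
        for a, b in zip(s1.W_list, s2.W_list):
            np.testing.assert_array_equal(a, b)

    def test_simplex_invariants(self):
        sources, target, _ = _toy_problem(5, S=3)
        params = ProblemConfig(max_iter=6, seed=5, k_neighbors=3)
        pl = pseudo_label(sources, target)
        state = solver.fit(sources, target, params, pl, n_classes=2)
        for vec in (state.theta, state.eta):
            assert vec.sum() == pytest.approx(1.0)
            assert np.all(vec >= 0)
        for F in state.F_list:
            assert np.all(F >= 0)

    def test_identical_sources_symmetric(self):
        rng = np.random.default_rng(9)
        y = np.repeat([1, 2], 8)
        X = rng.standard_normal((16, 3))
        X[y == 1, 0] += 3.0
        Xt = rng.standard_normal((12, 3))
        s1 = DomainDataset(X, y, name="a")
        s2 = DomainDataset(X.copy(), y.copy(), name="b")
        tgt = DomainDataset(Xt, name="t")
        params = ProblemConfig(max_iter=8, seed=1, k_neighbors=3)
        pl = pseudo_label([s1, s2], tgt)
        state = solver.fit([s1, s2], tgt, params, pl, n_classes=2)
        assert state.theta[0] == pytest.approx(state.theta[1], rel=1e-8)
        assert state.eta[0] == pytest.approx(state.eta[1], rel=1e-8)
        np.testing.assert_allclose(state.W_list[0], state.W_list[1],
                                   rtol=1e-8, atol=1e-12)


class TestConvergenceLemmas:
    """Numerical regression tests of the descent machinery."""

    def test_vector_inequality(self, rng):
        # ||v1|| - ||v1||^2/(2||v2||) <= ||v2|| - ||v2||^2/(2||v2||)
        for _ in range(100):
            v1 = rng.standard_normal(4)
            v2 = rng.standard_normal(4)
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            assert (n1 - n1 ** 2 / (2 * n2)
                    <= n2 - n2 ** 2 / (2 * n2) + 1e-12)

    def test_spd_trace_inequality(self, rng):
        # 0.5 tr(P Q^-1/2) - tr(P^1/2) >= 0.5 tr(Q Q^-1/2) - tr(Q^1/2)
        import scipy.linalg as sla
        for _ in range(50):
            A = rng.standard_normal((4, 4))
            B = rng.standard_normal((4, 4))
            P = A @ A.T + 0.1 * np.eye(4)
            Q = B @ B.T + 0.1 * np.eye(4)
            Qinv_sqrt = np.linalg.inv(sla.sqrtm(Q).real)
            lhs = 0.5 * np.trace(P @ Qinv_sqrt) - np.trace(sla.sqrtm(P).real)
            rhs = 0.5 * np.trace(Q @ Qinv_sqrt) - np.trace(sla.sqrtm(Q).real)
            assert lhs >= rhs - 1e-8
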