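"""Alternating IRLS optimizer for the joint multi-source objective.

The objective couples, per source ``a``:

* a robust regression loss ``||K_a^T W_a - F_a||_{2,1}`` against a
  nonnegative soft-label matrix ``F_a``,
* the MMD alignment quadratic form ``tr(W_a^T C_a W_a)``,
* label smoothness ``g(F_a)`` (confidence-weighted fit to the known labels
  plus a graph-Laplacian penalty),
* a row-sparsity penalty ``beta * ||W_a||_{2,1}``,

weighted by a learned simplex vector ``theta^{q1}`` on the first two
terms, plus across sources a model-alignment term
``sum_a eta_a^{q2} ||W_a - W0||_F^2`` and a trace-norm coupling
``lam/2 * ||[W_1,...,W_S]||_*``.

Each non-smooth norm is majorized by a weighted quadratic (IRLS); every
block update below minimizes (or at least never increases) its majorizer,
which makes the exact objective trace monotonically non-increasing per
sweep -- that monotonicity is asserted at runtime and in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .datasets_io import DomainDataset, ProblemConfig, ValidationError, one_hot
from .distribution_alignment import build_alignment
from .graphs import gamma_heuristic, knn_affinity
from .kernels import KernelSpec, build_empirical_kernel

__all__ = [
    "NumericalError",
    "SourceOperators",
    "ObjectiveParts",
    "SolverState",
    "l21_norm",
    "trace_norm",
    "irls_diag_l21",
    "trace_norm_weight",
    "objective",
    "update_W",
    "update_F",
    "update_theta",
    "update_eta",
    "update_W0",
    "window_stop",
    "fit",
]


class NumericalError(RuntimeError):
    """NaN/Inf or divergence inside the solver."""


# ---------------------------------------------------------------------------
# norms and IRLS weights


def l21_norm(A: np.ndarray) -> float:
    """Sum of the l2 norms of the rows."""
    return float(np.linalg.norm(A, axis=1).sum())


def trace_norm(A: np.ndarray) -> float:
    """Sum of singular values."""
    return float(np.linalg.svd(A, compute_uv=False).sum())


def irls_diag_l21(T: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Diagonal of the IRLS reweighting for the l2,1 norm.

    Entry ``i`` is ``1 / (2 ||T_i,:||_2 + eps)``; the additive guard keeps
    zero rows finite.  Returned as a 1-D vector of diagonal entries.
    """
    if eps <= 0:
        raise ValidationError("eps must be > 0")
    norms = np.linalg.norm(np.atleast_2d(T), axis=1)
    return 1.0 / (2.0 * norms + eps)


def trace_norm_weight(W: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """``U = 0.5 * (W W^T + eps I)^(-1/2)`` via symmetric eigendecomposition."""
    if eps <= 0:
        raise ValidationError("eps must be > 0")
    W = np.atleast_2d(W)
    S = W @ W.T
    vals, vecs = np.linalg.eigh(S)
    inv_sqrt = 1.0 / np.sqrt(np.maximum(vals, 0.0) + eps)
    return 0.5 * (vecs * inv_sqrt) @ vecs.T


# ---------------------------------------------------------------------------
# per-source problem data and solver state


@dataclass
class SourceOperators:
    """Everything precomputed for one source-target pair."""

    kmap: np.ndarray           # R x N empirical map matrix
    C: np.ndarray              # R x R combined MMD operator
    Pi: np.ndarray             # N x N affinity weights
    lap_degree: np.ndarray     # N, degrees (diagonal of Lambda)
    Y: np.ndarray              # N x c packed (true + pseudo) one-hot labels
    uconf: np.ndarray          # N, diagonal of the confidence matrix
    name: str = ""

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.lap_degree) - self.Pi


@dataclass
class ObjectiveParts:
    regression: float
    mmd: float
    smoothness: float
    sparsity: float
    alignment: float
    trace: float

    @property
    def total(self) -> float:
        return (self.regression + self.mmd + self.smoothness
                + self.sparsity + self.alignment + self.trace)


@dataclass
class SolverState:
    W_list: list
    F_list: list
    W0: np.ndarray
    theta: np.ndarray
    eta: np.ndarray
    Z_list: list = field(default_factory=list)
    G_list: list = field(default_factory=list)
    U: Optional[np.ndarray] = None
    objective_trace: list = field(default_factory=list)
    iter: int = 0
    converged: bool = False

    @property
    def W(self) -> np.ndarray:
        """Horizontal concatenation ``[W_1, ..., W_S]`` (R x S*c)."""
        return np.hstack(self.W_list)


# ---------------------------------------------------------------------------
# objective


def _smoothness(F: np.ndarray, op: SourceOperators, alpha: float) -> float:
    diff = F - op.Y
    fit = float(np.sum(op.uconf[:, None] * diff * diff))
    lap = float(np.einsum("ij,ik,jk->", op.Pi, F, F))  # sum Pi_ij <F_i,F_j>
    deg = float(np.sum(op.lap_degree[:, None] * F * F))
    return fit + alpha * (deg - lap)


def objective(
    state: SolverState, operators: Sequence[SourceOperators],
    params: ProblemConfig,
) -> tuple:
    """Exact objective value (true norms, no IRLS surrogates) + its parts."""
    reg = mmd_part = smooth = sparse = 0.0
    for a, op in enumerate(operators):
        W, F = state.W_list[a], state.F_list[a]
        th = state.theta[a] ** params.q1
        T = op.kmap.T @ W - F
        reg += th * l21_norm(T)
        mmd_part += th * float(np.einsum("ij,ik,jk->", op.C, W, W))
        sm = _smoothness(F, op, params.alpha)
        smooth += th * sm if params.theta_weight_smoothness else sm
        sparse += params.beta * l21_norm(W)
    align = float(sum(
        e ** params.q2 * np.sum((W - state.W0) ** 2)
        for e, W in zip(state.eta, state.W_list)
    ))
    tn = 0.5 * params.lam * trace_norm(state.W)
    parts = ObjectiveParts(reg, mmd_part, smooth, sparse, align, tn)
    for name in ("regression", "mmd", "smoothness", "sparsity",
                 "alignment", "trace"):
        if not np.isfinite(getattr(parts, name)):
            raise NumericalError(f"objective part {name!r} is not finite")
    return parts.total, parts


# ---------------------------------------------------------------------------
# block updates


def update_W(
    theta_a: float,
    C: np.ndarray,
    K: np.ndarray,
    z_diag: np.ndarray,
    F: np.ndarray,
    beta: float,
    g_diag: np.ndarray,
    eta_a: float,
    W0: np.ndarray,
    lam: float,
    U: np.ndarray,
    q1: float,
    q2: float,
    ridge: float = 1e-10,
) -> np.ndarray:
    """SPD solve for one source model with all IRLS weights frozen.

    Minimizes ``theta^q1 (tr(T^T Z T) + tr(W^T C W)) + beta tr(W^T G W)
    + eta^q2 ||W - W0||_F^2 + lam tr(W^T U W)`` over ``W``
    (``T = K^T W - F``), i.e. solves

        [theta^q1 (C + K Z K^T) + beta G + eta^q2 I + lam U + ridge I] W
            = theta^q1 K Z F + eta^q2 W0
    """
    th = theta_a ** q1
    et = eta_a ** q2
    R = K.shape[0]
    KZ = K * z_diag[None, :]
    A = th * (C + KZ @ K.T) + lam * U
    A[np.diag_indices_from(A)] += beta * g_diag + et
    A[np.diag_indices_from(A)] += ridge * (np.trace(A) / R + 1.0) * 1.0
    B = th * (KZ @ F) + et * W0
    try:
        return scipy.linalg.solve(A, B, assume_a="pos")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"W-update system not SPD: {exc}") from exc


def update_F(
    F: np.ndarray,
    KtW: np.ndarray,
    z_diag: np.ndarray,
    theta_a: float,
    op: SourceOperators,
    params: ProblemConfig,
    delta: float = 1e-12,
) -> np.ndarray:
    """One multiplicative, nonnegativity-preserving step on ``F``.

    Positive and negative parts of the gradient terms are split across
    numerator and denominator as in standard nonnegative factorization
    updates; ``delta`` guards the division.
    """
    th = theta_a ** params.q1
    ZKtW = z_diag[:, None] * KtW
    pos = np.maximum(ZKtW, 0.0)
    neg = np.maximum(-ZKtW, 0.0)
    u = op.uconf[:, None]
    numer = (th * pos + u * op.Y + params.alpha * (op.Pi @ F)
             + params.zeta * F)
    denom = (th * (z_diag[:, None] * F + neg) + u * F
             + params.alpha * op.lap_degree[:, None] * F
             + params.zeta * F @ (F.T @ F) + delta)
    return np.maximum(F * numer / denom, 0.0)


def _f_block_objective(F, KtW, theta_a, op, params) -> float:
    th = theta_a ** params.q1
    sm = _smoothness(F, op, params.alpha)
    if params.theta_weight_smoothness:
        sm *= th
    return th * l21_norm(KtW - F) + sm


def _accept_F(F_old, F_cand, KtW, theta_a, op, params, max_halvings=25):
    """Damped acceptance: keep halving the step until the exact F-block
    objective does not increase (t -> 0 recovers the old iterate, so the
    sweep-level objective trace stays monotone)."""
    base = _f_block_objective(F_old, KtW, theta_a, op, params)
    t = 1.0
    for _ in range(max_halvings):
        F_try = F_old + t * (F_cand - F_old)
        if _f_block_objective(F_try, KtW, theta_a, op, params) <= base * (1 + 1e-12) + 1e-15:
            return F_try
        t *= 0.5
    return F_old


def _w_block_objective(W, F, op, theta_a, eta_a, W0, W_others_left,
                       W_others_right, params) -> float:
    th = theta_a ** params.q1
    val = th * (l21_norm(op.kmap.T @ W - F)
                + float(np.einsum("ij,ik,jk->", op.C, W, W)))
    val += params.beta * l21_norm(W)
    val += eta_a ** params.q2 * float(np.sum((W - W0) ** 2))
    concat = np.hstack(W_others_left + [W] + W_others_right)
    val += 0.5 * params.lam * trace_norm(concat)
    return val


def _accept_W(W_old, W_cand, F, op, theta_a, eta_a, W0, left, right, params,
              max_halvings=25):
    """Damped acceptance for the W solve.

    The eps-regularized trace-norm weight is not an exact majorizer when W
    has near-zero singular values, so the SPD solve can raise the exact
    objective by O(eps); every term is convex along the segment to the old
    iterate, so halving the step restores monotone descent.
    """
    base = _w_block_objective(W_old, F, op, theta_a, eta_a, W0, left, right,
                              params)
    t = 1.0
    for _ in range(max_halvings):
        W_try = W_old + t * (W_cand - W_old)
        val = _w_block_objective(W_try, F, op, theta_a, eta_a, W0, left,
                                 right, params)
        if val <= base * (1 + 1e-12) + 1e-15:
            return W_try
        t *= 0.5
    return W_old


def _simplex_from_losses(values: np.ndarray, q: float) -> np.ndarray:
    """Closed-form simplex minimizer of ``sum w_a^q * v_a``.

    ``w_a ~ v_a^{1/(1-q)}``; zero-loss entries absorb all weight uniformly
    among themselves (the limit of the formula).
    """
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValidationError("losses must be nonnegative")
    zero = v <= 0
    if zero.any():
        out = zero.astype(float)
        return out / out.sum()
    p = 1.0 / (1.0 - q)
    w = (v / v.max()) ** p
    return w / w.sum()


def update_theta(g: Sequence[float], q1: float) -> np.ndarray:
    """Source weights from per-source losses (closed form on the simplex)."""
    return _simplex_from_losses(np.asarray(g, dtype=float), q1)


def update_eta(h: Sequence[float], q2: float) -> np.ndarray:
    """Alignment weights from per-source gaps ``||W_a - W0||_F^2``."""
    return _simplex_from_losses(np.asarray(h, dtype=float), q2)


def update_W0(W_list: Sequence[np.ndarray], eta: Sequence[float],
              q2: float) -> np.ndarray:
    """Reference model: the ``eta^{q2}``-normalized convex combination."""
    eta = np.asarray(eta, dtype=float)
    w = eta ** q2
    tot = w.sum()
    if tot <= 0:
        w = np.full_like(eta, 1.0 / eta.size)
        tot = 1.0
    w = w / tot
    return sum(wi * W for wi, W in zip(w, W_list))


def window_stop(trace: Sequence[float], window: int, tol: float) -> bool:
    """Relative spread of the last ``window`` objective values below ``tol``."""
    if len(trace) < window:
        return False
    tail = np.asarray(trace[-window:], dtype=float)
    hi, lo = tail.max(), tail.min()
    denom = abs(hi) if hi != 0 else 1.0
    return (hi - lo) / denom < tol


# ---------------------------------------------------------------------------
# precomputation + main loop


def build_source_operators(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    target_pseudo_labels: np.ndarray,
    params: ProblemConfig,
    n_classes: int,
) -> list:
    """Algorithm step 1: kernels, graphs, MMD operators, label matrices."""
    specs = tuple(
        KernelSpec(family=f, sigma=params.kernel_sigma)
        for f in params.kernel_families
    )
    ops = []
    map_dims = set()
    for src in sources:
        ek = build_empirical_kernel(src, target, specs,
                                    standardize=params.standardize)
        packed_labels = np.concatenate([src.labels, target_pseudo_labels])
        gamma = (gamma_heuristic(ek.packed_data, n_classes)
                 if params.gamma == "auto" else float(params.gamma))
        graph = knn_affinity(ek.packed_data, packed_labels,
                             params.k_neighbors, gamma,
                             label_aware=params.label_aware_graph)
        lm = one_hot(packed_labels, n_classes)
        uconf = np.empty(ek.n_packed)
        uconf[: ek.n_source] = params.varsigma
        uconf[ek.n_source:] = params.varsigma * params.rho
        align = build_alignment(ek, src.labels, target_pseudo_labels,
                                n_classes)
        ops.append(SourceOperators(
            kmap=ek.kmap, C=align.C, Pi=graph.weights,
            lap_degree=graph.weights.sum(axis=1),
            Y=lm.indicator, uconf=uconf, name=src.name,
        ))
        map_dims.add(ek.map_dim)
    if len(map_dims) > 1:
        raise ValidationError(
            "all sources must share the model row dimension (equalize the "
            f"source sizes for non-linear kernels); got {sorted(map_dims)}"
        )
    return ops


def fit(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    params: ProblemConfig,
    target_pseudo_labels: np.ndarray,
    n_classes: Optional[int] = None,
    operators: Optional[Sequence[SourceOperators]] = None,
) -> SolverState:
    """Run the full alternating optimization and return the final state.

    Every source's initial model is drawn from an identically seeded
    generator, so identical sources stay exactly symmetric throughout.
    """
    if n_classes is None:
        n_classes = int(max(max(s.labels.max() for s in sources),
                            np.max(target_pseudo_labels, initial=0)))
    if operators is None:
        operators = build_source_operators(
            sources, target, target_pseudo_labels, params, n_classes)
    S = len(operators)
    c = n_classes
    R = operators[0].kmap.shape[0]

    W_list, F_list = [], []
    for op in operators:
        rng = np.random.default_rng(params.seed)  # same seed per block
        # Warm start: ridge fit of the packed label matrix plus seeded
        # noise.  A purely random tiny init leaves the l2,1 IRLS weights
        # 1/(2||W_row||) enormous and traps W in the zero-row basin.
        K = op.kmap
        A = K @ K.T
        A[np.diag_indices_from(A)] += 1e-6 * (np.trace(A) / R + 1.0)
        W = np.linalg.solve(A, K @ op.Y)
        W += 0.01 * np.abs(W).max() * rng.standard_normal((R, c))
        W_list.append(W)
        # F must start nonnegative and strictly interior for the
        # multiplicative updates to move; clip K^T W and lift slightly.
        F_list.append(np.maximum(op.kmap.T @ W, 0.0) + 1e-3)

    state = SolverState(
        W_list=W_list,
        F_list=F_list,
        W0=np.mean(W_list, axis=0),
        theta=np.full(S, 1.0 / S),
        eta=np.full(S, 1.0 / S),
    )
    total, _ = objective(state, operators, params)
    state.objective_trace.append(total)

    bad_streak = 0
    for sweep in range(params.max_iter):
        state.W0 = update_W0(state.W_list, state.eta, params.q2)
        state.U = trace_norm_weight(state.W, eps=params.irls_eps)

        # theta from the exact per-source losses (closed-form minimizer of
        # the theta-part of the objective, so this step always descends)
        g_true = []
        for a, op in enumerate(operators):
            T = op.kmap.T @ state.W_list[a] - state.F_list[a]
            g_a = l21_norm(T) + float(
                np.einsum("ij,ik,jk->", op.C, state.W_list[a], state.W_list[a]))
            if params.theta_weight_smoothness:
                g_a += _smoothness(state.F_list[a], op, params.alpha)
            g_true.append(g_a)
        state.theta = update_theta(g_true, params.q1)

        state.G_list, state.Z_list = [], []
        for a, op in enumerate(operators):
            W, F = state.W_list[a], state.F_list[a]
            g_diag = irls_diag_l21(W, eps=params.irls_eps)
            KtW = op.kmap.T @ W
            z_diag = irls_diag_l21(KtW - F, eps=params.irls_eps)

            F_cand = update_F(F, KtW, z_diag, state.theta[a], op, params)
            F = _accept_F(F, F_cand, KtW, state.theta[a], op, params)
            state.F_list[a] = F

            # relinearize the regression loss at the fresh F before the solve
            z_diag = irls_diag_l21(KtW - F, eps=params.irls_eps)
            W_cand = update_W(
                state.theta[a], op.C, op.kmap, z_diag, F, params.beta,
                g_diag, state.eta[a], state.W0, params.lam, state.U,
                params.q1, params.q2, ridge=params.ridge,
            )
            state.W_list[a] = _accept_W(
                W, W_cand, F, op, state.theta[a], state.eta[a], state.W0,
                state.W_list[:a], state.W_list[a + 1:], params,
            )
            state.G_list.append(g_diag)
            state.Z_list.append(z_diag)

        h = [float(np.sum((W - state.W0) ** 2)) for W in state.W_list]
        state.eta = update_eta(h, params.q2)

        total, _ = objective(state, operators, params)
        prev = state.objective_trace[-1]
        state.objective_trace.append(total)
        state.iter = sweep + 1
        if total > prev * (1 + 1e-6) + 1e-12:
            bad_streak += 1
            if bad_streak >= 3:
                raise NumericalError(
                    f"objective diverged for 3 consecutive sweeps "
                    f"(last {prev:.6g} -> {total:.6g}); "
                    f"theta={state.theta}, eta={state.eta}"
                )
        else:
            bad_streak = 0
        if window_stop(state.objective_trace, params.window, params.tol):
            state.converged = True
            break
    else:
        if not window_stop(state.objective_trace, params.window, params.tol):
            warnings.warn("solver hit max_iter without window convergence",
                          stacklevel=2)
    return state
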