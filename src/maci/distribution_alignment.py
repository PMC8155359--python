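"""Marginal + class-conditional MMD operators and model-discrepancy metrics.

The squared empirical MMD between a source and the target in the span of
the empirical kernel map is the quadratic form ``tr(W^T C W)`` where
``C = K M K^T`` and ``M`` is a rank-one coefficient matrix built from the
domain sizes.  The class-conditional terms repeat the construction on the
class-restricted index sets (using pseudo-labels on the target side) and
everything is summed into a single PSD operator ``C`` in the row space of
the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets_io import ValidationError
from .kernels import EmpiricalKernel

__all__ = [
    "AlignmentOperators",
    "ModelAlignmentReport",
    "alignment_report",
    "mmd_coeff_marginal",
    "mmd_coeff_conditional",
    "build_alignment",
    "mdd",
    "maf",
]


@dataclass
class AlignmentOperators:
    """Combined MMD operator for one source-target pair."""

    M_marginal: np.ndarray                 # N x N, rank one
    M_class: list                          # per surviving class, on class subsets
    C: np.ndarray                          # R x R, matches model row space
    class_index_sets: dict = field(default_factory=dict)
    skipped_classes: list = field(default_factory=list)


def _mmd_vector(n_source: int, n_target: int) -> np.ndarray:
    v = np.empty(n_source + n_target)
    v[:n_source] = 1.0 / n_source
    v[n_source:] = -1.0 / n_target
    return v


def mmd_coeff_marginal(n_source: int, n_target: int) -> np.ndarray:
    """Rank-one MMD coefficient matrix ``v v^T``.

    Entries: ``1/n_s^2`` on the source block, ``1/n_t^2`` on the target
    block and ``-1/(n_s n_t)`` across; every row sums to zero.
    """
    if n_source < 1 or n_target < 1:
        raise ValidationError("both domains must be non-empty")
    v = _mmd_vector(n_source, n_target)
    return np.outer(v, v)


def mmd_coeff_conditional(
    class_sizes_source: Sequence[int], class_sizes_target: Sequence[int]
) -> list:
    """Per-class coefficient matrices on the class-restricted sample sets.

    Classes empty in either domain are skipped (their 1/n^2 entries would
    be undefined); the returned list covers surviving classes in order.
    """
    cs = np.asarray(class_sizes_source, dtype=int)
    ct = np.asarray(class_sizes_target, dtype=int)
    if cs.shape != ct.shape:
        raise ValidationError("class size vectors must have equal length")
    out = []
    for ns, nt in zip(cs, ct):
        if ns == 0 or nt == 0:
            continue
        out.append(mmd_coeff_marginal(int(ns), int(nt)))
    if not out:
        warnings.warn(
            "no class is populated in both domains; conditional MMD omitted",
            stacklevel=2,
        )
    return out


def build_alignment(
    ek: EmpiricalKernel,
    source_labels: np.ndarray,
    target_pseudo_labels: np.ndarray,
    n_classes: Optional[int] = None,
) -> AlignmentOperators:
    """Assemble ``C = K M K^T + sum_l K_l M_l K_l^T`` for one pair.

    ``K`` is the (possibly stacked) ``R x N`` map matrix; the conditional
    terms restrict its columns to each class's source+target index set, so
    the sum lives in a single ``R x R`` frame and stays PSD.
    """
    source_labels = np.asarray(source_labels, dtype=int)
    target_pseudo_labels = np.asarray(target_pseudo_labels, dtype=int)
    n_s, n_t = ek.n_source, ek.n_target
    if source_labels.shape != (n_s,) or target_pseudo_labels.shape != (n_t,):
        raise ValidationError("label vectors must match the packed layout")
    if n_classes is None:
        n_classes = int(max(source_labels.max(initial=0),
                            target_pseudo_labels.max(initial=0)))

    K = ek.kmap                            # R x N
    M0 = mmd_coeff_marginal(n_s, n_t)
    C = K @ M0 @ K.T

    M_class, index_sets, skipped = [], {}, []
    for cls in range(1, n_classes + 1):
        src_idx = np.flatnonzero(source_labels == cls)
        tgt_idx = n_s + np.flatnonzero(target_pseudo_labels == cls)
        if src_idx.size == 0 or tgt_idx.size == 0:
            skipped.append(cls)
            continue
        idx = np.concatenate([src_idx, tgt_idx])
        Ml = mmd_coeff_marginal(src_idx.size, tgt_idx.size)
        Kl = K[:, idx]
        C += Kl @ Ml @ Kl.T
        M_class.append(Ml)
        index_sets[cls] = idx
    C = 0.5 * (C + C.T)                    # kill numerical asymmetry
    return AlignmentOperators(
        M_marginal=M0, M_class=M_class, C=C,
        class_index_sets=index_sets, skipped_classes=skipped,
    )


@dataclass
class ModelAlignmentReport:
    """Model-discrepancy metrics for a set of source models.

    For two models with simplex-uniform weights the alignment value is at
    least a quarter of their squared Frobenius distance for any reference
    (parallelogram bound), with equality exactly when the reference is the
    convex combination.
    """

    mdd: float
    maf: float
    eta: np.ndarray
    w0_mode: str  # {"given", "convex_combination"}


def alignment_report(W_list: Sequence[np.ndarray], eta: Sequence[float],
                     W0="convex") -> ModelAlignmentReport:
    """Convenience bundle of :func:`mdd` (max over pairs) and :func:`maf`."""
    pairs = [
        mdd(W_list[i], W_list[j])
        for i in range(len(W_list)) for j in range(i + 1, len(W_list))
    ]
    return ModelAlignmentReport(
        mdd=max(pairs) if pairs else 0.0,
        maf=maf(W_list, eta, W0),
        eta=np.asarray(eta, dtype=float),
        w0_mode="convex_combination" if isinstance(W0, str) else "given",
    )


def mdd(W_P: np.ndarray, W_Q: np.ndarray) -> float:
    """Squared Frobenius distance between two domain models."""
    W_P = np.asarray(W_P, dtype=float)
    W_Q = np.asarray(W_Q, dtype=float)
    if W_P.shape != W_Q.shape:
        raise ValidationError("model shapes differ")
    return float(np.sum((W_P - W_Q) ** 2))


def maf(W_list: Sequence[np.ndarray], eta: Sequence[float], W0="convex") -> float:
    """Weighted spread of source models around a reference.

    ``sum_a eta_a * ||W_a - W0||_F^2`` with ``eta`` on the simplex; with
    ``W0="convex"`` the reference is the eta-convex combination of the
    models (for two models this equals ``eta_1*eta_2`` times their squared
    Frobenius distance).
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0) or abs(eta.sum() - 1.0) > 1e-10:
        raise ValidationError("eta must lie on the probability simplex")
    W_arr = [np.asarray(W, dtype=float) for W in W_list]
    if len(W_arr) != eta.size:
        raise ValidationError("one weight per model required")
    if isinstance(W0, str):
        if W0 != "convex":
            raise ValidationError("W0 must be a matrix or 'convex'")
        W0 = sum(e * W for e, W in zip(eta, W_arr))
    else:
        W0 = np.asarray(W0, dtype=float)
    return float(sum(e * np.sum((W - W0) ** 2) for e, W in zip(eta, W_arr)))
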