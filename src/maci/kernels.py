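"""Kernel functions and the empirical kernel map over packed data.

Data follows the column-sample convention here: a domain with ``n`` samples
in ``d`` dimensions is a ``d x n`` matrix.  A source and the target are
packed side by side into ``X = [X_src | X_tgt]`` (``d x N``) and the model
lives in the row space of the map matrix ``K`` (``R x N``): ``R = N`` for a
single non-linear kernel, ``R = d`` for the linear kernel, and the vertical
stack of per-kernel blocks for a multi-kernel list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .datasets_io import DomainDataset, ValidationError

__all__ = ["KernelSpec", "EmpiricalKernel", "gram", "empirical_map",
           "build_empirical_kernel"]

FAMILIES = ("linear", "gaussian", "laplacian", "inverse_square_distance",
            "inverse_distance")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus bandwidth; ``sigma="auto"`` resolves to 1/d."""

    family: str = "gaussian"
    sigma: object = "auto"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown kernel family {self.family!r}; choose from {FAMILIES}"
            )
        if self.sigma != "auto":
            if not np.isreal(self.sigma) or float(self.sigma) <= 0:
                raise ValidationError("kernel sigma must be 'auto' or a real > 0")

    def resolve_sigma(self, d: int) -> float:
        if self.sigma == "auto":
            return 1.0 / d
        return float(self.sigma)


@dataclass
class EmpiricalKernel:
    """Precomputed empirical map for one packed source-target pair.

    ``kmap`` is the ``R x N`` map matrix: column ``j`` is the empirical-map
    image of packed point ``j``.  For a single non-linear kernel this is the
    ``N x N`` Gram matrix; for the linear kernel it is the packed data
    itself; for multiple kernels the blocks are stacked vertically.
    """

    packed_data: np.ndarray        # d x N
    kmap: np.ndarray               # R x N
    specs: tuple
    source_mask: np.ndarray        # length N, True on source columns

    @property
    def n_packed(self) -> int:
        return self.packed_data.shape[1]

    @property
    def n_source(self) -> int:
        return int(self.source_mask.sum())

    @property
    def n_target(self) -> int:
        return self.n_packed - self.n_source

    @property
    def map_dim(self) -> int:
        return self.kmap.shape[0]


def gram(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Kernel matrix between the columns of ``A`` (d x m) and ``B`` (d x n)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValidationError(
            f"dimension mismatch: {A.shape[0]} vs {B.shape[0]}"
        )
    if spec.family == "linear":
        return A.T @ B
    sigma = spec.resolve_sigma(A.shape[0])
    if spec.family == "gaussian":
        sq = cdist(A.T, B.T, metric="sqeuclidean")
        return np.exp(-sigma * sq)
    if spec.family == "laplacian":
        dist = cdist(A.T, B.T, metric="euclidean")
        return np.exp(-sigma * dist)
    if spec.family == "inverse_square_distance":
        sq = cdist(A.T, B.T, metric="sqeuclidean")
        return 1.0 / (1.0 + sigma * sq)
    # inverse_distance
    dist = cdist(A.T, B.T, metric="euclidean")
    return 1.0 / (1.0 + sigma * dist)


def _map_block(spec: KernelSpec, packed: np.ndarray, points: np.ndarray) -> np.ndarray:
    """One kernel's contribution to the map of ``points`` (d x m)."""
    if spec.family == "linear":
        return points
    return gram(spec, packed, points)


def empirical_map(ek: EmpiricalKernel, x: np.ndarray) -> np.ndarray:
    """Map a single point (or d x m batch) into the model's row space."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    pts = x[:, None] if single else x
    if pts.shape[0] != ek.packed_data.shape[0]:
        raise ValidationError(
            f"point dimension {pts.shape[0]} does not match "
            f"d={ek.packed_data.shape[0]}"
        )
    blocks = [_map_block(spec, ek.packed_data, pts) for spec in ek.specs]
    out = np.vstack(blocks)
    return out[:, 0] if single else out


def build_empirical_kernel(
    source: DomainDataset,
    target: DomainDataset,
    specs: Sequence[KernelSpec],
    standardize: bool = False,
) -> EmpiricalKernel:
    """Pack ``[source | target]`` columns and precompute the map matrix."""
    specs = tuple(specs)
    if not specs:
        raise ValidationError("at least one kernel spec is required")
    if source.d != target.d:
        raise ValidationError("source/target dimensionality mismatch")
    packed = np.hstack([source.features.T, target.features.T])  # d x N
    if standardize:
        mu = packed.mean(axis=1, keepdims=True)
        sd = packed.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        packed = (packed - mu) / sd
    kmap = np.vstack([_map_block(s, packed, packed) for s in specs])
    mask = np.zeros(packed.shape[1], dtype=bool)
    mask[: source.n] = True
    return EmpiricalKernel(packed_data=packed, kmap=kmap, specs=specs,
                           source_mask=mask)
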