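"""Class-aware k-NN affinity graphs and their Laplacians.

The graph is built on the packed source+target columns (pseudo-labels fill
in the target side) so that the Laplacian matches the ``N x c`` label
matrix it smooths.  An edge exists when either endpoint is among the
other's k nearest neighbours; with ``label_aware=True`` edges between
differently labelled points are dropped (the supervised construction),
otherwise every neighbour pair gets the heat-kernel weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .datasets_io import ValidationError

__all__ = ["AffinityGraph", "gamma_heuristic", "knn_affinity", "laplacian"]


@dataclass
class AffinityGraph:
    weights: np.ndarray    # symmetric N x N, zero diagonal
    gamma: float
    k: int

    @property
    def degree(self) -> np.ndarray:
        return np.diag(self.weights.sum(axis=1))

    @property
    def laplacian(self) -> np.ndarray:
        return self.degree - self.weights


def gamma_heuristic(X: np.ndarray, c: int) -> float:
    """Affinity bandwidth: sqrt(mean column norm of ``X``) divided by c.

    ``X`` is ``d x N`` (columns = samples).  All-zero data falls back to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValidationError("empty data")
    mean_norm = float(np.linalg.norm(X, axis=0).mean())
    if mean_norm == 0.0:
        warnings.warn("all-zero data; falling back to gamma=1", stacklevel=2)
        return 1.0
    return np.sqrt(mean_norm) / c


def knn_affinity(
    X: np.ndarray,
    labels: np.ndarray,
    k: int,
    gamma: float,
    label_aware: bool = True,
) -> AffinityGraph:
    """Symmetric k-NN heat-kernel affinity over the columns of ``X``.

    Neighbourhoods are exact (brute force, Euclidean); distance ties break
    toward the lower sample index for determinism.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = X.shape[1]
    if k >= n:
        raise ValidationError(f"k={k} must be < N={n}")
    if labels.shape != (n,):
        raise ValidationError("labels must have one entry per column of X")

    sq = squareform(pdist(X.T, metric="sqeuclidean"))
    # self-distance pushed to +inf so a point is never its own neighbour
    np.fill_diagonal(sq, np.inf)
    # stable argsort => ties broken by lower index
    order = np.argsort(sq, axis=1, kind="stable")
    neigh = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    neigh[rows, order[:, :k].ravel()] = True
    edges = neigh | neigh.T

    np.fill_diagonal(sq, 0.0)
    W = np.where(edges, np.exp(-gamma * sq), 0.0)
    if label_aware:
        same = labels[:, None] == labels[None, :]
        W = np.where(same, W, 0.0)
    np.fill_diagonal(W, 0.0)
    return AffinityGraph(weights=W, gamma=float(gamma), k=int(k))


def laplacian(graph: AffinityGraph) -> np.ndarray:
    """Combinatorial Laplacian ``L = D - W`` (rows sum to zero, PSD)."""
    return graph.laplacian
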