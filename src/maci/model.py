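"""User-facing estimator: pseudo-labeling, fit, ensemble prediction,
row ranking and empirical chance-level estimation."""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.stats

from . import solver
from .datasets_io import (DomainDataset, ProblemConfig, ValidationError,
                          one_hot, validate_problem)
from .kernels import EmpiricalKernel, KernelSpec, empirical_map

__all__ = [
    "RidgeScorer",
    "MaciModel",
    "ChanceLevel",
    "pseudo_label",
    "fit_maci",
    "predict",
    "rank_rows",
    "empirical_chance_level",
    "save_model",
    "load_model",
]


class RidgeScorer:
    """Built-in regularized least-squares one-vs-all scorer.

    Used as the default base classifier for pseudo-labeling; any object
    with sklearn-style ``fit(X, y)`` / ``predict(X)`` can replace it.
    """

    def __init__(self, reg: float = 1.0):
        self.reg = float(reg)
        self.coef_: Optional[np.ndarray] = None
        self.classes_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RidgeScorer":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        c = self.classes_.size
        remap = {cls: i + 1 for i, cls in enumerate(self.classes_)}
        Y = one_hot([remap[v] for v in y], c).indicator
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])  # intercept
        A = Xa.T @ Xa
        A[np.diag_indices_from(A)] += self.reg
        self.coef_ = np.linalg.solve(A, Xa.T @ Y)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xa = np.hstack([X, np.ones((X.shape[0], 1))])
        return Xa @ self.coef_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


@dataclass
class MaciModel:
    """Fitted artifacts needed for prediction."""

    packed_list: list                  # per source, d x N packed data
    source_masks: list                 # per source, boolean mask of columns
    specs: tuple                       # kernel specs shared by all sources
    W_list: list
    theta: np.ndarray
    W0: np.ndarray
    n_classes: int
    codebook: Optional[dict] = None
    config: Optional[ProblemConfig] = None
    objective_trace: list = field(default_factory=list)
    eta: Optional[np.ndarray] = None

    @property
    def d(self) -> int:
        return self.packed_list[0].shape[0]

    def _kernel(self, a: int) -> EmpiricalKernel:
        return EmpiricalKernel(
            packed_data=self.packed_list[a],
            kmap=np.empty((0, 0)),
            specs=self.specs,
            source_mask=self.source_masks[a],
        )


def pseudo_label(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    base_classifier=None,
) -> np.ndarray:
    """Label the target with a classifier trained on pooled source data."""
    if target.n == 0:
        return np.empty(0, dtype=int)
    X = np.vstack([s.features for s in sources])
    y = np.concatenate([s.labels for s in sources])
    clf = base_classifier if base_classifier is not None else RidgeScorer()
    clf.fit(X, y)
    pred = np.asarray(clf.predict(target.features), dtype=int)
    missing = sorted(set(np.unique(y)) - set(np.unique(pred)))
    if missing:
        warnings.warn(
            f"classes {missing} never predicted on the target; their "
            "conditional alignment terms will be skipped", stacklevel=2)
    return pred


def fit_maci(
    sources: Sequence[DomainDataset],
    target: DomainDataset,
    config: Optional[ProblemConfig] = None,
    base_classifier=None,
) -> MaciModel:
    """End-to-end fit: validate, pseudo-label, optimize, package."""
    config = config or ProblemConfig()
    summary = validate_problem(sources, target)
    c = summary.n_classes
    pseudo = pseudo_label(sources, target, base_classifier)

    state = solver.fit(sources, target, config, pseudo, n_classes=c)
    if config.refresh_pseudo_labels:
        model = _package(sources, target, config, state, c)
        refreshed, _ = predict(model, target.features)
        if not np.array_equal(refreshed, pseudo):
            state = solver.fit(sources, target, config, refreshed,
                               n_classes=c)
    return _package(sources, target, config, state, c)


def _package(sources, target, config, state, c) -> MaciModel:
    packed, masks = [], []
    for src in sources:
        Xp = np.hstack([src.features.T, target.features.T])
        mask = np.zeros(Xp.shape[1], dtype=bool)
        mask[: src.n] = True
        packed.append(Xp)
        masks.append(mask)
    specs = tuple(KernelSpec(family=f, sigma=config.kernel_sigma)
                  for f in config.kernel_families)
    codebook = next((s.codebook for s in sources if s.codebook), None)
    return MaciModel(
        packed_list=packed, source_masks=masks, specs=specs,
        W_list=list(state.W_list), theta=np.asarray(state.theta),
        W0=np.asarray(state.W0), n_classes=c, codebook=codebook,
        config=config, objective_trace=list(state.objective_trace),
        eta=np.asarray(state.eta),
    )


def predict(model: MaciModel, X_test: np.ndarray, mode: Optional[str] = None):
    """Classify test rows; returns ``(labels, scores)``.

    ``mode="sum"`` (default) scores with the theta-weighted vote of the
    per-source models -- the closed-form minimizer of the weighted residue
    to each source's projection.  ``mode="w0"`` scores with the shared
    reference model alone (averaged over the per-source kernel maps).
    Argmax ties break toward the lowest class index.
    """
    mode = mode or (model.config.predict_mode if model.config else "sum")
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    if X_test.shape[1] != model.d:
        raise ValidationError(
            f"test dimensionality {X_test.shape[1]} != model d={model.d}")
    m = X_test.shape[0]
    scores = np.zeros((m, model.n_classes))
    for a in range(len(model.packed_list)):
        kmat = empirical_map(model._kernel(a), X_test.T)  # R x m
        if mode == "sum":
            scores += model.theta[a] * (kmat.T @ model.W_list[a])
        elif mode == "w0":
            scores += (kmat.T @ model.W0) / len(model.packed_list)
        else:
            raise ValidationError(f"unknown predict mode {mode!r}")
    labels = np.argmax(scores, axis=1) + 1
    return labels, scores


def rank_rows(W: np.ndarray):
    """Rows of a fitted model sorted by decreasing l2 norm.

    With the linear kernel, rows correspond to original features (feature
    selection); with empirical maps they correspond to packed training
    prototypes.  Ties keep the lower index first (stable sort).
    """
    norms = np.linalg.norm(np.atleast_2d(W), axis=1)
    order = np.argsort(-norms, kind="stable")
    return order, norms[order]


@dataclass
class ChanceLevel:
    mean: float
    upper: float
    accuracies: np.ndarray
    confidence: float


def empirical_chance_level(
    labels: Sequence[int],
    pipeline: Callable[[np.ndarray], float],
    repetitions: int = 100,
    confidence: float = 0.95,
    seed: Optional[int] = None,
) -> ChanceLevel:
    """Permutation estimate of the accuracy of uninformed guessing.

    ``pipeline`` receives an independently permuted copy of ``labels`` and
    returns an accuracy in [0, 1].  Returns the mean accuracy over the
    repetitions and the upper bound of the normal-approximation confidence
    interval of that mean.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("need at least two classes for a chance level")
    if repetitions < 20:
        raise ValidationError("use at least 20 repetitions")
    rng = np.random.default_rng(seed)
    accs = np.array([
        float(pipeline(rng.permutation(labels))) for _ in range(repetitions)
    ])
    mean = float(accs.mean())
    sem = float(accs.std(ddof=1) / np.sqrt(repetitions)) if repetitions > 1 else 0.0
    z = float(scipy.stats.norm.ppf(0.5 + confidence / 2.0))
    return ChanceLevel(mean=mean, upper=mean + z * sem, accuracies=accs,
                       confidence=confidence)


# ---------------------------------------------------------------------------
# persistence


def save_model(model: MaciModel, path) -> None:
    """Serialize to a single archive (matrices + codebook + config)."""
    meta = {
        "n_classes": model.n_classes,
        "codebook": model.codebook,
        "config": model.config.to_dict() if model.config else None,
        "specs": [{"family": s.family, "sigma": s.sigma} for s in model.specs],
        "n_sources": len(model.packed_list),
        "objective_trace": list(map(float, model.objective_trace)),
    }
    arrays = {"theta": model.theta, "W0": model.W0,
              "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    if model.eta is not None:
        arrays["eta"] = model.eta
    for a in range(len(model.packed_list)):
        arrays[f"packed_{a}"] = model.packed_list[a]
        arrays[f"mask_{a}"] = model.source_masks[a]
        arrays[f"W_{a}"] = model.W_list[a]
    buf = io.BytesIO()
    np.savez(buf, **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_model(path) -> MaciModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        S = meta["n_sources"]
        cfg = (ProblemConfig.from_dict(meta["config"])
               if meta["config"] else None)
        return MaciModel(
            packed_list=[data[f"packed_{a}"] for a in range(S)],
            source_masks=[data[f"mask_{a}"] for a in range(S)],
            specs=tuple(KernelSpec(**s) for s in meta["specs"]),
            W_list=[data[f"W_{a}"] for a in range(S)],
            theta=data["theta"],
            W0=data["W0"],
            n_classes=meta["n_classes"],
            codebook=meta["codebook"],
            config=cfg,
            objective_trace=meta["objective_trace"],
            eta=data["eta"] if "eta" in data else None,
        )
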