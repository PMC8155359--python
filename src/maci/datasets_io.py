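"""Feature-table I/O, dataset containers and problem configuration.

Feature tables are plain delimited text (comma or tab, auto-detected), one
sample per row, optional label as the trailing column.  Raw labels may be
arbitrary strings; they are remapped to a contiguous codebook ``1..c`` in
lexicographic order of the raw values so that runs are reproducible.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

__all__ = [
    "DomainDataset",
    "LabelMatrix",
    "ProblemConfig",
    "ProblemSummary",
    "ParseError",
    "ValidationError",
    "load_feature_table",
    "write_feature_table",
    "one_hot",
    "validate_problem",
    "load_config",
    "save_config",
]


class ParseError(ValueError):
    """Malformed feature table (ragged rows, non-numeric cells)."""


class ValidationError(ValueError):
    """Inconsistent problem setup (dimension mismatch, bad labels...)."""


@dataclass
class DomainDataset:
    """One domain: an ``n x d`` feature matrix plus optional labels.

    ``labels`` are contiguous class indices in ``1..c`` (0 marks an
    unlabeled row when a partially labeled vector is carried around).
    ``label_kind`` records whether labels are ground truth, pseudo-labels
    produced by a base classifier, or absent.
    """

    features: np.ndarray
    labels: Optional[np.ndarray] = None
    label_kind: str = "none"  # {"true", "pseudo", "none"}
    name: str = ""
    codebook: Optional[dict] = None  # raw label -> class index

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        if self.features.shape[0] < 1 or self.features.shape[1] < 1:
            raise ValidationError("features must be non-empty (n >= 1, d >= 1)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (self.features.shape[0],):
                raise ValidationError(
                    f"labels length {self.labels.shape} does not match "
                    f"n={self.features.shape[0]}"
                )
            if self.label_kind == "none":
                self.label_kind = "true"
        elif self.label_kind != "none":
            raise ValidationError("label_kind set but no labels given")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        if self.labels is None:
            return 0
        return int(self.labels.max(initial=0))


@dataclass
class LabelMatrix:
    """One-hot indicator (``n x c``) plus per-sample confidence weights."""

    indicator: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.indicator = np.asarray(self.indicator, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.indicator.shape[0] != self.confidence.shape[0]:
            raise ValidationError("indicator/confidence length mismatch")
        if np.any(self.confidence < 0):
            raise ValidationError("confidence weights must be >= 0")


@dataclass
class ProblemConfig:
    """All tunable parameters of the co-adaptation problem.

    Defaults follow the empirical settings used throughout: ``q1=q2=2``,
    ``alpha=1e3``, stopping window ``6`` with tolerance ``1e-5`` and at most
    100 sweeps.  ``lam`` (trace-norm) and ``beta`` (row sparsity) are meant
    to be tuned on a log grid; 1.0 is a neutral default.
    """

    q1: float = 2.0
    q2: float = 2.0
    alpha: float = 1.0e3
    beta: float = 1.0
    lam: float = 1.0
    zeta: float = 1.0e3          # orthogonality penalty on F
    varsigma: float = 1.0e6      # confidence weight of true labels
    rho: float = 0.1             # confidence factor for target pseudo-labels
    k_neighbors: int = 5
    kernel_families: tuple = ("gaussian",)
    kernel_sigma: object = "auto"   # "auto" -> 1/d, or positive real
    gamma: object = "auto"          # affinity bandwidth, "auto" or real
    label_aware_graph: bool = True
    max_iter: int = 100
    window: int = 6
    tol: float = 1.0e-5
    seed: int = 0
    ridge: float = 1.0e-10       # relative ridge added to SPD solves
    irls_eps: float = 1.0e-12    # zero-row guard in IRLS diagonals
    standardize: bool = False
    refresh_alignment: bool = False   # rebuild C each sweep from pseudo-labels
    refresh_pseudo_labels: bool = False
    theta_weight_smoothness: bool = False  # weight g(F) by theta^q1 as well
    predict_mode: str = "sum"    # {"sum", "w0"}

    def __post_init__(self) -> None:
        if self.q1 <= 1 or self.q2 <= 1:
            raise ValidationError("q1 and q2 must be > 1 (trivial solution otherwise)")
        for name in ("alpha", "beta", "lam"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.zeta <= 0 or self.varsigma <= 0:
            raise ValidationError("zeta and varsigma must be > 0")
        if isinstance(self.kernel_families, str):
            self.kernel_families = (self.kernel_families,)
        else:
            self.kernel_families = tuple(self.kernel_families)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["kernel_families"] = list(self.kernel_families)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ProblemConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ProblemSummary:
    """Shape summary produced by :func:`validate_problem`."""

    n_sources: int
    n_classes: int
    d: int
    source_sizes: list
    target_size: int
    warnings: list = field(default_factory=list)


def _sniff_delimiter(first_line: str) -> str:
    return "\t" if ("\t" in first_line and "," not in first_line) else ","


def load_feature_table(
    path,
    delimiter: Optional[str] = None,
    has_labels: bool = False,
    name: str = "",
    codebook: Optional[dict] = None,
    strict: bool = False,
) -> DomainDataset:
    """Read a delimited text table into a :class:`DomainDataset`.

    The label column, if any, is last.  Labels are remapped through a
    lexicographic codebook; pass an existing ``codebook`` to reuse a
    previous mapping (``strict=True`` forbids unseen raw labels).
    """
    path = Path(path)
    rows: list[list[str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(lines[0])
    width = None
    for lineno, line in enumerate(lines, start=1):
        cells = [c.strip() for c in line.split(delimiter)]
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ParseError(
                f"{path}: line {lineno} has {len(cells)} columns, expected {width}"
            )
        rows.append(cells)

    raw_labels = None
    if has_labels:
        if width < 2:
            raise ParseError(f"{path}: has_labels requires >= 2 columns")
        raw_labels = [r[-1] for r in rows]
        rows = [r[:-1] for r in rows]

    feats = np.empty((len(rows), len(rows[0])), dtype=float)
    for i, row in enumerate(rows):
        for j, cell in enumerate(row):
            try:
                feats[i, j] = float(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: non-numeric cell {cell!r} at line {i + 1}, "
                    f"column {j + 1}"
                ) from exc

    labels = None
    if raw_labels is not None:
        if codebook is None:
            codebook = {lab: i + 1 for i, lab in enumerate(sorted(set(raw_labels)))}
        else:
            unseen = set(raw_labels) - set(codebook)
            if unseen:
                if strict:
                    raise ValidationError(
                        f"{path}: labels {sorted(unseen)} not in codebook"
                    )
                nxt = max(codebook.values(), default=0)
                for lab in sorted(unseen):
                    nxt += 1
                    codebook[lab] = nxt
        labels = np.array([codebook[lab] for lab in raw_labels], dtype=int)

    return DomainDataset(
        features=feats,
        labels=labels,
        label_kind="true" if labels is not None else "none",
        name=name or path.stem,
        codebook=codebook,
    )


def write_feature_table(dataset: DomainDataset, path, delimiter: str = ",") -> None:
    """Write a dataset back to delimited text (inverse of the loader)."""
    inv = None
    if dataset.labels is not None and dataset.codebook:
        inv = {v: k for k, v in dataset.codebook.items()}
    with open(path, "w") as fh:
        for i in range(dataset.n):
            cells = [repr(float(v)) for v in dataset.features[i]]
            if dataset.labels is not None:
                lab = int(dataset.labels[i])
                cells.append(str(inv[lab]) if inv else str(lab))
            fh.write(delimiter.join(cells) + "\n")


def one_hot(
    labels: Sequence[int],
    c: int,
    weights: Optional[Sequence[float]] = None,
    confidence_scale: float = 1.0,
) -> LabelMatrix:
    """Build the one-hot indicator and diagonal confidence weights.

    ``labels`` use 1-based class indices; 0 marks an unlabeled row, which
    gets a zero indicator row and zero confidence.  The confidence of row
    ``i`` is ``confidence_scale * weights[i]``.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size and labels.max() > c:
        raise ValidationError(f"label {labels.max()} exceeds c={c}")
    if labels.size and labels.min() < 0:
        raise ValidationError("labels must be >= 0 (0 = unlabeled)")
    n = labels.shape[0]
    indicator = np.zeros((n, c))
    labeled = labels > 0
    indicator[np.flatnonzero(labeled), labels[labeled] - 1] = 1.0
    if weights is None:
        w = labeled.astype(float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValidationError("weights length must match labels")
        w = w * labeled
    return LabelMatrix(indicator=indicator, confidence=confidence_scale * w)


def validate_problem(
    sources: Sequence[DomainDataset], target: DomainDataset
) -> ProblemSummary:
    """Check cross-domain consistency and summarize the problem shape."""
    if len(sources) == 0:
        raise ValidationError("at least one source domain is required")
    d = target.d
    for src in sources:
        if src.d != d:
            raise ValidationError(
                f"feature dimensionality mismatch: source {src.name!r} has "
                f"d={src.d}, target has d={d}"
            )
        if src.labels is None:
            raise ValidationError(f"source {src.name!r} has no labels")
    c = max(src.n_classes for src in sources)
    warns = []
    for src in sources:
        missing = sorted(set(range(1, c + 1)) - set(np.unique(src.labels)))
        if missing:
            msg = f"source {src.name!r} is missing classes {missing}"
            warns.append(msg)
            warnings.warn(msg, stacklevel=2)
    return ProblemSummary(
        n_sources=len(sources),
        n_classes=c,
        d=d,
        source_sizes=[src.n for src in sources],
        target_size=target.n,
        warnings=warns,
    )


def load_config(path) -> ProblemConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ProblemConfig.from_dict(data)


def save_config(config: ProblemConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
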