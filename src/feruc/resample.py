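"""Class balancing for the one-vs-rest bin classifiers.

When the response is split into ``c > 2`` bins, each bin's one-vs-rest
classification set is imbalanced roughly ``1 : (c-1)``.  Two balancing
modes are provided:

- random undersampling — drop majority rows (chosen without replacement)
  until both classes match the original minority count; and
- SMOTE oversampling — grow the minority to the majority count by
  interpolating between a minority row and one of its ``k`` nearest
  minority neighbours (Euclidean distance on raw features, ``k`` default 5).

Resampling applies only to classifier training sets; per-bin regressors
always see raw bin samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import DegenerateClassError, ValidationError

MODES = ("none", "undersample", "oversample")


@dataclass(frozen=True)
class ResamplingSpec:
    """How (and whether) to balance classifier training sets.

    ``mode="none"`` ignores ``k`` and ``seed``.  ``k`` is the SMOTE
    neighbour count (used only for ``mode="oversample"``).
    """

    mode: str = "none"
    k: int = 5
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        offenders = []
        if self.mode not in MODES:
            offenders.append(f"mode={self.mode!r} not in {MODES}")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            offenders.append(f"k={self.k!r} must be an integer >= 1")
        if offenders:
            raise ValidationError("; ".join(offenders))


def _check_binary(X, labels) -> Tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels).ravel()
    if X.ndim != 2 or X.shape[0] != labels.size:
        raise ValueError("features must be 2-D with one row per label")
    classes = np.unique(labels)
    if classes.size == 1:
        raise DegenerateClassError(
            f"only class {classes[0]!r} present; both classes are required"
        )
    if classes.size != 2:
        raise DegenerateClassError(f"expected binary labels, got classes {classes}")
    return X, labels


def undersample(X, labels, seed: Optional[int] = None) -> Tuple[np.ndarray, np.ndarray]:
    """Randomly drop majority rows until both classes match the minority count.

    All returned rows are originals (no synthesis); majority rows are chosen
    without replacement under ``seed``.  Original row order is preserved
    among the kept rows.  A balanced input is returned unchanged.
    """
    X, labels = _check_binary(X, labels)
    classes, counts = np.unique(labels, return_counts=True)
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = counts.min()
    if counts[0] == counts[1]:
        return X.copy(), labels.copy()
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(labels == majority)
    keep_maj = rng.choice(maj_idx, size=n_min, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(labels == minority), keep_maj]))
    return X[keep], labels[keep]


def smote_oversample(
    X, labels, k: int = 5, seed: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Grow the minority class to the majority count by SMOTE interpolation.

    Each synthetic row is ``x + u * (x' - x)`` for a minority row ``x``, one
    of its ``k`` nearest minority neighbours ``x'`` (Euclidean distance,
    self excluded), and ``u`` drawn uniformly from [0, 1].  All original
    rows are retained and synthetic rows are appended.  If the minority has
    ``m <= k`` members the neighbour count is clamped to ``m - 1``; a
    single-member minority is balanced by duplication.
    """
    if k < 1:
        raise ValidationError(f"k={k} must be >= 1")
    X, labels = _check_binary(X, labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts[0] == counts[1]:
        return X.copy(), labels.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    need = int(n_maj - n_min)
    X_min = X[labels == minority]
    rng = np.random.default_rng(seed)
    if n_min == 1:
        synth = np.repeat(X_min, need, axis=0)
    else:
        k_eff = int(min(k, n_min - 1))
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_min)
        _, idx = nn.kneighbors(X_min)
        # drop self by index (duplicates may shuffle the self column)
        neighbours = np.empty((n_min, k_eff), dtype=int)
        for i in range(n_min):
            row = idx[i][idx[i] != i]
            if row.size < k_eff:  # self appeared more than once is impossible;
                row = np.concatenate([row, idx[i][idx[i] == i][1:]])
            neighbours[i] = row[:k_eff]
        base = rng.integers(0, n_min, size=need)
        pick = rng.integers(0, k_eff, size=need)
        u = rng.random(need)
        nbr = neighbours[base, pick]
        synth = X_min[base] + u[:, None] * (X_min[nbr] - X_min[base])
    X_out = np.vstack([X, synth])
    labels_out = np.concatenate([labels, np.full(need, minority, dtype=labels.dtype)])
    return X_out, labels_out


def apply_resampling(X, labels, spec: ResamplingSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Apply the balancing mode named by ``spec`` (``none`` is the identity)."""
    if spec.mode == "none":
        return np.asarray(X, dtype=float), np.asarray(labels).ravel()
    if spec.mode == "undersample":
        return undersample(X, labels, spec.seed)
    return smote_oversample(X, labels, spec.k, spec.seed)
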