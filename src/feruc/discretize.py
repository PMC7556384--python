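"""Unsupervised discretization of a continuous response into ``c`` bins.

Four schemes are provided, all returning a :class:`BinAssignment` whose
labels form a disjoint, exhaustive cover of the samples with values in
``1..c``:

``random``
    A seeded random permutation split into equal-as-possible blocks — a
    bagging-like control in which every bin follows the overall response
    distribution.
``even_split``
    Sort by response (stable on ties), then split into contiguous blocks of
    equal-as-possible size.  Bin sizes always differ by at most 1, even when
    the response contains duplicate values.
``equal_frequency``
    Quantile binning: like ``even_split`` but all samples sharing one value
    land in the same bin (ties never straddle a boundary), so bin sizes can
    be uneven when duplicates sit on a cut point.
``kmeans``
    1-D k-means on the response (Lloyd's algorithm, k-means++ restarts),
    clusters relabelled ``1..c`` in ascending order of centre.

The three non-random schemes are order-respecting: a sample with a smaller
response never lands in a higher bin than a sample with a larger response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import BinCountError, EmptyBinError

METHODS = ("random", "even_split", "equal_frequency", "kmeans")

#: Minimum number of samples a bin must hold for ensemble fitting: a
#: regressor cannot be meaningfully trained on fewer than two points.
MIN_BIN_OCCUPANCY = 2


@dataclass(frozen=True)
class BinAssignment:
    """Exhaustive, disjoint mapping of ``n`` samples to bins ``1..c``.

    Parameters
    ----------
    labels
        Per-sample bin index, values in ``1..c``, in original sample order.
    c
        Number of bins.
    method
        The discretizer that produced the assignment, one of :data:`METHODS`.
    seed
        Seed used by stochastic discretizers, or ``None``.
    """

    labels: np.ndarray
    c: int
    method: str
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", labels)
        if self.c < 1:
            raise BinCountError(f"bin count c={self.c} must be >= 1")
        if labels.ndim != 1 or labels.size == 0:
            raise ValueError("labels must be a non-empty 1-D array")
        if labels.min() < 1 or labels.max() > self.c:
            raise ValueError(f"labels must lie in 1..{self.c}")
        if np.any(self.sizes == 0):
            empty = int(np.flatnonzero(self.sizes == 0)[0]) + 1
            raise EmptyBinError(f"bin {empty} of {self.c} is empty ({self.method})")

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @property
    def sizes(self) -> np.ndarray:
        """Bin sizes as an array of length ``c`` (bin ``b`` at index ``b-1``)."""
        return np.bincount(self.labels, minlength=self.c + 1)[1:]

    def members(self, b: int) -> np.ndarray:
        """Boolean mask selecting the samples of bin ``b`` (1-based)."""
        if not 1 <= b <= self.c:
            raise BinCountError(f"bin index {b} outside 1..{self.c}")
        return self.labels == b


def _check_args(y, c: int) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n == 0:
        raise BinCountError("response vector is empty")
    if not 1 <= c <= n:
        raise BinCountError(f"bin count c={c} must satisfy 1 <= c <= n={n}")
    return y


def _block_sizes(n: int, c: int) -> np.ndarray:
    """Equal-as-possible block sizes: the first ``n mod c`` bins get one extra."""
    sizes = np.full(c, n // c, dtype=int)
    sizes[: n % c] += 1
    return sizes


def _sorted_block_labels(n: int, c: int) -> np.ndarray:
    return np.repeat(np.arange(1, c + 1), _block_sizes(n, c))


def discretize_random(y, c: int, seed: Optional[int] = None) -> BinAssignment:
    """Assign samples to ``c`` equal-as-possible bins at random.

    A seeded permutation is split into blocks, so bin sizes differ by at
    most 1 (the response values play no role).  Reproducible for a fixed
    seed.
    """
    y = _check_args(y, c)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(y.size)
    labels = np.empty(y.size, dtype=int)
    labels[perm] = _sorted_block_labels(y.size, c)
    return BinAssignment(labels, c, "random", seed)


def discretize_even_split(y, c: int) -> BinAssignment:
    """Sort ascending (stable on ties) and split into equal-as-possible blocks.

    Bin sizes differ by at most 1 for every ``(n, c)``, duplicates included;
    the first ``n mod c`` bins receive the extra samples.
    """
    y = _check_args(y, c)
    order = np.argsort(y, kind="stable")
    labels = np.empty(y.size, dtype=int)
    labels[order] = _sorted_block_labels(y.size, c)
    return BinAssignment(labels, c, "even_split")


def discretize_equal_frequency(y, c: int) -> BinAssignment:
    """Quantile (equal-frequency) binning with ties kept together.

    Starts from the even-split block assignment on the sorted response and
    then moves every group of tied values into the lowest bin any of them
    tentatively occupies, so a value equal to a cut point goes to the lower
    bin and ties never straddle a boundary.  On a duplicate-free response
    this is identical to :func:`discretize_even_split`; with duplicates the
    bins can be uneven, and a bin emptied by tie consolidation raises
    :class:`~feruc.exceptions.EmptyBinError`.
    """
    y = _check_args(y, c)
    order = np.argsort(y, kind="stable")
    ys = y[order]
    tentative = _sorted_block_labels(y.size, c)
    # first occurrence index of each distinct sorted value
    _, starts = np.unique(ys, return_index=True)
    if starts.size < c:
        raise EmptyBinError(
            f"cannot form {c} equal-frequency bins from {starts.size} distinct "
            f"value(s); bin {starts.size + 1} would be empty"
        )
    seg = np.searchsorted(starts, np.arange(y.size), side="right") - 1
    consolidated = tentative[starts[seg]]
    sizes = np.bincount(consolidated, minlength=c + 1)[1:]
    if np.any(sizes == 0):
        empty = int(np.flatnonzero(sizes == 0)[0]) + 1
        raise EmptyBinError(
            f"equal-frequency bin {empty} of {c} is empty after tie consolidation"
        )
    labels = np.empty(y.size, dtype=int)
    labels[order] = consolidated
    return BinAssignment(labels, c, "equal_frequency")


def discretize_kmeans(
    y, c: int, seed: Optional[int] = None, restarts: int = 10
) -> BinAssignment:
    """1-D k-means clustering of the response.

    Lloyd's algorithm with k-means++ initialization; the best of
    ``restarts`` seeded initializations by within-cluster sum of squares is
    kept and clusters are relabelled ``1..c`` in ascending order of centre.
    Requires at least ``c`` distinct response values.
    """
    y = _check_args(y, c)
    if np.unique(y).size < c:
        raise EmptyBinError(
            f"cannot form {c} k-means bins from {np.unique(y).size} distinct "
            "value(s); at least one bin would be empty"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn chatters about strict convergence
        km = KMeans(
            n_clusters=c,
            n_init=restarts,
            max_iter=300,
            algorithm="lloyd",
            random_state=None if seed is None else int(seed),
        ).fit(y[:, None])
    centre_order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    rank = np.empty(c, dtype=int)
    rank[centre_order] = np.arange(c)
    labels = rank[km.labels_] + 1
    return BinAssignment(labels, c, "kmeans", seed)


def wcss(y, labels) -> float:
    """Within-cluster sum of squares of a labelling of ``y``."""
    y = np.asarray(y, dtype=float).ravel()
    labels = np.asarray(labels)
    total = 0.0
    for b in np.unique(labels):
        vals = y[labels == b]
        total += float(((vals - vals.mean()) ** 2).sum())
    return total


def discretize(
    y, c: int, method: str, seed: Optional[int] = None, restarts: int = 10
) -> BinAssignment:
    """Dispatch to one of the four discretizers by name."""
    if method == "random":
        return discretize_random(y, c, seed)
    if method == "even_split":
        return discretize_even_split(y, c)
    if method == "equal_frequency":
        return discretize_equal_frequency(y, c)
    if method == "kmeans":
        return discretize_kmeans(y, c, seed, restarts)
    raise ValueError(f"unknown discretizer {method!r}; expected one of {METHODS}")
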