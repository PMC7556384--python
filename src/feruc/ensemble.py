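"""The core estimator: per-bin regressor/classifier pairs with
probability-weighted aggregation.

Training phase, given a feature matrix, a continuous response and a bin
count ``c``:

1. discretize the response into ``c`` bins;
2. for each bin ``b`` train a regressor R_b on that bin's samples only, and
   (for the ``weighted`` aggregator) a one-vs-rest binary classifier C_b on
   the full training set — bin samples positive, everything else negative —
   optionally balanced by undersampling or SMOTE oversampling first.

Prediction phase, given a new sample: every R_b predicts a value, every C_b
predicts the probability that the sample belongs in bin ``b``; the
probabilities are normalized to weights summing to 1 and the final
prediction is the weight-blended combination of the per-bin values.  With
the ``averaging`` aggregator no classifiers are built and the final value
is the plain mean of the per-bin predictions.

The estimator is learner agnostic: any object pair honouring
``fit``/``predict`` (regressor) and ``fit``/``predict_proba`` (binary
classifier, probabilities in [0, 1]) may be supplied through
:class:`BaseLearnerSpec`.  The default is a random forest with 1000 trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Any, Callable, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .discretize import MIN_BIN_OCCUPANCY, BinAssignment, discretize
from .exceptions import ContractViolationError, FitError
from .resample import ResamplingSpec, apply_resampling

logger = logging.getLogger("feruc")

AGGREGATORS = ("averaging", "weighted")

_MODEL_FORMAT = "feruc-model"
_MODEL_VERSION = 1

# sub-seed component indices (see derive_seed)
_REGRESSOR, _CLASSIFIER, _RESAMPLER, _DISCRETIZER = 0, 1, 2, 3


def derive_seed(master: Optional[int], *path: int) -> Optional[int]:
    """Derive a deterministic sub-seed from a master seed and an index path.

    Uses :class:`numpy.random.SeedSequence` so that each (bin, component)
    pair draws from an independent stream: adding a bin never perturbs the
    randomness of existing bins.  Returns ``None`` when ``master`` is
    ``None`` (fully stochastic mode).
    """
    if master is None:
        return None
    seq = np.random.SeedSequence((int(master),) + tuple(int(p) for p in path))
    return int(seq.generate_state(1)[0] % (2**31))


@dataclass
class BaseLearnerSpec:
    """Factories producing the per-bin base learners.

    ``regressor_factory(seed)`` must return an object with ``fit(X, y)``
    and ``predict(X)``; ``classifier_factory(seed)`` one with ``fit(X, y)``
    and ``predict_proba(X)`` whose positive-class column lies in [0, 1].
    """

    regressor_factory: Callable[[Optional[int]], Any]
    classifier_factory: Callable[[Optional[int]], Any]
    name: str = "custom"


def default_learner(n_trees: int = 1000, n_jobs: Optional[int] = None) -> BaseLearnerSpec:
    """Random-forest base learners (default 1000 trees).

    mtry follows the conventional forest defaults: a third of the features
    per split for regression, the square root for classification.  The
    classifier's probability is the fraction of trees voting positive.
    """

    def make_regressor(seed: Optional[int]):
        return RandomForestRegressor(
            n_estimators=n_trees, max_features=1 / 3, random_state=seed, n_jobs=n_jobs
        )

    def make_classifier(seed: Optional[int]):
        return RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=n_jobs
        )

    return BaseLearnerSpec(make_regressor, make_classifier, name="random_forest")


def normalize_weights(probabilities: Sequence[float]) -> np.ndarray:
    """Normalize per-bin probabilities to non-negative weights summing to 1.

    Each probability must lie in [0, 1].  An all-zero vector falls back to
    uniform weights (the plain normalization would divide by zero); this
    preserves the convexity of the final prediction and degrades gracefully
    to simple averaging.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    if p.size < 1:
        raise ContractViolationError("at least one probability is required")
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise ContractViolationError(f"probabilities must lie in [0, 1], got {p}")
    total = p.sum()
    if total == 0.0:
        return np.full(p.size, 1.0 / p.size)
    return p / total


@dataclass
class PredictionBreakdown:
    """Per-bin view of one prediction.

    ``final`` is always a convex combination of ``per_bin_predictions``;
    ``per_bin_probabilities`` is ``None`` for the averaging aggregator.
    """

    per_bin_predictions: np.ndarray
    per_bin_probabilities: Optional[np.ndarray]
    weights: np.ndarray
    final: float


def _positive_probability(clf: Any, X: np.ndarray) -> np.ndarray:
    proba = np.asarray(clf.predict_proba(X), dtype=float)
    classes = list(getattr(clf, "classes_", [0, 1]))
    if 1 in classes:
        return proba[:, classes.index(1)]
    return np.zeros(X.shape[0])


@dataclass
class FerucModel:
    """A fitted ensemble: ``c`` regressors and (optionally) ``c`` classifiers.

    Built by :func:`fit`; use :meth:`predict` / :meth:`predict_one` and
    :meth:`save` / :meth:`load`.
    """

    c: int
    method: str
    aggregator: str
    resampling: ResamplingSpec
    learner_name: str
    regressors: List[Any]
    classifiers: Optional[List[Any]]
    assignment: BinAssignment
    bin_response_ranges: np.ndarray  # (c, 2) min/max training response per bin
    classifier_class_counts: Optional[List[Tuple[int, int]]]  # (n_neg, n_pos)
    n_features: int
    seed: Optional[int] = None

    def _check_matrix(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D feature matrix")
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature arity mismatch: model expects {self.n_features}, got {X.shape[1]}"
            )
        return X

    def predict(self, X, return_breakdowns: bool = False):
        """Predict a value for every row of ``X`` (order preserved).

        With ``return_breakdowns=True`` also returns one
        :class:`PredictionBreakdown` per row.
        """
        X = self._check_matrix(X)
        n = X.shape[0]
        if n == 0:
            finals = np.empty(0)
            return (finals, []) if return_breakdowns else finals
        preds = np.column_stack([reg.predict(X) for reg in self.regressors])
        if self.aggregator == "averaging" or self.c == 1 or self.classifiers is None:
            probs = None
            weights = np.full((n, self.c), 1.0 / self.c)
        else:
            probs = np.column_stack(
                [_positive_probability(clf, X) for clf in self.classifiers]
            )
            if np.any(probs < 0.0) or np.any(probs > 1.0):
                raise ContractViolationError("classifier probabilities outside [0, 1]")
            totals = probs.sum(axis=1, keepdims=True)
            weights = np.where(
                totals > 0.0,
                probs / np.where(totals == 0.0, 1.0, totals),
                1.0 / self.c,
            )
        finals = (weights * preds).sum(axis=1)
        if not return_breakdowns:
            return finals
        breakdowns = [
            PredictionBreakdown(
                per_bin_predictions=preds[i],
                per_bin_probabilities=None if probs is None else probs[i],
                weights=weights[i],
                final=float(finals[i]),
            )
            for i in range(n)
        ]
        return finals, breakdowns

    def predict_one(self, x) -> PredictionBreakdown:
        """Predict a single sample, returning the full per-bin breakdown."""
        x = np.asarray(x, dtype=float).ravel()
        if x.size != self.n_features:
            raise ValueError(
                f"feature arity mismatch: model expects {self.n_features}, got {x.size}"
            )
        _, breakdowns = self.predict(x[None, :], return_breakdowns=True)
        return breakdowns[0]

    def save(self, path) -> None:
        """Serialize to disk (versioned, self-describing); see :meth:`load`."""
        joblib.dump(
            {"format": _MODEL_FORMAT, "version": _MODEL_VERSION, "model": self}, path
        )

    @classmethod
    def load(cls, path) -> "FerucModel":
        payload = joblib.load(path)
        if not (isinstance(payload, dict) and payload.get("format") == _MODEL_FORMAT):
            raise ValueError(f"{path} is not a serialized feruc model")
        if payload.get("version") != _MODEL_VERSION:
            raise ValueError(
                f"unsupported model version {payload.get('version')!r} "
                f"(expected {_MODEL_VERSION})"
            )
        return payload["model"]


def fit(
    X,
    y,
    c: int,
    *,
    method: str = "even_split",
    aggregator: str = "weighted",
    resampling: Optional[ResamplingSpec] = None,
    learner: Optional[BaseLearnerSpec] = None,
    seed: Optional[int] = None,
    restarts: int = 10,
) -> FerucModel:
    """Fit the ensemble: discretize, then train one pair per bin.

    Parameters
    ----------
    X, y
        Training feature matrix (n x p) and continuous response (length n).
    c
        Number of bins; ``n >= 2*c`` is required and every bin must end up
        with at least :data:`~feruc.discretize.MIN_BIN_OCCUPANCY` samples.
    method
        Discretizer name (see :data:`~feruc.discretize.METHODS`).
    aggregator
        ``"weighted"`` (classifier-probability weights) or ``"averaging"``
        (plain mean; no classifiers are built).
    resampling
        Balancing applied to each classifier's one-vs-rest training set.
        Its ``seed`` field is ignored here: per-bin resampling seeds are
        derived from ``seed``.  Regressors always see raw bin samples.
    learner
        Base-learner factories; defaults to :func:`default_learner`.
    seed
        Master seed; every stochastic step (discretizer, resamplers, base
        learners) draws a sub-seed derived from it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per response value")
    if aggregator not in AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}; expected {AGGREGATORS}")
    if c < 1:
        raise FitError(f"bin count c={c} must be >= 1")
    if X.shape[0] < 2 * c:
        raise FitError(
            f"need at least 2*c={2 * c} training samples for c={c} bins, got {X.shape[0]}"
        )
    resampling = resampling if resampling is not None else ResamplingSpec()
    learner = learner if learner is not None else default_learner()

    assignment = discretize(
        y, c, method, seed=derive_seed(seed, 0, _DISCRETIZER), restarts=restarts
    )
    sizes = assignment.sizes
    for b in range(1, c + 1):
        if sizes[b - 1] < MIN_BIN_OCCUPANCY:
            raise FitError(
                f"bin {b} of {c} from discretizer '{method}' holds "
                f"{sizes[b - 1]} sample(s); at least {MIN_BIN_OCCUPANCY} required "
                "to train a regressor"
            )

    regressors: List[Any] = []
    classifiers: Optional[List[Any]] = None
    class_counts: Optional[List[Tuple[int, int]]] = None
    build_classifiers = aggregator == "weighted" and c > 1
    if build_classifiers:
        classifiers, class_counts = [], []

    ranges = np.empty((c, 2))
    for b in range(1, c + 1):
        mask = assignment.members(b)
        ranges[b - 1] = (y[mask].min(), y[mask].max())
        reg = learner.regressor_factory(derive_seed(seed, b - 1, _REGRESSOR))
        reg.fit(X[mask], y[mask])
        regressors.append(reg)
        logger.info(
            "bin %d/%d (%s): %d samples, response range [%.4g, %.4g]",
            b, c, method, int(mask.sum()), ranges[b - 1, 0], ranges[b - 1, 1],
        )
        if build_classifiers:
            ovr = mask.astype(int)
            spec_b = replace(resampling, seed=derive_seed(seed, b - 1, _RESAMPLER))
            Xb, yb = apply_resampling(X, ovr, spec_b)
            counts = (int((yb == 0).sum()), int((yb == 1).sum()))
            class_counts.append(counts)
            logger.info(
                "bin %d/%d classifier training set (%s): %d negative / %d positive",
                b, c, resampling.mode, counts[0], counts[1],
            )
            clf = learner.classifier_factory(derive_seed(seed, b - 1, _CLASSIFIER))
            clf.fit(Xb, yb)
            classifiers.append(clf)

    return FerucModel(
        c=c,
        method=method,
        aggregator=aggregator,
        resampling=resampling,
        learner_name=learner.name,
        regressors=regressors,
        classifiers=classifiers,
        assignment=assignment,
        bin_response_ranges=ranges,
        classifier_class_counts=class_counts,
        n_features=X.shape[1],
        seed=seed,
    )


def save_models(models: dict, path, feature_names=None) -> None:
    """Serialize a per-target mapping of fitted models (multi-target runs)."""
    joblib.dump(
        {
            "format": "feruc-model-bundle",
            "version": _MODEL_VERSION,
            "models": models,
            "feature_names": list(feature_names) if feature_names is not None else None,
        },
        path,
    )


def load_models(path) -> Tuple[dict, Optional[List[str]]]:
    """Load a bundle written by :func:`save_models`."""
    payload = joblib.load(path)
    if not (
        isinstance(payload, dict) and payload.get("format") == "feruc-model-bundle"
    ):
        raise ValueError(f"{path} is not a serialized feruc model bundle")
    if payload.get("version") != _MODEL_VERSION:
        raise ValueError(f"unsupported bundle version {payload.get('version')!r}")
    return payload["models"], payload.get("feature_names")
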