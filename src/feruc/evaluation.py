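"""Scoring and the discretizer x aggregator x bin-size evaluation grid.

Regression skill is the coefficient of determination R² = 1 - SSres/SStot
(about the observed mean), which is unbounded below: a model that fits
worse than the horizontal line scores negative.  Bin classifiers are scored
with accuracy, precision, recall and F1 under documented zero-denominator
conventions (precision := 0 when nothing is predicted positive; F1 := 0
when precision + recall = 0).

:func:`run_grid` evaluates every (discretizer, aggregator, c) cell per
target against a base case — one regressor trained on the full,
undiscretized training set — and reports per-target R², the mean percentage
difference vs the base, and per-bin classifier metrics on the test set.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .discretize import METHODS, discretize_random
from .ensemble import (
    BaseLearnerSpec,
    FerucModel,
    default_learner,
    derive_seed,
    fit,
)
from .exceptions import DegenerateTestError, FerucError, UndefinedMetricError
from .io import Dataset
from .resample import ResamplingSpec

logger = logging.getLogger("feruc")

#: Grid aggregator names -> (ensemble aggregator, resampling mode).
AGGREGATOR_COMBOS: Dict[str, Tuple[str, str]] = {
    "averaging": ("averaging", "none"),
    "imbalanced": ("weighted", "none"),
    "undersample": ("weighted", "undersample"),
    "oversample": ("weighted", "oversample"),
}

_CONVENTIONS_NOTE = (
    "Conventions: precision := 0 when no positives are predicted; F1 := 0 when "
    "precision + recall = 0. Percentage differences use |base| as denominator "
    "(unstable when the base R^2 is near 0 or negative). Paired t-tests, where "
    "reported, carry no multiple-testing correction."
)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination, 1 - SSres/SStot about the observed mean.

    Equals 1 for a perfect fit, 0 for predicting the observed mean, and is
    negative when the model fits worse than the horizontal line.  Raises
    :class:`UndefinedMetricError` for a constant observed vector.
    """
    o = np.asarray(observed, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if o.size != p.size or o.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(((o - o.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedMetricError("observed vector is constant; R^2 undefined")
    ss_res = float(((o - p) ** 2).sum())
    return 1.0 - ss_res / ss_tot


class ClassificationMetrics(NamedTuple):
    accuracy: float
    precision: float
    recall: float
    f1: float


def classification_metrics(actual, predicted) -> ClassificationMetrics:
    """Accuracy, precision, recall and F1 from a binary confusion matrix.

    Zero-denominator conventions: precision is 0 when no positives are
    predicted, recall is 0 when there are no actual positives, and F1 is 0
    when precision + recall = 0.
    """
    a = np.asarray(actual).ravel().astype(bool)
    p = np.asarray(predicted).ravel().astype(bool)
    if a.size != p.size or a.size < 1:
        raise ValueError("actual and predicted must have equal length >= 1")
    tp = int(np.sum(a & p))
    tn = int(np.sum(~a & ~p))
    fp = int(np.sum(~a & p))
    fn = int(np.sum(a & ~p))
    accuracy = (tp + tn) / a.size
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) > 0 else 0.0
    return ClassificationMetrics(accuracy, precision, recall, f1)


def percent_difference(base_scores, method_scores) -> float:
    """Mean over targets of ``100 * (method - base) / |base|``.

    Targets whose base score is exactly 0 are excluded with a warning (the
    ratio is undefined).  With a negative or near-zero base the magnitude
    is unstable; the absolute-value denominator keeps the sign meaningful
    (positive = method better).
    """
    b = np.asarray(base_scores, dtype=float).ravel()
    m = np.asarray(method_scores, dtype=float).ravel()
    if b.size != m.size or b.size < 1:
        raise ValueError("score vectors must have equal length >= 1")
    mask = b != 0.0
    if not mask.all():
        warnings.warn(
            f"{int((~mask).sum())} target(s) with base score exactly 0 excluded "
            "from percent difference",
            stacklevel=2,
        )
    if not mask.any():
        raise UndefinedMetricError("all base scores are 0; percent difference undefined")
    return float(np.mean(100.0 * (m[mask] - b[mask]) / np.abs(b[mask])))


def paired_comparison(base_scores, method_scores) -> Tuple[float, float]:
    """Two-sided paired t-test of method vs base across targets.

    Returns ``(t, p)``.  Identical score vectors return ``(0.0, 1.0)``; a
    nonzero constant difference (zero variance, nonzero mean) raises
    :class:`DegenerateTestError`.
    """
    b = np.asarray(base_scores, dtype=float).ravel()
    m = np.asarray(method_scores, dtype=float).ravel()
    if b.size != m.size or b.size < 3:
        raise ValueError("paired comparison requires at least 3 pairs")
    d = m - b
    if np.allclose(d, d[0], rtol=1e-12, atol=1e-12):
        if np.all(d == 0.0):
            return 0.0, 1.0
        raise DegenerateTestError(
            "differences are a nonzero constant; the paired t statistic is undefined"
        )
    t, p = stats.ttest_rel(m, b)
    return float(t), float(p)


def assign_test_bins(model: FerucModel, y_test, seed: Optional[int] = None) -> np.ndarray:
    """True-bin labels for test samples, mirroring the training discretizer.

    For order-respecting discretizers a test sample belongs to the bin whose
    training response interval contains it, with interval boundaries at the
    midpoints between adjacent bins' training extremes.  For the random
    discretizer test samples are randomly assigned to bins under ``seed``,
    mirroring the training-time rule.
    """
    y_test = np.asarray(y_test, dtype=float).ravel()
    if model.c == 1:
        return np.ones(y_test.size, dtype=int)
    if model.method == "random":
        return discretize_random(y_test, model.c, seed).labels
    uppers = model.bin_response_ranges[:-1, 1]
    lowers = model.bin_response_ranges[1:, 0]
    boundaries = (uppers + lowers) / 2.0
    # a value equal to a boundary goes to the lower bin
    return np.searchsorted(boundaries, y_test, side="left") + 1


def classifier_performance(
    model: FerucModel,
    X_test,
    y_test,
    threshold: float = 0.5,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Per-bin test-set metrics of the one-vs-rest aggregating classifiers.

    Hard labels are ``P(positive) >= threshold``.  Returns one row per bin
    with the four metrics plus the bin's resampled training class counts.
    """
    if model.classifiers is None:
        raise FerucError("model has no classifiers (averaging aggregator or c=1)")
    X_test = model._check_matrix(np.asarray(X_test, dtype=float))
    true_bins = assign_test_bins(model, y_test, seed=seed)
    from .ensemble import _positive_probability  # local import: private helper

    rows = []
    for b in range(1, model.c + 1):
        prob = _positive_probability(model.classifiers[b - 1], X_test)
        metrics = classification_metrics(true_bins == b, prob >= threshold)
        n_neg, n_pos = model.classifier_class_counts[b - 1]
        rows.append(
            {
                "bin": b,
                "accuracy": metrics.accuracy,
                "precision": metrics.precision,
                "recall": metrics.recall,
                "f1": metrics.f1,
                "train_negatives": n_neg,
                "train_positives": n_pos,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Tidy result of :func:`run_grid`.

    ``base`` has one row per target (the single full-data regressor);
    ``regression`` one row per (target, discretizer, aggregator, c) cell;
    ``classification`` one row per cell per bin.  ``errors`` records cells
    whose fit failed (the grid continues past them).
    """

    base: pd.DataFrame
    regression: pd.DataFrame
    classification: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    errors: List[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        """Mean test R² over targets, one row per c, columns (discretizer, aggregator)."""
        if self.regression.empty:
            return pd.DataFrame()
        return self.regression.pivot_table(
            index="c", columns=["discretizer", "aggregator"], values="r2", aggfunc="mean"
        )

    def classifier_summary(self) -> pd.DataFrame:
        """Classifier metrics averaged with equal bin weight, then over targets."""
        if self.classification.empty:
            return pd.DataFrame()
        per_cell = self.classification.groupby(
            ["target", "discretizer", "aggregator", "c"], as_index=False
        )[["accuracy", "precision", "recall", "f1"]].mean()
        return per_cell.groupby(["discretizer", "aggregator", "c"], as_index=False)[
            ["accuracy", "precision", "recall", "f1"]
        ].mean()

    def write(self, outdir) -> Dict[str, Path]:
        """Write base/regression/classification CSVs plus a summary text file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "base": outdir / "base.csv",
            "regression": outdir / "regression.csv",
            "classification": outdir / "classification.csv",
            "summary": outdir / "summary.txt",
        }
        self.base.to_csv(paths["base"], index=False)
        self.regression.to_csv(paths["regression"], index=False)
        self.classification.to_csv(paths["classification"], index=False)
        with open(paths["summary"], "w") as fh:
            fh.write("# Evaluation grid summary\n")
            fh.write(_CONVENTIONS_NOTE + "\n\n")
            for key in sorted(self.metadata):
                fh.write(f"{key}: {self.metadata[key]}\n")
            fh.write("\nMean test R^2 over targets (base case: see base.csv):\n")
            fh.write(self.summary().round(4).to_string() + "\n")
            clf = self.classifier_summary()
            if not clf.empty:
                fh.write("\nAggregating-classifier metrics (equal bin weight):\n")
                fh.write(clf.round(4).to_string(index=False) + "\n")
            if self.errors:
                fh.write("\nFailed cells (grid continued past them):\n")
                for err in self.errors:
                    fh.write(f"  {err}\n")
        return paths


def _target_seed(master: Optional[int], target: str) -> Optional[int]:
    """Per-target master seed, derived from the target NAME so the grid is
    invariant to target column order."""
    if master is None:
        return None
    digest = hashlib.sha256(target.encode("utf-8")).digest()
    return derive_seed(master, int.from_bytes(digest[:4], "big"), 4)


def run_grid(
    train: Dataset,
    test: Dataset,
    *,
    c_values: Sequence[int] = (2, 3, 4, 5),
    discretizers: Sequence[str] = METHODS,
    aggregators: Sequence[str] = ("averaging", "imbalanced", "undersample", "oversample"),
    learner: Optional[BaseLearnerSpec] = None,
    smote_k: int = 5,
    seed: Optional[int] = None,
    restarts: int = 10,
) -> EvalReport:
    """Evaluate every (discretizer, aggregator, c) cell per target vs a base case.

    The base case is a single regressor trained on the full training set
    with the same derived seed as a ``c=1`` ensemble's only regressor, so a
    grid cell with ``c=1`` reproduces the base case exactly.  A cell whose
    fit raises is recorded in ``errors`` and the grid continues.
    """
    learner = learner if learner is not None else default_learner()
    unknown = [a for a in aggregators if a not in AGGREGATOR_COMBOS]
    if unknown:
        raise ValueError(
            f"unknown aggregator(s) {unknown}; expected {sorted(AGGREGATOR_COMBOS)}"
        )
    base_rows, reg_rows, clf_rows, errors = [], [], [], []
    for target in train.targets:
        y_train = train.response(target)
        y_test = test.response(target)
        seed_t = _target_seed(seed, target)
        base_reg = learner.regressor_factory(derive_seed(seed_t, 0, 0))
        base_reg.fit(train.X, y_train)
        base_r2 = r_squared(y_test, base_reg.predict(test.X))
        base_rows.append({"target": target, "r2": base_r2})
        logger.info("target %s: base-case R^2 = %.4f", target, base_r2)
        for method in discretizers:
            for agg_name in aggregators:
                ens_aggregator, resample_mode = AGGREGATOR_COMBOS[agg_name]
                for c in c_values:
                    try:
                        model = fit(
                            train.X,
                            y_train,
                            c,
                            method=method,
                            aggregator=ens_aggregator,
                            resampling=ResamplingSpec(mode=resample_mode, k=smote_k),
                            learner=learner,
                            seed=seed_t,
                            restarts=restarts,
                        )
                    except FerucError as exc:
                        errors.append(
                            {
                                "target": target,
                                "discretizer": method,
                                "aggregator": agg_name,
                                "c": c,
                                "error": str(exc),
                            }
                        )
                        logger.warning(
                            "cell (%s, %s, c=%d) failed for target %s: %s",
                            method, agg_name, c, target, exc,
                        )
                        continue
                    r2 = r_squared(y_test, model.predict(test.X))
                    pct = (
                        100.0 * (r2 - base_r2) / abs(base_r2) if base_r2 != 0 else np.nan
                    )
                    reg_rows.append(
                        {
                            "target": target,
                            "discretizer": method,
                            "aggregator": agg_name,
                            "c": c,
                            "r2": r2,
                            "pct_diff_vs_base": pct,
                        }
                    )
                    if model.classifiers is not None:
                        perf = classifier_performance(
                            model,
                            test.X,
                            y_test,
                            seed=derive_seed(seed_t, c, 5),
                        )
                        perf.insert(0, "c", c)
                        perf.insert(0, "aggregator", agg_name)
                        perf.insert(0, "discretizer", method)
                        perf.insert(0, "target", target)
                        clf_rows.append(perf)
    report = EvalReport(
        base=pd.DataFrame(base_rows, columns=["target", "r2"]),
        regression=pd.DataFrame(
            reg_rows,
            columns=["target", "discretizer", "aggregator", "c", "r2", "pct_diff_vs_base"],
        ),
        classification=(
            pd.concat(clf_rows, ignore_index=True)
            if clf_rows
            else pd.DataFrame(
                columns=[
                    "target", "discretizer", "aggregator", "c", "bin",
                    "accuracy", "precision", "recall", "f1",
                    "train_negatives", "train_positives",
                ]
            )
        ),
        metadata={
            "seed": seed,
            "c_values": list(c_values),
            "discretizers": list(discretizers),
            "aggregators": list(aggregators),
            "learner": learner.name,
            "smote_k": smote_k,
            "n_train": train.n_samples,
            "n_test": test.n_samples,
            "targets": train.targets,
        },
        errors=errors,
    )
    return report
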