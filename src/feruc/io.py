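"""Tabular input/output and run configuration.

Learning and test sets are delimited text files (CSV, or TSV by extension)
with a header row: one column per feature plus one numeric column per
continuous response target.  :func:`read_table` splits such a file into a
:class:`Dataset` of features and responses with strict numeric validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import (
    MissingColumnError,
    NonNumericCellError,
    TableFormatError,
    ValidationError,
)

logger = logging.getLogger("feruc")


@dataclass
class Dataset:
    """A feature matrix plus one continuous response column per target."""

    features: pd.DataFrame
    responses: pd.DataFrame

    @property
    def X(self):
        return self.features.to_numpy(dtype=float)

    @property
    def targets(self) -> List[str]:
        return list(self.responses.columns)

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def response(self, name: str):
        if name not in self.responses.columns:
            raise MissingColumnError(f"no such target column: {name!r}")
        return self.responses[name].to_numpy(dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.features, self.responses], axis=1)


def _delimiter_for(path: Path, delimiter: Optional[str]) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _coerce_numeric(df: pd.DataFrame, column: str) -> pd.Series:
    coerced = pd.to_numeric(df[column], errors="coerce")
    bad = coerced.isna()
    if bad.any():
        row = int(bad.idxmax())
        raise NonNumericCellError(
            f"non-numeric or missing value {df[column].iloc[row]!r} at "
            f"row {row}, column {column!r}"
        )
    return coerced.astype(float)


def read_table(
    path, targets: Sequence[str] = (), delimiter: Optional[str] = None
) -> Dataset:
    """Read a delimited table into a :class:`Dataset`.

    ``targets`` names the response columns; every other column is treated
    as a feature and coerced to float.  The delimiter is inferred from the
    extension (``.tsv``/``.tab`` -> tab, else comma) unless given.  A
    header-only file yields an empty (but valid) dataset; a missing target
    or a non-numeric cell raises with the offending name or coordinates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_delimiter_for(path, delimiter))
    except pd.errors.EmptyDataError:
        raise TableFormatError(f"{path} is empty (no header row)") from None
    missing = [t for t in targets if t not in df.columns]
    if missing:
        raise MissingColumnError(
            f"target column(s) {missing} not found in {path}; "
            f"available: {list(df.columns)}"
        )
    feature_cols = [col for col in df.columns if col not in set(targets)]
    features = pd.DataFrame(
        {col: _coerce_numeric(df, col) for col in feature_cols},
        columns=feature_cols,
        index=df.index,
    )
    responses = pd.DataFrame(
        {col: _coerce_numeric(df, col) for col in targets},
        columns=list(targets),
        index=df.index,
    )
    logger.info(
        "read %d rows from %s: %d feature column(s), %d target(s)",
        len(df), path, len(feature_cols), len(targets),
    )
    return Dataset(features=features, responses=responses)


def write_table(dataset: Dataset, path, delimiter: Optional[str] = None) -> None:
    """Write features + responses as one delimited table with header."""
    path = Path(path)
    dataset.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


#: CLI discretizer aliases -> library method names.
DISCRETIZER_ALIASES = {
    "random": "random",
    "even": "even_split",
    "freq": "equal_frequency",
    "kmeans": "kmeans",
}

#: CLI aggregator aliases -> evaluation-grid combo names.
AGGREGATOR_ALIASES = {
    "avg": "averaging",
    "imbalanced": "imbalanced",
    "under": "undersample",
    "over": "oversample",
}


@dataclass
class RunConfig:
    """Resolved settings for a fit/grid run (flags and/or config file)."""

    train: Optional[str] = None
    test: Optional[str] = None
    out: str = "feruc_out"
    targets: List[str] = field(default_factory=list)
    bins: List[int] = field(default_factory=lambda: [2, 3, 4, 5])
    discretizers: List[str] = field(
        default_factory=lambda: ["random", "even_split", "equal_frequency", "kmeans"]
    )
    aggregators: List[str] = field(
        default_factory=lambda: ["averaging", "imbalanced", "undersample", "oversample"]
    )
    smote_k: int = 5
    trees: int = 1000
    seed: Optional[int] = None
    delimiter: Optional[str] = None
    log_level: str = "INFO"
    restarts: int = 10

    def validate(self) -> "RunConfig":
        offenders = []
        if any(c < 1 for c in self.bins):
            offenders.append(f"bins={self.bins} must all be >= 1")
        if self.smote_k < 1:
            offenders.append(f"smote_k={self.smote_k} must be >= 1")
        if self.trees < 1:
            offenders.append(f"trees={self.trees} must be >= 1")
        unknown_d = [d for d in self.discretizers if d not in DISCRETIZER_ALIASES.values()]
        if unknown_d:
            offenders.append(f"unknown discretizer(s) {unknown_d}")
        unknown_a = [a for a in self.aggregators if a not in AGGREGATOR_ALIASES.values()]
        if unknown_a:
            offenders.append(f"unknown aggregator(s) {unknown_a}")
        if offenders:
            raise ValidationError("; ".join(offenders))
        return self


def load_config(path) -> dict:
    """Load a YAML mapping of RunConfig fields (config overrides flags)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    return data
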