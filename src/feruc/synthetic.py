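"""Regime-structured synthetic regression data.

Emulates, at desk scale, a perturbation-response dataset in which a naive
single regressor is good near the centre of the response distribution but
poor at its tails: each sample belongs to a latent *regime*, regimes shift
a handful of informative features, and each regime carries its own linear
feature-to-response map, so the response distribution consists of largely
disjoint bands.  Because bin membership is predictable from the features,
per-bin specialization (and the bin classifiers that exploit it) is
genuinely rewarded.

Defaults are a 10x scale-down of the motivating study shape: 700 training
and 300 test samples.  An optional heavy-tail contamination knob inflates
the response variance of a fraction of samples, which is what makes 1-D
k-means discretization isolate tiny outlier bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import Dataset, write_table

#: Number of regime-shifted (informative) leading features.
N_INFORMATIVE = 5


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    ``regime_separation`` is the spacing between adjacent regime response
    bands in within-band standard-deviation units (band s.d. is ~1 plus
    ``noise_sd``); ``feature_shift`` is the Euclidean norm of the regime
    mean shift applied to the informative features; ``outlier_fraction`` of
    samples receive inflated-variance responses.
    """

    # Defaults are the package's reference study conditions: a 10x
    # scale-down of the motivating data shape, with mild heavy-tail
    # contamination (see docs/methods.md).
    n_train: int = 700
    n_test: int = 300
    p: int = 50
    n_targets: int = 2
    n_regimes: int = 3
    noise_sd: float = 0.5
    regime_separation: float = 8.0
    feature_shift: float = 1.0
    outlier_fraction: float = 0.05
    outlier_scale: float = 5.0
    seed: Optional[int] = None

    def validate(self) -> "SyntheticSpec":
        offenders = []
        for name in ("n_train", "n_test", "p", "n_targets", "n_regimes"):
            if getattr(self, name) < 1:
                offenders.append(f"{name}={getattr(self, name)} must be >= 1")
        if not 0.0 <= self.outlier_fraction < 1.0:
            offenders.append(
                f"outlier_fraction={self.outlier_fraction} must lie in [0, 1)"
            )
        if self.noise_sd < 0:
            offenders.append(f"noise_sd={self.noise_sd} must be >= 0")
        if self.regime_separation < 0:
            offenders.append(f"regime_separation={self.regime_separation} must be >= 0")
        if offenders:
            raise ValidationError("; ".join(offenders))
        return self


def generate(spec: SyntheticSpec) -> Tuple[Dataset, Dataset, Dict[str, np.ndarray]]:
    """Draw a (train, test) pair plus the ground-truth regime labels.

    Mechanism per sample: (i) draw a latent regime uniformly; (ii) draw
    features from a standard normal with a regime-specific mean shift on
    the informative features; (iii) response = regime offset + the regime's
    own linear map of the centred features + Gaussian noise.  Regimes are
    ordered so response bands are largely disjoint.  Fully
    seed-deterministic.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_train + spec.n_test
    q = min(N_INFORMATIVE, spec.p)
    regimes = rng.integers(0, spec.n_regimes, size=n)

    # unit-norm regime directions in the informative subspace
    shifts = rng.standard_normal((spec.n_regimes, q))
    shifts /= np.linalg.norm(shifts, axis=1, keepdims=True)
    shifts *= spec.feature_shift

    X = rng.standard_normal((n, spec.p))
    X[:, :q] += shifts[regimes]

    centred = X - np.pad(shifts, ((0, 0), (0, spec.p - q)))[regimes]
    responses = {}
    out_mask = rng.random(n) < spec.outlier_fraction
    for t in range(spec.n_targets):
        # one linear map per (target, regime); unit response variance
        maps = rng.standard_normal((spec.n_regimes, spec.p)) / np.sqrt(spec.p)
        resp = (
            spec.regime_separation * regimes
            + np.einsum("ij,ij->i", centred, maps[regimes])
            + spec.noise_sd * rng.standard_normal(n)
        )
        resp = resp + out_mask * rng.standard_normal(n) * (
            spec.outlier_scale * max(spec.regime_separation, 1.0)
        )
        responses[f"target_{t + 1}"] = resp

    feature_cols = [f"f{j:03d}" for j in range(spec.p)]
    features = pd.DataFrame(X, columns=feature_cols)
    resp_frame = pd.DataFrame(responses)

    def split(frame: pd.DataFrame, lo: int, hi: int) -> pd.DataFrame:
        return frame.iloc[lo:hi].reset_index(drop=True)

    train = Dataset(
        features=split(features, 0, spec.n_train),
        responses=split(resp_frame, 0, spec.n_train),
    )
    test = Dataset(
        features=split(features, spec.n_train, n),
        responses=split(resp_frame, spec.n_train, n),
    )
    labels = {
        "train": regimes[: spec.n_train].copy(),
        "test": regimes[spec.n_train :].copy(),
    }
    return train, test, labels


def write_fixture(
    train: Dataset,
    test: Dataset,
    outdir,
    labels: Optional[Dict[str, np.ndarray]] = None,
) -> Dict[str, Path]:
    """Write train/test CSVs (and optional regime labels) under ``outdir``.

    Files round-trip losslessly through :func:`feruc.io.read_table`; a
    zero-row dataset produces a header-only, still-readable file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"train": outdir / "train.csv", "test": outdir / "test.csv"}
    write_table(train, paths["train"])
    write_table(test, paths["test"])
    if labels is not None:
        paths["regimes"] = outdir / "regimes.csv"
        frames = [
            pd.DataFrame({"split": split, "regime": np.asarray(arr, dtype=int)})
            for split, arr in labels.items()
        ]
        pd.concat(frames, ignore_index=True).to_csv(paths["regimes"], index=False)
    return paths
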