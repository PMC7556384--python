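import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from feruc import BaseLearnerSpec, SyntheticSpec, default_learner, generate

settings.register_profile(
    "feruc",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("feruc")


class MeanRegressor:
    """Predicts the training-response mean everywhere."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(np.asarray(X).shape[0], self.mean_)


class ConstantProbClassifier:
    """Reports a fixed positive-class probability for every sample."""

    def __init__(self, p=0.5):
        self.p = p
        self.classes_ = np.array([0, 1])

    def fit(self, X, y):
        return self

    def predict_proba(self, X):
        n = np.asarray(X).shape[0]
        return np.column_stack([np.full(n, 1 - self.p), np.full(n, self.p)])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def trivial_learner():
    """Analytically tractable learner pair: mean regressor + constant-probability classifier."""
    return BaseLearnerSpec(
        regressor_factory=lambda seed: MeanRegressor(),
        classifier_factory=lambda seed: ConstantProbClassifier(0.5),
        name="trivial",
    )


@pytest.fixture
def small_forest():
    """A fast forest learner for wiring tests (not for accuracy claims)."""
    return default_learner(n_trees=15)


@pytest.fixture(scope="session")
def tiny_split():
    """A small regime-structured train/test pair shared across tests."""
    spec = SyntheticSpec(
        n_train=90, n_test=45, p=8, n_targets=2, n_regimes=2, seed=7
    )
    train, test, labels = generate(spec)
    return train, test, labels
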