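import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import precision_recall_fscore_support, r2_score

from feruc import (
    assign_test_bins,
    classification_metrics,
    fit,
    paired_comparison,
    percent_difference,
    r_squared,
    run_grid,
)
from feruc.evaluation import classifier_performance
from feruc.exceptions import DegenerateTestError, UndefinedMetricError
from feruc.io import Dataset


class TestRSquared:
    def test_perfect_fit(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, y) == pytest.approx(1.0)

    def test_horizontal_line_scores_zero(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, np.full(20, y.mean())) == pytest.approx(0.0)

    def test_unbounded_below(self):
        assert r_squared([0.0, 1.0], [1.0, 0.0]) == pytest.approx(-3.0)

    def test_constant_observed_rejected(self):
        with pytest.raises(UndefinedMetricError):
            r_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_agrees_with_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        o = rng.normal(size=30)
        p = o + rng.normal(scale=rng.uniform(0.01, 3.0), size=30)
        assert abs(r_squared(o, p) - r2_score(o, p)) < 1e-12


class TestClassificationMetrics:
    def test_predict_all_positive_half_actually_positive(self):
        actual = np.array([1] * 10 + [0] * 10)
        predicted = np.ones(20, dtype=int)
        m = classification_metrics(actual, predicted)
        assert m.accuracy == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(1.0)
        assert round(m.f1, 2) == 0.67

    def test_perfect_prediction(self, rng):
        actual = rng.integers(0, 2, size=30)
        actual[0], actual[1] = 0, 1  # both classes present
        m = classification_metrics(actual, actual)
        assert m == (1.0, 1.0, 1.0, 1.0)

    def test_no_predicted_positives_convention(self):
        m = classification_metrics([1, 1, 0], [0, 0, 0])
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    @given(seed=st.integers(min_value=0, max_value=2**16))
    def test_agrees_with_reference_and_internal_identities(self, seed):
        rng = np.random.default_rng(seed)
        actual = rng.integers(0, 2, size=40)
        predicted = rng.integers(0, 2, size=40)
        m = classification_metrics(actual, predicted)
        prec, rec, f1, _ = precision_recall_fscore_support(
            actual, predicted, average="binary", zero_division=0
        )
        assert m.precision == pytest.approx(prec)
        assert m.recall == pytest.approx(rec)
        assert m.f1 == pytest.approx(f1)
        if m.precision + m.recall > 0:
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / (m.precision + m.recall)
            )
        # accuracy from an explicitly materialized confusion matrix
        cm = np.zeros((2, 2), dtype=int)
        for a, p in zip(actual, predicted):
            cm[a, p] += 1
        assert m.accuracy == pytest.approx((cm[0, 0] + cm[1, 1]) / 40)


class TestPercentDifference:
    def test_doubling_every_target_is_plus_100(self):
        assert percent_difference([0.1, 0.2], [0.2, 0.4]) == pytest.approx(100.0)

    def test_identical_scores_is_zero(self):
        assert percent_difference([0.3, 0.4], [0.3, 0.4]) == pytest.approx(0.0)

    def test_headline_structure(self):
        assert percent_difference([0.075], [0.15]) == pytest.approx(100.0)

    def test_zero_base_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            val = percent_difference([0.0, 0.1], [0.5, 0.2])
        assert val == pytest.approx(100.0)


class TestPairedComparison:
    def test_constant_positive_shift_is_significant(self, rng):
        base = rng.normal(size=20)
        method = base + 0.5 + rng.normal(scale=0.01, size=20)
        t, p = paired_comparison(base, method)
        assert t > 0 and p < 1e-6

    def test_identical_scores_give_zero_statistic(self):
        t, p = paired_comparison([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert t == 0.0 and p == 1.0

    def test_nonzero_constant_difference_is_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_comparison([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])

    def test_breaking_the_pairing_changes_the_statistic(self, rng):
        base = rng.normal(size=15)
        method = base + rng.normal(loc=0.3, scale=0.05, size=15)
        t_paired, _ = paired_comparison(base, method)
        t_shuffled, _ = paired_comparison(base, rng.permutation(method))
        assert t_paired != pytest.approx(t_shuffled)


class TestAssignTestBins:
    def test_interval_membership_via_midpoints(self, small_forest):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = np.concatenate([np.linspace(0, 1, 10), np.linspace(10, 11, 10)])
        model = fit(X, y, 2, method="even_split", learner=small_forest, seed=0)
        # training ranges are exactly [0, 1] and [10, 11] -> boundary at 5.5
        bins = assign_test_bins(model, np.array([0.5, 5.4, 5.5, 5.6, 10.5]))
        assert bins.tolist() == [1, 1, 1, 2, 2]  # a value on the boundary goes lower

    def test_random_method_assigns_equal_blocks(self, small_forest):
        rng = np.random.default_rng(0)
        X, y = rng.normal(size=(20, 3)), rng.normal(size=20)
        model = fit(X, y, 2, method="random", learner=small_forest, seed=0)
        bins = assign_test_bins(model, rng.normal(size=10), seed=1)
        assert sorted(np.bincount(bins)[1:].tolist()) == [5, 5]


class TestRunGrid:
    def test_single_bin_cell_reproduces_base_case(self, tiny_split, small_forest):
        train, test, _ = tiny_split
        report = run_grid(
            train, test, c_values=[1], discretizers=["even_split"],
            aggregators=["averaging"], learner=small_forest, seed=5,
        )
        for target in train.targets:
            base = report.base.loc[report.base.target == target, "r2"].item()
            cell = report.regression.loc[
                report.regression.target == target, "r2"
            ].item()
            assert cell == pytest.approx(base, abs=1e-12)

    def test_empty_discretizer_list_gives_base_only_report(self, tiny_split, small_forest):
        train, test, _ = tiny_split
        report = run_grid(
            train, test, c_values=[2], discretizers=[], aggregators=["averaging"],
            learner=small_forest, seed=5,
        )
        assert report.regression.empty and len(report.base) == 2

    def test_failed_cells_recorded_and_grid_continues(self, tiny_split, small_forest):
        train, test, _ = tiny_split
        big_c = train.n_samples // 2 + 5  # forces the n >= 2c precondition to fail
        report = run_grid(
            train, test, c_values=[2, big_c], discretizers=["even_split"],
            aggregators=["averaging"], learner=small_forest, seed=5,
        )
        assert len(report.errors) == len(train.targets)
        assert set(report.regression.c) == {2}

    def test_invariant_to_target_column_order(self, tiny_split, trivial_learner):
        train, test, _ = tiny_split
        flipped_train = Dataset(train.features, train.responses[train.targets[::-1]])
        flipped_test = Dataset(test.features, test.responses[test.targets[::-1]])
        kwargs = dict(
            c_values=[2], discretizers=["even_split"], aggregators=["averaging"],
            learner=trivial_learner, seed=9,
        )
        a = run_grid(train, test, **kwargs).regression.set_index("target")
        b = run_grid(flipped_train, flipped_test, **kwargs).regression.set_index("target")
        for target in train.targets:
            assert a.loc[target, "r2"] == pytest.approx(b.loc[target, "r2"])

    def test_report_written_as_tidy_csv(self, tmp_path, tiny_split, small_forest):
        train, test, _ = tiny_split
        report = run_grid(
            train, test, c_values=[2], discretizers=["even_split"],
            aggregators=["oversample"], learner=small_forest, seed=5,
        )
        paths = report.write(tmp_path / "out")
        assert all(p.exists() for p in paths.values())
        assert not report.classification.empty
        perf_cols = {"accuracy", "precision", "recall", "f1"}
        assert perf_cols <= set(report.classification.columns)


def test_classifier_performance_requires_classifiers(tiny_split, small_forest):
    train, test, _ = tiny_split
    model = fit(
        train.X, train.response("target_1"), 2,
        aggregator="averaging", learner=small_forest, seed=0,
    )
    with pytest.raises(Exception, match="no classifiers"):
        classifier_performance(model, test.X, test.response("target_1"))
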