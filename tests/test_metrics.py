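import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envtrace.metrics import (balanced_accuracy_per_class,
                              mean_balanced_accuracy, metric_suite,
                              partition_variation, r_squared)


class TestMeanBalancedAccuracy:
    def test_perfect_predictions(self):
        y = ["a", "b", "c", "a", "b", "c"]
        assert mean_balanced_accuracy(y, y) == 1.0

    def test_binary_confusion_counts(self):
        """TP=40, FN=10, TN=30, FP=20 -> both class scores 0.7, mean 0.7."""
        truth = ["pos"] * 50 + ["neg"] * 50
        pred = (["pos"] * 40 + ["neg"] * 10) + (["pos"] * 20 + ["neg"] * 30)
        per = balanced_accuracy_per_class(truth, pred)
        assert per["pos"] == pytest.approx(0.7)
        assert per["neg"] == pytest.approx(0.7)
        assert mean_balanced_accuracy(truth, pred) == pytest.approx(0.7)

    def test_constant_prediction_on_balanced_binary(self):
        truth = ["a"] * 30 + ["b"] * 30
        pred = ["a"] * 60
        assert mean_balanced_accuracy(truth, pred) == pytest.approx(0.5)

    def test_absent_class_refused(self):
        with pytest.raises(ValueError, match="absent"):
            mean_balanced_accuracy(["a", "a"], ["a", "b"], classes=["a", "b"])

    def test_macro_average_of_sklearn_on_binary(self, rng):
        from sklearn.metrics import balanced_accuracy_score
        truth = rng.integers(0, 2, 500)
        pred = rng.integers(0, 2, 500)
        # binary: one-vs-rest balanced accuracy equals sklearn's for
        # either class, hence also their mean
        assert mean_balanced_accuracy(truth, pred) == pytest.approx(
            balanced_accuracy_score(truth, pred), abs=1e-12)


class TestMetricSuite:
    def test_perfect_predictions_all_ones(self):
        y = ["g", "w", "s", "l"] * 5
        frame = metric_suite(y, y)
        per_class = frame.loc["balanced_accuracy":"true_negative_rate"]
        assert np.allclose(per_class.drop(columns="overall").to_numpy(), 1.0)
        assert frame.loc["accuracy", "overall"] == 1.0
        assert frame.loc["kappa", "overall"] == 1.0
        assert frame.loc["matthews_correlation", "overall"] == pytest.approx(1.0)

    def test_tss_identity(self, rng):
        truth = rng.integers(0, 3, 300)
        pred = rng.integers(0, 3, 300)
        frame = metric_suite(truth, pred)
        for c in (0, 1, 2):
            assert frame.loc["true_skill_statistic", c] == pytest.approx(
                frame.loc["recall", c] + frame.loc["true_negative_rate", c]
                - 1.0, abs=1e-12)

    def test_matches_sklearn_oracle(self, rng):
        """Random 3-class tables: every metric agrees with the established
        textbook implementations to 1e-12."""
        from sklearn.metrics import (cohen_kappa_score, f1_score,
                                     matthews_corrcoef, precision_score,
                                     recall_score)
        for _ in range(5):
            truth = rng.integers(0, 3, 400)
            pred = np.where(rng.random(400) < 0.6, truth,
                            rng.integers(0, 3, 400))
            frame = metric_suite(truth, pred)
            assert frame.loc["accuracy", "overall"] == pytest.approx(
                np.mean(truth == pred), abs=1e-12)
            assert frame.loc["kappa", "overall"] == pytest.approx(
                cohen_kappa_score(truth, pred), abs=1e-12)
            assert frame.loc["matthews_correlation", "overall"] == \
                pytest.approx(matthews_corrcoef(truth, pred), abs=1e-12)
            prec = precision_score(truth, pred, average=None,
                                   zero_division=np.nan)
            rec = recall_score(truth, pred, average=None,
                               zero_division=np.nan)
            f1 = f1_score(truth, pred, average=None, zero_division=np.nan)
            for c in (0, 1, 2):
                assert frame.loc["precision", c] == pytest.approx(
                    prec[c], abs=1e-12, nan_ok=True)
                assert frame.loc["recall", c] == pytest.approx(
                    rec[c], abs=1e-12, nan_ok=True)
                assert frame.loc["f1", c] == pytest.approx(
                    f1[c], abs=1e-12, nan_ok=True)


class TestRSquared:
    def test_perfect_fit(self):
        assert r_squared([1, 2, 3], [1, 2, 3]) == 1.0

    def test_predicting_the_mean_is_zero(self):
        assert r_squared([1, 2, 3], [2, 2, 2]) == 0.0

    def test_can_be_negative(self):
        assert r_squared([1, 2, 3], [3, 3, 3]) == pytest.approx(-1.5)

    def test_zero_variance_refused(self):
        with pytest.raises(ValueError, match="variance"):
            r_squared([2, 2, 2], [1, 2, 3])

    def test_matches_sse_sst_oracle(self, rng):
        y = rng.normal(size=200)
        f = y + rng.normal(0, 0.5, 200)
        want = 1 - np.sum((y - f) ** 2) / np.sum((y - np.mean(y)) ** 2)
        assert r_squared(y, f) == pytest.approx(want, abs=1e-12)


class TestPartition:
    def test_time_since_milking_worked_example(self):
        """R2 ACC 0.21, GPS 0.29, combined 0.33 -> 17% shared, 12%/4%
        independent."""
        p = partition_variation(0.21, 0.29, 0.33)
        assert p["shared"] == pytest.approx(0.17)
        assert p["independent_gps"] == pytest.approx(0.12)
        assert p["independent_acc"] == pytest.approx(0.04)

    def test_biomass_worked_example_shared_below_one_percent(self):
        p = partition_variation(0.29, 0.08, 0.37)
        assert p["shared"] == pytest.approx(0.0, abs=1e-12)
        assert p["shared"] <= 0.01

    def test_disjoint_information_case(self):
        p = partition_variation(0.4, 0.0, 0.4)
        assert p["shared"] == pytest.approx(0.0)
        assert p["independent_acc"] == pytest.approx(0.4)

    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identity_holds_exactly(self, a, g, c):
        p = partition_variation(a, g, c)
        total = p["shared"] + p["independent_acc"] + p["independent_gps"]
        assert total == pytest.approx(c, abs=1e-12)
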