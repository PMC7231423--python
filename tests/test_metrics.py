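import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import (accuracy_score, matthews_corrcoef,
                             precision_score, recall_score)

import szdetect as sz
from szdetect.metrics import (ConfusionCounts, InconsistentRatesError,
                              compute_metrics, confusion_from_rates,
                              counts_from_predictions, mean_report,
                              reports_to_frame)
from szdetect.models import ModelSpec, TrainConfig, build_model


def labels_from_counts(counts):
    """Expand integer confusion counts into label vectors for sklearn."""
    tp, tn, fp, fn = (int(counts.tp), int(counts.tn),
                      int(counts.fp), int(counts.fn))
    y_true = np.array([1] * tp + [0] * tn + [0] * fp + [1] * fn)
    y_pred = np.array([1] * tp + [0] * tn + [1] * fp + [0] * fn)
    return y_true, y_pred


class TestComputeMetrics:
    def test_perfect_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert (rep.accuracy, rep.precision, rep.recall, rep.mcor) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_chance_classifier(self):
        rep = compute_metrics(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert rep.accuracy == 0.5 and rep.mcor == 0.0

    def test_hand_evaluated_counts(self):
        rep = compute_metrics(ConfusionCounts(tp=40, tn=45, fp=5, fn=10))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(0.888889, abs=1e-6)
        assert rep.recall == pytest.approx(0.8)
        # mcor = 1750 / sqrt(45*50*50*55), cross-checked against sklearn
        assert rep.mcor == pytest.approx(0.7035265, abs=1e-6)

    def test_zero_denominators_define_zero(self):
        rep = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert rep.precision == 0.0 and rep.recall == 0.0 and rep.mcor == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            ConfusionCounts(tp=-1, tn=5, fp=2, fn=3)

    def test_agrees_with_sklearn_on_random_counts(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            vals = rng.integers(0, 200, 4)
            if vals.sum() == 0:
                continue
            counts = ConfusionCounts(*(int(v) for v in vals))
            rep = compute_metrics(counts)
            y_true, y_pred = labels_from_counts(counts)
            assert rep.accuracy == pytest.approx(
                accuracy_score(y_true, y_pred), abs=1e-9)
            assert rep.precision == pytest.approx(
                precision_score(y_true, y_pred, zero_division=0), abs=1e-9)
            assert rep.recall == pytest.approx(
                recall_score(y_true, y_pred, zero_division=0), abs=1e-9)
            assert rep.mcor == pytest.approx(
                matthews_corrcoef(y_true, y_pred), abs=1e-9)

    @given(st.tuples(*(st.floats(0, 1e6) for _ in range(4))))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_mcor_bounded_in_unit_interval(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn <= 0:
            return
        rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert -1.0 - 1e-12 <= rep.mcor <= 1.0 + 1e-12

    @given(st.floats(0.1, 100), st.floats(0.1, 100), st.floats(0.1, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mcor_zero_when_products_balance(self, tp, tn, fp):
        fn = tp * tn / fp  # ensures TP*TN == FP*FN
        rep = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
        assert rep.mcor == pytest.approx(0.0, abs=1e-9)


class TestConfusionFromRates:
    def test_perfect_rates_recover_perfect_counts(self):
        counts, residual = confusion_from_rates(1.0, 1.0, 1.0, 100, 0.5)
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (50, 50, 0, 0)
        assert residual == 0.0

    def test_round_trip_from_known_counts(self):
        counts, _ = confusion_from_rates(0.85, 0.8, 40 / 45, 100, 0.5)
        assert counts.tp == pytest.approx(40)
        assert counts.fp == pytest.approx(5)
        assert counts.tn == pytest.approx(45)
        assert counts.fn == pytest.approx(10)

    def test_printed_table_rates_reproduce_published_mcor(self):
        counts, residual = confusion_from_rates(0.9795, 0.9844, 0.9747,
                                                1695, 0.495)
        assert residual < 1.0  # rounded rates are nearly self-consistent
        assert compute_metrics(counts).mcor == pytest.approx(0.9589,
                                                             abs=2e-3)

    def test_inconsistent_rates_name_the_negative_count(self):
        # accuracy too low for the implied TP -> negative TN
        with pytest.raises(InconsistentRatesError, match="TN"):
            confusion_from_rates(0.4, 0.99, 0.99, 100, 0.5)

    def test_rate_range_validation(self):
        with pytest.raises(ValueError, match="recall"):
            confusion_from_rates(0.9, 1.2, 0.9, 100, 0.5)

    def test_metric_inversion_round_trip_random(self):
        rng = np.random.default_rng(1)
        tried = 0
        while tried < 500:
            tp, tn, fp, fn = rng.integers(1, 500, 4)
            counts = ConfusionCounts(int(tp), int(tn), int(fp), int(fn))
            rep = compute_metrics(counts)
            prevalence = (counts.tp + counts.fn) / counts.n
            back, residual = confusion_from_rates(
                rep.accuracy, rep.recall, rep.precision, counts.n, prevalence)
            rep2 = compute_metrics(back)
            for field in ("accuracy", "precision", "recall", "mcor"):
                assert getattr(rep2, field) == pytest.approx(
                    getattr(rep, field), abs=1e-9)
            assert residual < 1e-6
            tried += 1


class TestEvaluate:
    def test_all_negative_model_on_balanced_set(self):
        counts = counts_from_predictions(
            np.array([0] * 50 + [1] * 50), np.zeros(100, dtype=int))
        rep = compute_metrics(counts)
        assert rep.recall == 0.0 and rep.accuracy == 0.5

    def test_counts_are_integers_conserving_test_size(self, small_image_bank):
        split = sz.split_dataset(small_image_bank, seed=1)
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(16, 8)), seed=1)
        sz.train(model, small_image_bank, split,
                 TrainConfig(max_epochs=2, batch_size=16, seed=1))
        counts, rep = sz.evaluate(model, small_image_bank, split.test_idx)
        total = counts.tp + counts.tn + counts.fp + counts.fn
        assert total == len(split.test_idx)
        assert all(float(v).is_integer() for v in
                   (counts.tp, counts.tn, counts.fp, counts.fn))
        assert rep.loss is not None and np.isfinite(rep.loss)

    def test_empty_test_set_rejected(self, small_image_bank):
        model = build_model(ModelSpec(backbone="tiny_random",
                                      fc_sizes=(16, 8)))
        with pytest.raises(ValueError, match="empty"):
            sz.evaluate(model, small_image_bank, np.array([], dtype=int))


def test_mean_report_is_arithmetic_mean():
    reports = [sz.MetricsReport(0.9, 0.8, 0.7, 0.6, loss=0.2),
               sz.MetricsReport(0.7, 0.6, 0.5, 0.4, loss=0.4)]
    mean = mean_report(reports)
    assert (mean.accuracy, mean.precision, mean.recall, mean.mcor,
            mean.loss) == (0.8, 0.7, 0.6, 0.5, pytest.approx(0.3))


def test_results_table_frame_shape():
    rep = sz.MetricsReport(0.9, 0.8, 0.7, 0.6, loss=0.1)
    frame = reports_to_frame([{"model": "tiny_random", "fc_size": "64x32",
                               "report": rep}])
    assert list(frame.columns) == ["model", "fc_size", "loss", "accuracy",
                                   "recall", "precision", "mcor"]
    assert frame.iloc[0]["mcor"] == 0.6
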