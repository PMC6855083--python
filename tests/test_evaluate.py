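"""Cascade routing and one-vs-rest classification metrics."""

import itertools

import numpy as np
import pytest

from ecgsqa.evaluate import (
    ConfusionMatrix,
    cascade_predict_batch,
    confusion_matrix,
    evaluate_predictions,
    overall_accuracy,
    per_record_accuracy,
    sensitivity,
    specificity,
)
from ecgsqa.rules import QualityClass, class_to_level


def brute_force_metrics(y_true, y_pred, n_classes, cls):
    """One-vs-rest Se/Sp by direct enumeration of the predictions."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p == cls)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == cls and p != cls)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p == cls)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t != cls and p != cls)
    se = tp / (tp + fn) if tp + fn else None
    sp = tn / (fp + tn) if fp + tn else None
    return se, sp


class TestMetrics:
    def test_worked_two_class_example(self):
        cm = ConfusionMatrix(np.array([[9, 1], [2, 8]]))
        assert sensitivity(cm, 0) == pytest.approx(0.9)
        assert specificity(cm, 0) == pytest.approx(0.8)
        assert overall_accuracy(cm) == pytest.approx(0.85)

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix(np.eye(4, dtype=int) * 5)
        for c in range(4):
            assert sensitivity(cm, c) == 1.0
            assert specificity(cm, c) == 1.0
        assert overall_accuracy(cm) == 1.0

    def test_single_column_collapse(self):
        """All predictions in one class: its specificity is 0."""
        y_true = [0, 1, 2, 0, 1, 2]
        y_pred = [1] * 6
        cm = confusion_matrix(y_true, y_pred, 3)
        assert specificity(cm, 1) == 0.0
        assert sensitivity(cm, 1) == 1.0
        assert sensitivity(cm, 0) == 0.0

    def test_matches_brute_force_enumeration(self, rng):
        """Confusion-matrix metrics equal direct enumeration on random
        labelings of up to 5 classes."""
        for n_classes in (2, 3, 5):
            y_true = rng.integers(0, n_classes, 60)
            y_pred = rng.integers(0, n_classes, 60)
            cm = confusion_matrix(y_true, y_pred, n_classes)
            for c in range(n_classes):
                se_bf, sp_bf = brute_force_metrics(y_true, y_pred, n_classes, c)
                assert sensitivity(cm, c) == se_bf
                assert specificity(cm, c) == sp_bf
            assert overall_accuracy(cm) == pytest.approx(
                float(np.mean(y_true == y_pred)))

    def test_marginal_identities(self, rng):
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        cm = confusion_matrix(y_true, y_pred, 4)
        tp_sum = sum(cm.one_vs_rest(c)[0] for c in range(4))
        assert tp_sum == np.trace(cm.counts)
        for c in range(4):
            tp, fn, fp, _ = cm.one_vs_rest(c)
            assert tp + fn == cm.counts[c].sum()
            assert tp + fp == cm.counts[:, c].sum()

    def test_undefined_metric_reported_missing(self):
        cm = confusion_matrix([0, 0], [0, 1], 2)
        assert sensitivity(cm, 1) is None  # class 1 has no true samples
        assert specificity(cm, 1) == pytest.approx(0.5)

    def test_report_serialization(self):
        rep = evaluate_predictions([0, 1, 1], [0, 1, 0], 2)
        d = rep.to_dict()
        assert d["accuracy"] == pytest.approx(2 / 3)
        assert "Se(%)" in rep.to_text()


class TestPerRecordAccuracy:
    def test_two_records(self):
        rows = per_record_accuracy(["a", "a", "b", "b"], [0, 1, 0, 1], [0, 1, 0, 0])
        assert rows == [("a", 1.0), ("b", 0.5)]

    def test_single_record_equals_overall(self, rng):
        y_true = rng.integers(0, 3, 30)
        y_pred = rng.integers(0, 3, 30)
        rows = per_record_accuracy(["r"] * 30, y_true, y_pred)
        cm = confusion_matrix(y_true, y_pred, 3)
        assert rows[0][1] == pytest.approx(overall_accuracy(cm))

    def test_pooled_equals_weighted_mean(self, rng):
        ids = rng.choice(list("abc"), 60)
        y_true = rng.integers(0, 2, 60)
        y_pred = rng.integers(0, 2, 60)
        rows = dict(per_record_accuracy(ids, y_true, y_pred))
        weighted = sum(rows[r] * np.sum(ids == r) for r in rows) / len(ids)
        assert weighted == pytest.approx(float(np.mean(y_true == y_pred)))


class _StubSubnet:
    """Fixed-output stand-in for a trained subnetwork."""

    def __init__(self, n_classes, probs):
        from ecgsqa.model import SubnetworkSpec

        self.spec = SubnetworkSpec(n_classes=n_classes)
        self._probs = np.asarray(probs, dtype=np.float32)

    def forward(self, spec_x, sig_x, training=False):
        return np.tile(self._probs, (sig_x.shape[0], 1))


class TestCascadeRouting:
    def segments(self, n=3):
        rng = np.random.default_rng(0)
        return [rng.standard_normal(512) for _ in range(n)]

    def test_motion_route_to_severe(self):
        subnets = (_StubSubnet(3, [0.1, 0.8, 0.1]),
                   _StubSubnet(2, [0.3, 0.7]),
                   _StubSubnet(2, [0.9, 0.1]))
        preds = cascade_predict_batch(self.segments(), subnets)
        assert all(p is QualityClass.SEVERE_MOTION for p in preds)

    def test_low_short_circuits_stage_two(self):
        class Exploding(_StubSubnet):
            def forward(self, *a, **k):
                raise AssertionError("stage-2 subnetwork must not run")

        subnets = (_StubSubnet(3, [0.9, 0.05, 0.05]),
                   Exploding(2, [0.5, 0.5]),
                   Exploding(2, [0.5, 0.5]))
        preds = cascade_predict_batch(self.segments(), subnets)
        assert all(p is QualityClass.LOW for p in preds)

    def test_myo_route_to_mild(self):
        subnets = (_StubSubnet(3, [0.1, 0.1, 0.8]),
                   _StubSubnet(2, [0.5, 0.5]),
                   _StubSubnet(2, [0.8, 0.2]))
        preds = cascade_predict_batch(self.segments(), subnets)
        assert all(p is QualityClass.MILD_MYO for p in preds)

    def test_argmax_tie_breaks_low(self):
        subnets = (_StubSubnet(3, [1 / 3, 1 / 3, 1 / 3]),
                   _StubSubnet(2, [0.5, 0.5]),
                   _StubSubnet(2, [0.5, 0.5]))
        preds = cascade_predict_batch(self.segments(), subnets)
        assert all(p is QualityClass.LOW for p in preds)

    def test_levels_consistent_with_classes(self):
        for probs in itertools.product([0.2, 0.5, 0.8], repeat=3):
            s = np.array(probs) / np.sum(probs)
            subnets = (_StubSubnet(3, s),
                       _StubSubnet(2, [0.4, 0.6]),
                       _StubSubnet(2, [0.6, 0.4]))
            for p in cascade_predict_batch(self.segments(1), subnets):
                assert class_to_level(p) is class_to_level(QualityClass(int(p)))

    def test_wrong_cascade_shape_rejected(self):
        subnets = (_StubSubnet(2, [0.5, 0.5]),) * 3
        with pytest.raises(ValueError):
            cascade_predict_batch(self.segments(), subnets)
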