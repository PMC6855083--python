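"""Cascade inference and classification metrics.

Inference is two-staged: subnetwork 1 assigns the interference type (low /
motion / myoelectric); segments typed as motion or myoelectric are routed
to subnetwork 2 or 3 respectively, which grade the level (mild / severe),
yielding one of the five quality classes.  Argmax ties break toward the
lowest class index.

Metrics follow the usual one-vs-rest reduction of a K-class confusion
matrix: per class, sensitivity Se = TP/(TP+FN) and specificity
Sp = TN/(FP+TN); overall accuracy Ac = trace/total.  A metric whose
denominator is zero is reported as missing (None), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import SubnetworkModel
from .rules import QualityClass, class_to_level
from .training import prepare_inputs

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "cascade_predict",
    "cascade_predict_batch",
    "confusion_matrix",
    "sensitivity",
    "specificity",
    "overall_accuracy",
    "evaluate_predictions",
    "per_record_accuracy",
]

#: Stage-1 type index -> (stage-2 network slot, mild class, severe class)
_ROUTING = {
    1: (1, QualityClass.MILD_MOTION, QualityClass.SEVERE_MOTION),
    2: (2, QualityClass.MILD_MYO, QualityClass.SEVERE_MYO),
}


def cascade_predict_batch(
    segments: Sequence,
    subnets: tuple[SubnetworkModel, SubnetworkModel, SubnetworkModel],
    batch_size: int = 100,
) -> list[QualityClass]:
    """Classify a batch of 512-sample segments through the cascade.

    Stage 1 runs on every segment; stages 2/3 run only on the segments the
    type stage routed to them.  Predictions are independent of batch
    order and batching.
    """
    s1, s2, s3 = subnets
    if s1.spec.n_classes != 3 or s2.spec.n_classes != 2 or s3.spec.n_classes != 2:
        raise ValueError("cascade needs subnetworks with 3, 2 and 2 classes")
    spec_x, sig_x = prepare_inputs(segments)
    n = sig_x.shape[0]

    def _argmax_batched(model, sx, gx):
        out = np.empty(gx.shape[0], dtype=int)
        for i in range(0, gx.shape[0], batch_size):
            p = model.forward(sx[i:i + batch_size], gx[i:i + batch_size], training=False)
            out[i:i + batch_size] = p.argmax(axis=1)  # ties -> lowest index
        return out

    types = _argmax_batched(s1, spec_x, sig_x)
    preds = np.full(n, int(QualityClass.LOW), dtype=int)
    for type_idx, (slot, mild, severe) in _ROUTING.items():
        sel = np.flatnonzero(types == type_idx)
        if sel.size == 0:
            continue
        model = (s1, s2, s3)[slot]
        level = _argmax_batched(model, spec_x[sel], sig_x[sel])
        preds[sel] = np.where(level == 0, int(mild), int(severe))
    return [QualityClass(int(p)) for p in preds]


def cascade_predict(segment, subnets) -> QualityClass:
    """Classify a single 512-sample segment through the cascade."""
    return cascade_predict_batch([segment], subnets)[0]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("confusion matrix entries must be non-negative integers")

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self, cls: int) -> tuple[int, int, int, int]:
        """(TP, FN, FP, TN) for one class against the rest."""
        c = self.counts
        tp = int(c[cls, cls])
        fn = int(c[cls].sum() - tp)
        fp = int(c[:, cls].sum() - tp)
        tn = self.total - tp - fn - fp
        return tp, fn, fp, tn


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int],
                     n_classes: int) -> ConfusionMatrix:
    yt = np.asarray([int(v) for v in y_true])
    yp = np.asarray([int(v) for v in y_pred])
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    counts = np.bincount(yt * n_classes + yp, minlength=n_classes * n_classes)
    return ConfusionMatrix(counts.reshape(n_classes, n_classes))


def sensitivity(cm: ConfusionMatrix, cls: int) -> float | None:
    """Se = TP / (TP + FN); None when the class has no true samples."""
    tp, fn, _, _ = cm.one_vs_rest(cls)
    return tp / (tp + fn) if tp + fn else None


def specificity(cm: ConfusionMatrix, cls: int) -> float | None:
    """Sp = TN / (FP + TN); None when every sample belongs to the class."""
    _, _, fp, tn = cm.one_vs_rest(cls)
    return tn / (fp + tn) if fp + tn else None


def overall_accuracy(cm: ConfusionMatrix) -> float | None:
    """Ac = trace / total; None on an empty matrix."""
    return float(np.trace(cm.counts)) / cm.total if cm.total else None


@dataclass(frozen=True)
class EvalReport:
    """Per-class Se/Sp, overall accuracy and the underlying matrix."""

    confusion: ConfusionMatrix
    sensitivity: tuple[float | None, ...]
    specificity: tuple[float | None, ...]
    accuracy: float | None

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.counts.tolist(),
            "sensitivity": list(self.sensitivity),
            "specificity": list(self.specificity),
            "accuracy": self.accuracy,
        }

    def to_text(self, class_names: Sequence[str] | None = None) -> str:
        k = self.confusion.n_classes
        names = list(class_names) if class_names else [f"class{i}" for i in range(k)]
        lines = [f"{'class':>16s} {'Se(%)':>7s} {'Sp(%)':>7s}"]
        for i in range(k):
            se = "--" if self.sensitivity[i] is None else f"{100 * self.sensitivity[i]:.1f}"
            sp = "--" if self.specificity[i] is None else f"{100 * self.specificity[i]:.1f}"
            lines.append(f"{names[i]:>16s} {se:>7s} {sp:>7s}")
        ac = "--" if self.accuracy is None else f"{100 * self.accuracy:.1f}"
        lines.append(f"{'overall Ac(%)':>16s} {ac:>7s}")
        return "\n".join(lines)


def evaluate_predictions(y_true: Sequence[int], y_pred: Sequence[int],
                         n_classes: int) -> EvalReport:
    cm = confusion_matrix(y_true, y_pred, n_classes)
    return EvalReport(
        confusion=cm,
        sensitivity=tuple(sensitivity(cm, c) for c in range(n_classes)),
        specificity=tuple(specificity(cm, c) for c in range(n_classes)),
        accuracy=overall_accuracy(cm),
    )


def per_record_accuracy(
    record_ids: Sequence, y_true: Sequence[int], y_pred: Sequence[int]
) -> list[tuple[object, float]]:
    """Overall accuracy per record, sorted by record id.

    The pooled accuracy equals the size-weighted mean of the per-record
    accuracies; empty groups cannot occur by construction.
    """
    rid = list(record_ids)
    yt = np.asarray([int(v) for v in y_true])
    yp = np.asarray([int(v) for v in y_pred])
    if not (len(rid) == yt.size == yp.size):
        raise ValueError("record_ids, y_true, y_pred must align")
    out = []
    for r in sorted(set(rid)):
        sel = np.array([x == r for x in rid])
        out.append((r, float((yt[sel] == yp[sel]).mean())))
    return out


def predicted_levels(preds: Sequence[QualityClass]):
    """Clinical level of each predicted class."""
    return [class_to_level(p) for p in preds]
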