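"""Training loops for the cascade subnetworks and the baseline classifier.

The three subnetworks are trained separately on their own sub-tasks:

* subnetwork 1 — interference type (low / motion / myoelectric) on all
  segments, with mild and severe merged per type;
* subnetwork 2 — motion level (mild / severe) on motion segments only;
* subnetwork 3 — myoelectric level (mild / severe) on myoelectric segments.

Optimization follows the reference protocol: Adam, minibatch 100, staircase
learning-rate decay (rate 0.5 every 10,000 optimizer steps), initial rate
0.02 for the subnetworks and 0.03 for the baseline, summed-Bernoulli
cross-entropy on the softmax outputs.  Network inputs are conditioned
upstream of the models: the spectrogram is z-scored over all entries and
the raw 512-sample trace is z-scored per segment (raw millivolt inputs
destabilize training).

Runs are reproducible bit-for-bit under a fixed seed and thread count; each
epoch shuffles with a seeded generator and consumes full minibatches only
(the sub-batch remainder of the shuffled order is skipped that epoch, so
all data is still visited across epochs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .model import (
    BaselineModel,
    BaselineSpec,
    SubnetworkModel,
    SubnetworkSpec,
    build_baseline,
    build_subnetwork,
)
from .nn import (
    Adam,
    BatchNorm,
    bernoulli_sum_loss,
    bernoulli_sum_loss_fused,
    categorical_cross_entropy_loss,
    categorical_cross_entropy_loss_fused,
)
from .nn.optim import staircase_lr
from .rules import QualityClass
from .spectrum import standardize_spectrogram, stft_spectrum
from .synthetic import SyntheticSegment

__all__ = [
    "TrainConfig",
    "SUBNET1_TASK",
    "SUBNET2_TASK",
    "SUBNET3_TASK",
    "learning_rate_at",
    "prepare_inputs",
    "train_subnetwork",
    "train_baseline",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings.

    Defaults are the cascade settings; ``TrainConfig.baseline()`` gives the
    baseline ones (initial rate 0.03, 100 epochs).
    """

    initial_lr: float = 0.02
    decay_rate: float = 0.50
    decay_step: int = 10_000
    epochs: int = 80
    batch_size: int = 100
    dropout_p: float = 0.5
    val_fraction: float = 0.1
    loss_form: str = "bernoulli_sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.initial_lr, self.decay_step, self.epochs, self.batch_size) <= 0:
            raise ValueError("learning rate, decay step, epochs, batch size must be positive")
        if not 0.0 < self.decay_rate <= 1.0:
            raise ValueError("decay_rate must lie in (0, 1]")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")

    @staticmethod
    def baseline(**overrides) -> "TrainConfig":
        cfg = TrainConfig(initial_lr=0.03, epochs=100)
        return replace(cfg, **overrides) if overrides else cfg


def learning_rate_at(step: int, cfg: TrainConfig) -> float:
    """Staircase schedule: initial_lr * decay_rate ** floor(step/decay_step)."""
    return staircase_lr(step, cfg.initial_lr, cfg.decay_rate, cfg.decay_step)


#: Class relabelling for subnetwork 1: low / motion / myoelectric.
SUBNET1_TASK: Mapping[QualityClass, int] = {
    QualityClass.LOW: 0,
    QualityClass.MILD_MOTION: 1,
    QualityClass.SEVERE_MOTION: 1,
    QualityClass.MILD_MYO: 2,
    QualityClass.SEVERE_MYO: 2,
}
#: Subnetwork 2: motion segments only, mild vs severe.
SUBNET2_TASK: Mapping[QualityClass, int] = {
    QualityClass.MILD_MOTION: 0,
    QualityClass.SEVERE_MOTION: 1,
}
#: Subnetwork 3: myoelectric segments only, mild vs severe.
SUBNET3_TASK: Mapping[QualityClass, int] = {
    QualityClass.MILD_MYO: 0,
    QualityClass.SEVERE_MYO: 1,
}

_EPS = 1e-8


def prepare_inputs(
    segments: Sequence[SyntheticSegment] | Sequence[np.ndarray],
    with_spectrogram: bool = True,
):
    """Convert segments into the two network input tensors.

    Returns ``(spec_x, sig_x)``: the standardized spectrogram stack
    (N, 257, 63, 1) and the per-segment z-scored raw signal (N, 1, 512, 1),
    both float32.  ``with_spectrogram=False`` skips the STFT and returns
    ``(None, sig_x)`` for raw-signal-only models.
    """
    raw = np.stack([
        s.samples if isinstance(s, SyntheticSegment) else np.asarray(s, dtype=float)
        for s in segments
    ])
    spec_x = None
    if with_spectrogram:
        spec_x = np.stack([
            standardize_spectrogram(stft_spectrum(x)).values for x in raw
        ]).astype(np.float32)[..., None]
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    sig = (raw - mu) / np.maximum(sd, _EPS)
    sig_x = sig.astype(np.float32)[:, None, :, None]
    return spec_x, sig_x


def _loss_fn(cfg: TrainConfig):
    return {"bernoulli_sum": bernoulli_sum_loss,
            "categorical": categorical_cross_entropy_loss}[cfg.loss_form]


def _fused_loss_fn(cfg: TrainConfig):
    # gradient taken in the logits: stable against softmax saturation
    return {"bernoulli_sum": bernoulli_sum_loss_fused,
            "categorical": categorical_cross_entropy_loss_fused}[cfg.loss_form]


def _split(n: int, labels: np.ndarray, val_fraction: float, rng: np.random.Generator):
    """Per-class stratified train/validation split."""
    val_idx = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(val_fraction * idx.size))
        val_idx.append(idx[:n_val])
    val = np.concatenate(val_idx) if val_idx else np.empty(0, dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[val] = False
    return np.flatnonzero(mask), np.sort(val)


def _evaluate(model, spec_x, sig_x, labels, n_classes, fn, batch_size):
    losses, correct = [], 0
    onehot = np.eye(n_classes, dtype=np.float32)
    for i in range(0, len(labels), batch_size):
        sl = slice(i, i + batch_size)
        if isinstance(model, BaselineModel):
            p = model.forward(sig_x[sl], training=False)
        else:
            p = model.forward(spec_x[sl], sig_x[sl], training=False)
        loss, _ = fn(p, onehot[labels[sl]])
        losses.append(loss * (sl.stop and min(sl.stop, len(labels)) - sl.start))
        correct += int((p.argmax(axis=1) == labels[sl]).sum())
    n = len(labels)
    return (float(np.sum(losses)) / n if n else float("nan"),
            correct / n if n else float("nan"))


def snapshot_state(model) -> list[dict]:
    """Copy all trainable parameters and batch-norm running statistics."""
    state = []
    for layer in model.layers():
        s = {k: v.copy() for k, v in layer.params.items()}
        if isinstance(layer, BatchNorm):
            s["running_mean"] = layer.running_mean.copy()
            s["running_var"] = layer.running_var.copy()
        state.append(s)
    return state


def restore_state(model, state: list[dict]) -> None:
    """Inverse of :func:`snapshot_state`."""
    for layer, s in zip(model.layers(), state):
        for k in layer.params:
            layer.params[k] = s[k].copy()
        if isinstance(layer, BatchNorm):
            layer.running_mean = s["running_mean"].copy()
            layer.running_var = s["running_var"].copy()


def _fit(model, spec_x, sig_x, labels, n_classes, cfg: TrainConfig):
    fn = _loss_fn(cfg)
    fused = _fused_loss_fn(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    tr, va = _split(len(labels), labels, cfg.val_fraction, rng)
    opt = Adam(model.layers())
    onehot = np.eye(n_classes, dtype=np.float32)
    history = {"train_loss": [], "train_accuracy": [],
               "val_loss": [], "val_accuracy": [], "lr": []}
    # best-validation snapshot kept alongside the final weights (no early
    # stopping: training always runs the configured epochs)
    best_acc, best_state, best_epoch = -1.0, None, None
    step = 0
    for epoch in range(cfg.epochs):
        order = tr[rng.permutation(tr.size)]
        batch_losses, batch_accs = [], []
        for b in range(tr.size // cfg.batch_size):
            sl = order[b * cfg.batch_size:(b + 1) * cfg.batch_size]
            lr = learning_rate_at(step, cfg)
            if isinstance(model, BaselineModel):
                p = model.forward(sig_x[sl], training=True)
            else:
                p = model.forward(spec_x[sl], sig_x[sl], training=True)
            loss, dz = fused(p, onehot[labels[sl]])
            batch_accs.append(float((p.argmax(axis=1) == labels[sl]).mean()))
            model.backward(dz, from_logits=True)
            opt.step(lr)
            step += 1
            batch_losses.append(loss)
        if va.size:
            vl, vacc = _evaluate(model, spec_x[va] if spec_x is not None else None,
                                 sig_x[va], labels[va], n_classes, fn, cfg.batch_size)
            if vacc > best_acc:
                best_acc, best_state, best_epoch = vacc, snapshot_state(model), epoch
        else:
            vl, vacc = float("nan"), float("nan")
        history["train_loss"].append(float(np.mean(batch_losses)))
        history["train_accuracy"].append(float(np.mean(batch_accs)))
        history["val_loss"].append(vl)
        history["val_accuracy"].append(vacc)
        history["lr"].append(learning_rate_at(step, cfg))
    model.best_state = best_state
    history["best_epoch"] = best_epoch
    return model, history


def train_subnetwork(
    segments: Sequence[SyntheticSegment],
    task: Mapping[QualityClass, int],
    cfg: TrainConfig,
    spec: SubnetworkSpec | None = None,
    prepared: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[SubnetworkModel, dict]:
    """Train one cascade subnetwork on the segments relevant to its task.

    ``task`` maps five-way labels onto the subnetwork's class indices;
    segments whose class is absent from the map are ignored.  Raises if any
    task class has no data.  ``prepared`` optionally supplies the
    ``prepare_inputs(segments)`` tensors, aligned with ``segments``, so
    callers training several subnetworks on one dataset compute the
    spectrograms once.
    """
    keep_idx = [i for i, s in enumerate(segments) if s.true_class in task]
    kept = [segments[i] for i in keep_idx]
    labels = np.array([task[s.true_class] for s in kept])
    n_classes = len(set(task.values()))
    if len(set(labels)) < n_classes:
        raise ValueError("every task class needs at least one segment")
    spec = spec or SubnetworkSpec(n_classes=n_classes, dropout_p=cfg.dropout_p)
    if spec.n_classes != n_classes:
        raise ValueError("spec.n_classes does not match the task")
    model = build_subnetwork(spec, cfg.seed)
    if prepared is None:
        spec_x, sig_x = prepare_inputs(kept)
    else:
        spec_x, sig_x = (prepared[0][keep_idx], prepared[1][keep_idx])
    return _fit(model, spec_x, sig_x, labels, n_classes, cfg)


def train_baseline(
    segments: Sequence[SyntheticSegment],
    cfg: TrainConfig | None = None,
    spec: BaselineSpec = BaselineSpec(),
) -> tuple[BaselineModel, dict]:
    """Train the five-class baseline on raw-signal input only."""
    cfg = cfg or TrainConfig.baseline()
    labels = np.array([int(s.true_class) for s in segments])
    if len(set(labels.tolist())) < spec.n_classes:
        raise ValueError("all five classes need at least one segment")
    model = build_baseline(spec, cfg.seed)
    _, sig_x = prepare_inputs(segments, with_spectrogram=False)
    return _fit(model, None, sig_x, labels, spec.n_classes, cfg)
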