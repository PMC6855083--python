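"""Network architectures for dynamic-ECG quality classification.

Two families are built here:

* a **baseline** CNN that maps the raw 512-sample segment straight to the
  five quality classes (stacked 1 x 3 conv blocks, max pooling by 4 between
  stages, a 1 x 1 bottleneck to 32 maps, a 128-unit dense layer, softmax);
* the **cascade subnetworks**, each with two feature extractors — CNN1 on
  the 257 x 63 spectrogram (3 x 3 conv blocks) and CNN2 on the raw signal
  (1 x 3 conv blocks) — whose flattened tail outputs are concatenated and
  classified by a 128-unit dense layer with dropout and a softmax over
  K = 3 (interference type) or K = 2 (interference level).

Every conv block is convolution + batch normalization + rectifier, with
size-preserving padding and stride 1; pooling is non-overlapping with floor
division on odd extents; the 1 x 1 tail is a bare convolution + rectifier.
With the default stage depths (1, 2, 5) and channel widths (32, 64, 128)
the baseline holds 0.28 M trainable parameters and the three-subnetwork
cascade 3.2 M.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import h5py
import numpy as np

from .nn import (
    Adam,  # noqa: F401  (re-exported for callers wiring training loops)
    BatchNorm,
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    MaxPool2d,
    ReLU,
    Sequential,
    Softmax,
    bernoulli_sum_loss,
    categorical_cross_entropy_loss,
)
from .spectrum import N_FRAMES, N_FREQ_BINS
from .synthetic import SEGMENT_SAMPLES

__all__ = [
    "ConvBlockKind",
    "StageSpec",
    "SubnetworkSpec",
    "BaselineSpec",
    "SubnetworkModel",
    "BaselineModel",
    "build_subnetwork",
    "build_baseline",
    "count_trainable_parameters",
    "cross_entropy_loss",
    "save_model",
    "load_model",
]


class ConvBlockKind(enum.Enum):
    """Convolution block flavour: 3 x 3 kernels for spectrogram branches,
    1 x 3 kernels for raw-signal branches."""

    BLOCK1 = (3, 3)
    BLOCK2 = (1, 3)

    @property
    def kernel(self) -> tuple[int, int]:
        return self.value


@dataclass(frozen=True)
class StageSpec:
    """Depths, widths and pooling of one three-stage conv trunk.

    block_counts (d1, d2, d3) stacked conv blocks per stage; channels the
    per-stage feature-map counts; pool_sizes the max-pool window after each
    stage; tail_channels the 1 x 1 bottleneck width.
    """

    block_counts: tuple[int, int, int] = (1, 2, 5)
    channels: tuple[int, int, int] = (32, 64, 128)
    pool_sizes: tuple[tuple[int, int], ...] = ((1, 4), (1, 4), (1, 4))
    tail_channels: int = 32

    def __post_init__(self) -> None:
        if len(self.block_counts) != 3 or any(d < 1 for d in self.block_counts):
            raise ValueError("block_counts must be three integers >= 1")
        if len(self.channels) != 3 or len(self.pool_sizes) != 3:
            raise ValueError("channels and pool_sizes must have three entries")


#: CNN1 trunk on the 257 x 63 spectrogram: pool 4x2, 4x2, 4x4.
CNN1_DEFAULT = StageSpec(pool_sizes=((4, 2), (4, 2), (4, 4)))
#: CNN2 / baseline trunk on the 1 x 512 raw segment: pool 1x4 three times.
CNN2_DEFAULT = StageSpec(pool_sizes=((1, 4), (1, 4), (1, 4)))


@dataclass(frozen=True)
class SubnetworkSpec:
    """One cascade subnetwork: dual conv trunks + fused dense head.

    n_classes is 3 for the type stage (low / motion / myoelectric) and 2
    for each level stage (mild / severe).
    """

    n_classes: int
    cnn1: StageSpec = CNN1_DEFAULT
    cnn2: StageSpec = CNN2_DEFAULT
    hidden_units: int = 128
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes not in (2, 3):
            raise ValueError("subnetworks classify 2 or 3 classes")


@dataclass(frozen=True)
class BaselineSpec:
    """Single-trunk five-class baseline on the raw segment."""

    n_classes: int = 5
    cnn: StageSpec = CNN2_DEFAULT
    hidden_units: int = 128


def _conv_trunk(kind: ConvBlockKind, stage: StageSpec, rng: np.random.Generator) -> Sequential:
    layers: list = []
    cin = 1
    for depth, ch, pool in zip(stage.block_counts, stage.channels, stage.pool_sizes):
        for _ in range(depth):
            layers += [
                Conv2d(cin, ch, kind.kernel, rng, input_grad=bool(layers)),
                BatchNorm(ch),
                ReLU(),
            ]
            cin = ch
        layers.append(MaxPool2d(pool))
    layers += [Conv2d(cin, stage.tail_channels, (1, 1), rng), ReLU(), Flatten()]
    return Sequential(layers)


def _trunk_output_size(stage: StageSpec, input_hw: tuple[int, int]) -> int:
    h, w = input_hw
    for ph, pw in stage.pool_sizes:
        h, w = h // ph, w // pw
    return h * w * stage.tail_channels


class SubnetworkModel:
    """Dual-branch classifier: (spectrogram, raw segment) -> K probabilities."""

    def __init__(self, spec: SubnetworkSpec, seed: int) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.cnn1 = _conv_trunk(ConvBlockKind.BLOCK1, spec.cnn1, rng)
        self.cnn2 = _conv_trunk(ConvBlockKind.BLOCK2, spec.cnn2, rng)
        self._m = _trunk_output_size(spec.cnn1, (N_FREQ_BINS, N_FRAMES))
        self._n = _trunk_output_size(spec.cnn2, (1, SEGMENT_SAMPLES))
        self.head = Sequential([
            Dense(self._m + self._n, spec.hidden_units, rng),
            ReLU(),
            Dropout(spec.dropout_p, np.random.default_rng(seed + 1)),
            Dense(spec.hidden_units, spec.n_classes, rng),
            Softmax(),
        ])

    @property
    def feature_sizes(self) -> tuple[int, int]:
        """Flattened feature-vector lengths (spectrogram branch, raw branch)."""
        return self._m, self._n

    def forward(self, spec_x: np.ndarray, sig_x: np.ndarray,
                training: bool = False) -> np.ndarray:
        m = self.cnn1.forward(spec_x, training)
        n = self.cnn2.forward(sig_x, training)
        return self.head.forward(np.concatenate([m, n], axis=1), training)

    def backward(self, dout: np.ndarray, from_logits: bool = False) -> None:
        """Backpropagate dL/d(probabilities), or dL/d(logits) when a fused
        loss gradient bypasses the softmax Jacobian."""
        grad = dout
        layers = self.head.layers[:-1] if from_logits else self.head.layers
        for layer in reversed(layers):
            grad = layer.backward(grad)
        self.cnn1.backward(grad[:, : self._m])
        self.cnn2.backward(grad[:, self._m:])

    def layers(self) -> list:
        return (list(self.cnn1.iter_layers()) + list(self.cnn2.iter_layers())
                + list(self.head.iter_layers()))


class BaselineModel:
    """Single-branch classifier: raw segment -> 5 probabilities."""

    def __init__(self, spec: BaselineSpec, seed: int) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.cnn = _conv_trunk(ConvBlockKind.BLOCK2, spec.cnn, rng)
        self._n = _trunk_output_size(spec.cnn, (1, SEGMENT_SAMPLES))
        self.head = Sequential([
            Dense(self._n, spec.hidden_units, rng),
            ReLU(),
            Dense(spec.hidden_units, spec.n_classes, rng),
            Softmax(),
        ])

    def forward(self, sig_x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.head.forward(self.cnn.forward(sig_x, training), training)

    def backward(self, dout: np.ndarray, from_logits: bool = False) -> None:
        grad = dout
        layers = self.head.layers[:-1] if from_logits else self.head.layers
        for layer in reversed(layers):
            grad = layer.backward(grad)
        self.cnn.backward(grad)

    def layers(self) -> list:
        return list(self.cnn.iter_layers()) + list(self.head.iter_layers())


def build_subnetwork(spec: SubnetworkSpec, seed: int) -> SubnetworkModel:
    """Construct a cascade subnetwork with He-initialized weights."""
    return SubnetworkModel(spec, seed)


def build_baseline(spec: BaselineSpec = BaselineSpec(), seed: int = 0) -> BaselineModel:
    """Construct the five-class baseline with He-initialized weights."""
    return BaselineModel(spec, seed)


def count_trainable_parameters(model) -> int:
    """Total element count over conv kernels and biases, batch-norm scales
    and shifts, and dense weights and biases."""
    return sum(layer.n_parameters() for layer in model.layers())


def cross_entropy_loss(predicted: np.ndarray, target: np.ndarray,
                       form: str = "bernoulli_sum") -> float:
    """Scalar training loss between predicted probabilities and one-hot
    targets (single sample or batch; batches return the mean).

    ``form="bernoulli_sum"`` (default) sums a Bernoulli term per class;
    ``form="categorical"`` is plain categorical cross-entropy.
    """
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float))
    target = np.atleast_2d(np.asarray(target, dtype=float))
    fn = {"bernoulli_sum": bernoulli_sum_loss,
          "categorical": categorical_cross_entropy_loss}[form]
    loss, _ = fn(predicted, target)
    return loss


# ---------------------------------------------------------------------------
# Checkpoint serialization: weights in HDF5, architecture in a JSON sidecar
# whose hash is validated on load.

def _spec_dict(model) -> dict:
    if isinstance(model, SubnetworkModel):
        return {"kind": "subnetwork", "spec": asdict(model.spec)}
    if isinstance(model, BaselineModel):
        return {"kind": "baseline", "spec": asdict(model.spec)}
    raise TypeError(f"unknown model type {type(model)!r}")


def _spec_hash(spec: dict) -> str:
    return hashlib.sha256(json.dumps(spec, sort_keys=True).encode()).hexdigest()


def save_model(model, path: str | Path) -> None:
    """Write weights (HDF5) and an architecture sidecar (JSON) next to it."""
    path = Path(path)
    spec = _spec_dict(model)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"spec": spec, "hash": _spec_hash(spec)}, indent=2))
    with h5py.File(path, "w") as f:
        f.attrs["spec_hash"] = _spec_hash(spec)
        for k, layer in enumerate(model.layers()):
            grp = f.create_group(f"layer_{k:03d}")
            for name, value in layer.params.items():
                grp.create_dataset(name, data=value, track_times=False)
            if isinstance(layer, BatchNorm):
                grp.create_dataset("running_mean", data=layer.running_mean,
                                   track_times=False)
                grp.create_dataset("running_var", data=layer.running_var,
                                   track_times=False)


def load_model(path: str | Path):
    """Rebuild a model from its checkpoint, validating the spec hash."""
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = sidecar["spec"]
    if _spec_hash(spec) != sidecar["hash"]:
        raise ValueError("architecture sidecar hash mismatch")

    def _stage(d: dict) -> StageSpec:
        return StageSpec(
            block_counts=tuple(d["block_counts"]),
            channels=tuple(d["channels"]),
            pool_sizes=tuple(tuple(p) for p in d["pool_sizes"]),
            tail_channels=d["tail_channels"],
        )

    if spec["kind"] == "subnetwork":
        s = spec["spec"]
        model = SubnetworkModel(
            SubnetworkSpec(n_classes=s["n_classes"], cnn1=_stage(s["cnn1"]),
                           cnn2=_stage(s["cnn2"]), hidden_units=s["hidden_units"],
                           dropout_p=s["dropout_p"]),
            seed=0,
        )
    else:
        s = spec["spec"]
        model = BaselineModel(
            BaselineSpec(n_classes=s["n_classes"], cnn=_stage(s["cnn"]),
                         hidden_units=s["hidden_units"]),
            seed=0,
        )

    with h5py.File(path, "r") as f:
        if f.attrs["spec_hash"] != sidecar["hash"]:
            raise ValueError("checkpoint/sidecar hash mismatch")
        for k, layer in enumerate(model.layers()):
            grp = f[f"layer_{k:03d}"]
            for name in layer.params:
                layer.params[name] = grp[name][...]
            if isinstance(layer, BatchNorm):
                layer.running_mean = grp["running_mean"][...]
                layer.running_var = grp["running_var"][...]
    return model
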