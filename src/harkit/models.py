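"""The four classifier architectures and the training harness.

Architectures are declared as ordered layer-descriptor lists with explicit
output shapes (``ModelArchitecture``), then compiled onto the package's
numpy engine. The four builders:

* **SC-CNN** — for single-plane images (14×60×1 single-channel layout, or
  the unaltered 6×60×1): conv 20@2×2 (stride 1) → batch-norm → rectifier →
  average-pool 2×4 → conv 40@3×3 → batch-norm → rectifier → average-pool
  1×2 → flatten → dense 512 → 8-class softmax.
* **DC-CNN** — the same stack for the 7×60×2 double-channel layout; the
  first kernels span both channels (2×2×2) and the dense stage is 256-wide.
* **LSTM** — 100 hidden units over the 60-timestep, 6-feature raw window,
  then a dense 8-class softmax.
* **ConvLSTM** — the window reshaped into 4 subsequences of 15 samples
  (4×1×15×6); a convolutional-recurrent layer with 64 kernels of size 1×3,
  full sequence flattened, dense 512, 8-class softmax.

Training uses Adam with an exponentially decaying learning rate
(initial 1e-4, rate 0.9 per 1000 steps, continuous by default),
mini-batches of 50, and batch normalization after each convolution.
Convolution padding is 'same' and pooling 'valid'; both conventions are
package choices, and printed parameter totals are informational only.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .labels import ActivityLabel, N_CLASSES
from .representations import RepresentationTag
from .structuring import Layout, VirtualImage, frame_to_image, layout_shape
from .windowing import DatasetSplit, WindowFrame, to_grayscale
from . import nn

#: ConvLSTM input adaptation: the 60-sample window is split into
#: (subsequences, image rows, samples per subsequence).
CONVLSTM_STEPS = 4
CONVLSTM_SUBLEN = 15


# ---------------------------------------------------------------------------
# declarative architecture


@dataclass(frozen=True)
class LayerSpec:
    """One layer descriptor: kind, hyperparameters and declared output shape."""

    kind: str
    output_shape: Tuple[int, ...]
    params: Dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelArchitecture:
    """Declarative description of one classifier.

    ``input_kind`` states how a 6×W window frame is adapted to the input:
    ``"image"`` (via a virtual-image layout), ``"sequence"`` (timesteps ×
    features) or ``"conv_sequence"`` (subsequences of a spatio-temporal
    grid).
    """

    name: str
    input_shape: Tuple[int, ...]
    layers: Tuple[LayerSpec, ...]
    input_kind: str
    layout: Optional[Layout] = None
    output_dim: int = N_CLASSES

    def __post_init__(self) -> None:
        if not self.layers or self.layers[-1].kind != "softmax":
            raise ValueError("the last layer must be an 8-class softmax")
        if self.layers[-1].output_shape != (self.output_dim,):
            raise ValueError("softmax output dim mismatch")

    def declared_shapes(self) -> List[Tuple[int, ...]]:
        return [spec.output_shape for spec in self.layers]

    def param_count(self, seed: int = 0) -> int:
        """Trainable parameter total of the compiled network."""
        return compile_network(self, seed=seed).n_params

    def to_json_dict(self) -> Dict:
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "input_kind": self.input_kind,
            "layout": self.layout.value if self.layout else None,
            "output_dim": self.output_dim,
            "layers": [
                {"kind": s.kind, "output_shape": list(s.output_shape),
                 "params": s.params}
                for s in self.layers
            ],
        }


def _conv_block(h, w, c, filters, kernel):
    """conv('same', stride 1) + batch-norm + rectifier layer specs."""
    shape = (h, w, filters)
    return [
        LayerSpec("conv2d", shape,
                  {"filters": filters, "kernel": list(kernel), "padding": "same",
                   "in_channels": c}),
        LayerSpec("batch_norm", shape, {"n_features": filters}),
        LayerSpec("relu", shape),
    ]


def _cnn_specs(h: int, w: int, c: int, dense_units: int) -> Tuple[LayerSpec, ...]:
    specs: List[LayerSpec] = []
    specs += _conv_block(h, w, c, 20, (2, 2))
    h2, w2 = h // 2, w // 4
    specs.append(LayerSpec("avg_pool", (h2, w2, 20), {"pool": [2, 4]}))
    specs += _conv_block(h2, w2, 20, 40, (3, 3))
    h3, w3 = h2 // 1, w2 // 2
    specs.append(LayerSpec("avg_pool", (h3, w3, 40), {"pool": [1, 2]}))
    flat = h3 * w3 * 40
    specs.append(LayerSpec("flatten", (flat,)))
    specs.append(LayerSpec("dense", (dense_units,), {"units": dense_units}))
    specs.append(LayerSpec("relu", (dense_units,)))
    specs.append(LayerSpec("dense", (N_CLASSES,), {"units": N_CLASSES}))
    specs.append(LayerSpec("softmax", (N_CLASSES,)))
    return tuple(specs)


def build_sc_cnn(input_shape: Tuple[int, int, int] = (14, 60, 1)) -> ModelArchitecture:
    """Single-channel CNN (dense width 512) for 14×W×1 or 6×W×1 images."""
    h, w, c = input_shape
    if c != 1:
        raise ValueError(f"SC-CNN expects a single-plane image, got C={c}")
    if h < 4 or w < 8:
        raise ValueError(f"input {input_shape} too small for the conv/pool stack")
    layout = Layout.SC if h == 14 else (Layout.UNALTERED if h == 6 else None)
    return ModelArchitecture(
        name="sc_cnn", input_shape=input_shape, input_kind="image",
        layout=layout, layers=_cnn_specs(h, w, c, dense_units=512))


def build_dc_cnn(input_shape: Tuple[int, int, int] = (7, 60, 2)) -> ModelArchitecture:
    """Double-channel CNN (first kernels 2×2×2, dense width 256)."""
    h, w, c = input_shape
    if c != 2:
        raise ValueError(f"DC-CNN expects a two-channel image, got C={c}")
    if h < 4 or w < 8:
        raise ValueError(f"input {input_shape} too small for the conv/pool stack")
    return ModelArchitecture(
        name="dc_cnn", input_shape=input_shape, input_kind="image",
        layout=Layout.DC, layers=_cnn_specs(h, w, c, dense_units=256))


def build_lstm(input_shape: Tuple[int, int] = (60, 6)) -> ModelArchitecture:
    """LSTM over the raw window: one timestep per sample, 6 features each."""
    t, f = input_shape
    specs = (
        LayerSpec("lstm", (100,), {"units": 100, "in_features": f}),
        LayerSpec("dense", (N_CLASSES,), {"units": N_CLASSES}),
        LayerSpec("softmax", (N_CLASSES,)),
    )
    return ModelArchitecture(
        name="lstm", input_shape=input_shape, input_kind="sequence", layers=specs)


def build_convlstm(
    input_shape: Tuple[int, int, int, int] = (CONVLSTM_STEPS, 1, CONVLSTM_SUBLEN, 6),
) -> ModelArchitecture:
    """Convolutional-recurrent classifier: 64 kernels of size 1×3.

    The window is reshaped to ``(steps, 1, sublen, channels)`` subsequences;
    the recurrent layer returns the full hidden sequence, which is
    flattened into the dense stage.
    """
    t, h, w, c = input_shape
    seq_shape = (t, h, w, 64)
    flat = t * h * w * 64
    specs = (
        LayerSpec("convlstm2d", seq_shape,
                  {"filters": 64, "kernel": [1, 3], "in_channels": c}),
        LayerSpec("flatten", (flat,)),
        LayerSpec("dense", (512,), {"units": 512}),
        LayerSpec("relu", (512,)),
        LayerSpec("dense", (N_CLASSES,), {"units": N_CLASSES}),
        LayerSpec("softmax", (N_CLASSES,)),
    )
    return ModelArchitecture(
        name="convlstm", input_shape=input_shape, input_kind="conv_sequence",
        layers=specs)


ARCHITECTURE_BUILDERS = {
    "sc_cnn": build_sc_cnn,
    "dc_cnn": build_dc_cnn,
    "lstm": build_lstm,
    "convlstm": build_convlstm,
}


def compile_network(arch: ModelArchitecture, seed: int = 0) -> nn.Network:
    """Instantiate the declared layers on the numpy engine, seeded."""
    ss = np.random.SeedSequence(seed)
    layers: List[nn.Layer] = []
    for spec, child in zip(arch.layers, ss.spawn(len(arch.layers))):
        rng = np.random.default_rng(child)
        p = spec.params
        if spec.kind == "conv2d":
            layers.append(nn.Conv2D(p["in_channels"], p["filters"],
                                    tuple(p["kernel"]), p["padding"], rng=rng))
        elif spec.kind == "batch_norm":
            layers.append(nn.BatchNorm(p["n_features"]))
        elif spec.kind == "relu":
            layers.append(nn.ReLU())
        elif spec.kind == "avg_pool":
            layers.append(nn.AvgPool2D(tuple(p["pool"])))
        elif spec.kind == "flatten":
            layers.append(nn.Flatten())
        elif spec.kind == "dense":
            in_features = _dense_in_features(arch, spec)
            layers.append(nn.Dense(in_features, p["units"], rng=rng))
        elif spec.kind == "lstm":
            layers.append(nn.LSTM(p["in_features"], p["units"], rng=rng))
        elif spec.kind == "convlstm2d":
            layers.append(nn.ConvLSTM2D(p["in_channels"], p["filters"],
                                        tuple(p["kernel"]), rng=rng))
        elif spec.kind == "softmax":
            layers.append(nn.Softmax())
        else:
            raise ValueError(f"unknown layer kind {spec.kind!r}")
    return nn.Network(layers)


def _dense_in_features(arch: ModelArchitecture, spec: LayerSpec) -> int:
    idx = arch.layers.index(spec)
    prev_shape = arch.layers[idx - 1].output_shape if idx else arch.input_shape
    return int(np.prod(prev_shape))


# ---------------------------------------------------------------------------
# learning-rate schedule and training configuration


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings (Adam throughout).

    The learning rate decays exponentially from ``lr0`` by ``decay_rate``
    every ``decay_steps`` optimizer steps, continuously unless
    ``staircase`` is set.
    """

    lr0: float = 1e-4
    decay_rate: float = 0.9
    decay_steps: int = 1000
    staircase: bool = False
    batch_size: int = 50
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if not 0 < self.decay_rate <= 1:
            raise ValueError("decay_rate must lie in (0, 1]")
        if self.decay_steps < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("decay_steps, batch_size and epochs must be >= 1")


def lr_at_step(step: int, config: TrainingConfig = TrainingConfig()) -> float:
    """Learning rate after ``step`` optimizer steps.

    Continuous decay: ``lr0 * decay_rate ** (step / decay_steps)``;
    staircase uses the floor of the exponent.
    """
    if step < 0:
        raise ValueError("step must be non-negative")
    exponent = step / config.decay_steps
    if config.staircase:
        exponent = np.floor(exponent)
    return float(config.lr0 * config.decay_rate ** exponent)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_accuracy: float
    val_loss: Optional[float]
    val_accuracy: Optional[float]
    seconds: float


@dataclass
class TrainingHistory:
    """One record per completed epoch."""

    records: List[EpochRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def final(self) -> EpochRecord:
        return self.records[-1]


# ---------------------------------------------------------------------------
# window-frame -> network-input adaptation


def frames_to_inputs(
    frames: Sequence[WindowFrame],
    arch: ModelArchitecture,
    representation: RepresentationTag = RepresentationTag.TD,
    quantize: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Adapt window frames to the architecture's input tensor.

    Returns ``(X, y)`` with integer labels. ``quantize`` routes values
    through the 0–255 grayscale mapping first (off by default: the networks
    consume raw sensor values and batch normalization handles scale).
    """
    xs, ys = [], []
    for frame in frames:
        if frame.label is None:
            raise ValueError("training frames must be labeled")
        values = frame
        if quantize:
            values = WindowFrame(
                to_grayscale(frame).pixels.astype(float),
                label=frame.label, origin=frame.origin)
        if arch.input_kind == "image":
            if arch.layout is None:
                raise ValueError(f"{arch.name} declares no image layout")
            img = frame_to_image(values, representation, arch.layout)
            xs.append(img.values)
        elif arch.input_kind == "sequence":
            xs.append(values.values.T)  # (W, 6)
        elif arch.input_kind == "conv_sequence":
            t, h, w, c = arch.input_shape
            xs.append(values.values.T.reshape(t, w, c).reshape(t, h, w, c))
        else:
            raise ValueError(f"unknown input kind {arch.input_kind!r}")
        ys.append(int(frame.label))
    x = np.stack(xs) if xs else np.empty((0,) + tuple(arch.input_shape))
    if x.shape[1:] != tuple(arch.input_shape):
        raise ValueError(
            f"adapted input shape {x.shape[1:]} does not match the "
            f"architecture's {arch.input_shape}")
    return x, np.asarray(ys, dtype=int)


def images_to_array(images: Union[np.ndarray, Sequence[VirtualImage]]) -> np.ndarray:
    if isinstance(images, np.ndarray):
        return images
    return np.stack([img.values for img in images])


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainedModel:
    """A compiled, trained network plus everything needed to feed it."""

    network: nn.Network
    arch: ModelArchitecture
    representation: RepresentationTag
    rate: float = 50.0

    def predict_frames(self, frames: Sequence[WindowFrame]) -> np.ndarray:
        """Probability matrix (n_frames, 8) for unlabeled or labeled frames."""
        xs = []
        for frame in frames:
            labeled = frame if frame.label is not None else WindowFrame(
                frame.values, label=ActivityLabel.WALKING, origin=frame.origin)
            xs.append(labeled)
        x, _ = frames_to_inputs(xs, self.arch, self.representation)
        return self.network.predict_proba(x)

    def save(self, directory) -> None:
        """Weights as an .npz plus a JSON sidecar with the declaration."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        weights = self.network.get_weights()
        np.savez(directory / "weights.npz",
                 **{f"w{i}": w for i, w in enumerate(weights)})
        sidecar = {
            "architecture": self.arch.to_json_dict(),
            "representation": self.representation.value,
            "rate_hz": self.rate,
            "label_encoding": {m.name.lower(): int(m) for m in ActivityLabel},
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        name = sidecar["architecture"]["name"]
        input_shape = tuple(sidecar["architecture"]["input_shape"])
        arch = ARCHITECTURE_BUILDERS[name](input_shape)
        network = compile_network(arch)
        with np.load(directory / "weights.npz") as data:
            weights = [data[f"w{i}"] for i in range(len(data.files))]
        network.set_weights(weights)
        return cls(network=network, arch=arch,
                   representation=RepresentationTag(sidecar["representation"]),
                   rate=sidecar["rate_hz"])


def train_model(
    arch: ModelArchitecture,
    split: DatasetSplit,
    config: TrainingConfig = TrainingConfig(),
    representation: RepresentationTag = RepresentationTag.TD,
    quantize: bool = False,
    verbose: bool = False,
) -> Tuple[TrainedModel, TrainingHistory]:
    """Train an architecture on a dataset split.

    Seeded end to end: weight initialization and mini-batch shuffling both
    derive from ``config.seed``. Validation loss/accuracy are evaluated on
    ``split.validation`` after every epoch. A NaN training loss aborts with
    a diagnostic rather than continuing silently.
    """
    if not split.train:
        raise ValueError("empty training set")
    x_train, y_train = frames_to_inputs(split.train, arch, representation, quantize)
    x_val, y_val = (frames_to_inputs(split.validation, arch, representation, quantize)
                    if split.validation else (None, None))

    network = compile_network(arch, seed=config.seed)
    optimizer = nn.Adam(network.params,
                        lr_fn=lambda step: lr_at_step(step, config))
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))

    history = TrainingHistory()
    n = len(x_train)
    for epoch in range(config.epochs):
        start = time.perf_counter()
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            loss = network.train_step_gradients(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at epoch {epoch}, "
                    f"step {optimizer.step_count}; lr was "
                    f"{lr_at_step(optimizer.step_count, config):.3g}")
            optimizer.step(network.grads)
            losses.append(loss)
        train_probs = network.predict_proba(x_train)
        train_acc = float(np.mean(train_probs.argmax(axis=1) == y_train))
        if x_val is not None and len(x_val):
            val_probs = network.predict_proba(x_val)
            val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val))
            val_loss = network.evaluate_loss(x_val, y_val)
        else:
            val_acc = val_loss = None
        record = EpochRecord(
            epoch=epoch, train_loss=float(np.mean(losses)),
            train_accuracy=train_acc, val_loss=val_loss, val_accuracy=val_acc,
            seconds=time.perf_counter() - start)
        history.records.append(record)
        if verbose:
            msg = (f"epoch {epoch + 1:3d}/{config.epochs}  "
                   f"loss {record.train_loss:.4f}  acc {train_acc:.4f}")
            if val_acc is not None:
                msg += f"  val_acc {val_acc:.4f}"
            print(msg)

    model = TrainedModel(network=network, arch=arch, representation=representation)
    return model, history


def predict(
    model: Union[TrainedModel, nn.Network],
    images: Union[np.ndarray, Sequence[VirtualImage], Sequence[WindowFrame]],
) -> Tuple[np.ndarray, List[ActivityLabel]]:
    """Per-image probability vectors and argmax labels.

    Probabilities are non-negative and sum to 1 (within float tolerance);
    ties break to the lowest class index. Order-preserving and invariant to
    batch partitioning.
    """
    if isinstance(model, TrainedModel):
        network = model.network
        if (len(images) and isinstance(images[0], WindowFrame)):
            probs = model.predict_frames(images)  # type: ignore[arg-type]
        else:
            probs = network.predict_proba(images_to_array(images))
    else:
        network = model
        probs = network.predict_proba(images_to_array(images))
    labels = [ActivityLabel(int(i)) for i in probs.argmax(axis=1)]
    return probs, labels
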