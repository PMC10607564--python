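"""The compact convolutional denoising autoencoder (< 30,000 parameters).

The architecture is declared as a framework-independent
:class:`NetworkSpec` and realized on the numpy engine in :mod:`.nn`:

    input -> [conv 3x3/32 relu -> maxpool 2x2] x2        (encoder)
          -> [conv 3x3/32 relu -> upsample 2x2] x2       (decoder)
          -> conv 3x3/1 linear                           (output)

All convolutions use "same" zero padding, so the two 2x poolings and two
2x nearest-neighbour upsamplings make the network exactly
shape-preserving whenever both input dimensions are divisible by 4.  At
the native 536x232 input the encoded representation is (134, 58, 32) and
the parameter total is 320 + 3*9248 + 289 = 28,353.

Weights are Glorot/Xavier-initialized and trained with Adam
(beta1 = 0.9, beta2 = 0.999, eps = 1e-7, lr = 0.001); the reference
schedule is 1000 epochs, configurable for desk-scale runs.  The loss is
mean squared error between the network output and the clean target.
Images are scaled by 1/255 on entry and rescaled on exit; because the
output activation is linear, outputs are clipped to [0, 255] and min-max
normalized before any metric sees them.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .filters import FilterSpec, lee_filter
from .speckle import normalize_to_range

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "TrainSpec",
    "TrainedDenoiser",
    "build_cnn_ae",
    "count_parameters",
    "propagate_shapes",
    "realize",
    "train_denoiser",
    "train_filter_mimic",
]

LAYER_KINDS = (
    "input", "conv", "maxpool", "upsample",
    "batchnorm", "relu", "flatten", "dense", "dropout",
)


@dataclass(frozen=True)
class LayerSpec:
    """One declarative layer; only the fields its kind needs are set."""

    kind: str
    kernel: tuple[int, int] | None = None
    channels: int | None = None
    activation: str | None = None
    padding: str | None = None
    rate: float | None = None  # dropout only

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv" and (self.kernel is None or self.channels is None):
            raise ValueError("conv layers need kernel and channels")
        if self.kind in ("maxpool", "upsample") and self.kernel is None:
            raise ValueError(f"{self.kind} layers need a kernel")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layer list plus the (rows, cols, 1) input shape."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int]


@dataclass(frozen=True)
class TrainSpec:
    """Optimization schedule; defaults follow the reference configuration."""

    epochs: int = 1000
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    seed: int = 0
    loss: str = "mse"
    batch_size: int = 8

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("mse", "bce"):
            raise ValueError(f"unsupported loss {self.loss!r}")


def build_cnn_ae(input_shape: tuple[int, int, int] = (536, 232, 1)) -> NetworkSpec:
    """Declare the two-stage encoder/decoder denoising autoencoder."""
    rows, cols = input_shape[0], input_shape[1]
    if rows % 4 or cols % 4:
        pad_r, pad_c = (-rows) % 4, (-cols) % 4
        raise ValueError(
            f"input dims must be divisible by 4 (two 2x poolings); "
            f"{rows}x{cols} is not — pad to {rows + pad_r}x{cols + pad_c}"
        )
    conv = lambda ch, act: LayerSpec("conv", kernel=(3, 3), channels=ch,
                                     activation=act, padding="same")
    layers = (
        LayerSpec("input"),
        conv(32, "relu"), LayerSpec("maxpool", kernel=(2, 2)),
        conv(32, "relu"), LayerSpec("maxpool", kernel=(2, 2)),
        conv(32, "relu"), LayerSpec("upsample", kernel=(2, 2)),
        conv(32, "relu"), LayerSpec("upsample", kernel=(2, 2)),
        conv(1, "linear"),
    )
    return NetworkSpec(layers=layers, input_shape=(rows, cols, 1))


def propagate_shapes(net: NetworkSpec) -> list[tuple]:
    """Per-layer output shapes, mirroring an architecture-summary table."""
    shape: tuple = tuple(net.input_shape)
    shapes: list[tuple] = []
    for layer in net.layers:
        if layer.kind == "input":
            pass
        elif layer.kind == "conv":
            shape = (shape[0], shape[1], layer.channels)
        elif layer.kind == "maxpool":
            shape = (shape[0] // 2, shape[1] // 2, shape[2])
        elif layer.kind == "upsample":
            shape = (shape[0] * 2, shape[1] * 2, shape[2])
        elif layer.kind in ("batchnorm", "relu", "dropout"):
            pass
        elif layer.kind == "flatten":
            shape = (int(np.prod(shape)),)
        elif layer.kind == "dense":
            shape = (layer.channels,)
        shapes.append(shape)
    return shapes


def count_parameters(net: NetworkSpec) -> tuple[list[tuple[str, int]], int]:
    """Per-layer parameter counts and their total.

    Conventions: conv = k*k*c_in*c_out + c_out; dense = n_in*n_out + n_out;
    batch normalization = 4*channels (scale/shift plus moving moments);
    pooling, upsampling, activations, flatten and dropout carry none.
    """
    shapes = propagate_shapes(net)
    in_shape: tuple = tuple(net.input_shape)
    rows: list[tuple[str, int]] = []
    for layer, out_shape in zip(net.layers, shapes):
        if layer.kind == "conv":
            k = layer.kernel[0]
            count = k * k * in_shape[-1] * layer.channels + layer.channels
            desc = f"conv {k}x{k}/{layer.channels}"
        elif layer.kind == "batchnorm":
            count = 4 * in_shape[-1]
            desc = "batchnorm"
        elif layer.kind == "dense":
            count = in_shape[0] * layer.channels + layer.channels
            desc = f"dense {layer.channels}"
        else:
            count, desc = 0, layer.kind
        rows.append((desc, count))
        in_shape = out_shape
    return rows, sum(c for _, c in rows)


def realize(net: NetworkSpec, seed: int = 0) -> nn.Sequential:
    """Instantiate the declared network on the numpy engine."""
    layers: list[nn.Layer] = []
    in_shape: tuple = tuple(net.input_shape)
    for layer, out_shape in zip(net.layers, propagate_shapes(net)):
        if layer.kind == "conv":
            layers.append(nn.Conv2D(in_shape[-1], layer.channels,
                                    kernel=layer.kernel[0],
                                    activation=layer.activation or "linear"))
        elif layer.kind == "maxpool":
            layers.append(nn.MaxPool2x2())
        elif layer.kind == "upsample":
            layers.append(nn.Upsample2x())
        elif layer.kind == "batchnorm":
            layers.append(nn.BatchNorm(in_shape[-1]))
        elif layer.kind == "relu":
            layers.append(nn.ReLU())
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
        elif layer.kind == "dense":
            layers.append(nn.Dense(in_shape[0], layer.channels,
                                   activation=layer.activation or "linear"))
        elif layer.kind == "dropout":
            layers.append(nn.Dropout(layer.rate))
        in_shape = out_shape
    return nn.Sequential(layers, seed=seed)


@dataclass
class TrainedDenoiser:
    """A realized, trained network plus everything needed to rebuild it."""

    net: NetworkSpec
    model: nn.Sequential
    history: list[float] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)
    timing: dict = field(default_factory=dict)

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return tuple(self.net.input_shape)

    def denoise(self, image: np.ndarray) -> np.ndarray:
        """Single deterministic forward pass, output in [0, 255]."""
        image = np.asarray(image, dtype=np.float64)
        if image.shape != self.input_shape[:2]:
            raise ValueError(
                f"image shape {image.shape} does not match model input "
                f"{self.input_shape[:2]}"
            )
        x = (image / 255.0).astype(np.float32)[None, :, :, None]
        out = self.model.forward(x, training=False)[0, :, :, 0].astype(np.float64)
        return normalize_to_range(np.clip(out * 255.0, 0.0, 255.0))

    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        config = {
            "input_shape": list(self.net.input_shape),
            "layers": [
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(layer).items() if v is not None}
                for layer in self.net.layers
            ],
        }
        (model_dir / "config.yaml").write_text(yaml.safe_dump(config))
        weights = self.model.get_weights()
        np.savez(model_dir / "weights.npz",
                 **{f"w{i}": w for i, w in enumerate(weights)})

    @classmethod
    def load(cls, model_dir: str | Path) -> "TrainedDenoiser":
        model_dir = Path(model_dir)
        config = yaml.safe_load((model_dir / "config.yaml").read_text())
        layers = tuple(
            LayerSpec(**{k: (tuple(v) if k == "kernel" else v)
                         for k, v in entry.items()})
            for entry in config["layers"]
        )
        net = NetworkSpec(layers=layers, input_shape=tuple(config["input_shape"]))
        model = realize(net, seed=0)
        with np.load(model_dir / "weights.npz") as data:
            model.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return cls(net=net, model=model)


def _stack(images, input_shape) -> np.ndarray:
    arr = []
    for img in images:
        img = np.asarray(img, dtype=np.float64)
        if img.shape != tuple(input_shape[:2]):
            raise ValueError(
                f"image shape {img.shape} does not match input_shape "
                f"{tuple(input_shape[:2])}"
            )
        arr.append(img)
    return (np.stack(arr) / 255.0).astype(np.float32)[..., None]


def _train(x, y, net: NetworkSpec, spec: TrainSpec) -> TrainedDenoiser:
    init_seed, shuffle_seed = (
        int(s) for s in np.random.SeedSequence(spec.seed).generate_state(2) >> np.uint32(1)
    )
    model = realize(net, seed=init_seed)
    optimizer = nn.Adam(model, lr=spec.learning_rate, beta1=spec.beta1,
                        beta2=spec.beta2, epsilon=spec.epsilon)
    log: list[dict] = []
    history = nn.fit(model, x, y, epochs=spec.epochs, batch_size=spec.batch_size,
                     optimizer=optimizer, loss=spec.loss,
                     shuffle_seed=shuffle_seed, log=log)
    return TrainedDenoiser(net=net, model=model, history=history, log=log)


def train_denoiser(pairs, net: NetworkSpec, spec: TrainSpec) -> TrainedDenoiser:
    """Fit the autoencoder on (noised, clean) image pairs."""
    if not pairs:
        raise ValueError("pairs must be non-empty")
    x = _stack([p[0] for p in pairs], net.input_shape)
    y = _stack([p[1] for p in pairs], net.input_shape)
    return _train(x, y, net, spec)


def train_filter_mimic(originals, net: NetworkSpec, spec: TrainSpec,
                       filter_spec: FilterSpec = FilterSpec()) -> TrainedDenoiser:
    """Train the autoencoder to reproduce the Lee filter's output.

    Targets are generated internally by Lee-filtering the originals.  The
    returned model's ``timing`` dict records mean per-image wall time for
    the Lee filter and for autoencoder inference (informational only).
    """
    originals = list(originals)
    if not originals:
        raise ValueError("originals must be non-empty")
    t0 = time.perf_counter()
    targets = [lee_filter(np.asarray(img, dtype=np.float64), filter_spec)
               for img in originals]
    lee_time = (time.perf_counter() - t0) / len(originals)
    trained = _train(_stack(originals, net.input_shape),
                     _stack(targets, net.input_shape), net, spec)
    t0 = time.perf_counter()
    for img in originals:
        trained.denoise(np.asarray(img, dtype=np.float64))
    trained.timing = {
        "lee_filter_s_per_image": lee_time,
        "inference_s_per_image": (time.perf_counter() - t0) / len(originals),
    }
    return trained
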