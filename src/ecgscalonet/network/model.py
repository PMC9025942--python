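"""Model assembly: the hybrid 2D-CNN -> LSTM classifier.

The network applies a CNN trunk (conv + ReLU + normalisation + 2x2/2 max
pooling blocks) to each scalogram image, reads the final feature map as a
top-to-bottom sequence of row-feature vectors, runs a single (peephole) LSTM
over that sequence, and classifies the last hidden state through fully
connected layers with dropout before the final 3-way softmax.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import (
    BatchNormLayer,
    Conv2D,
    ConvGeometry,
    CrossChannelNorm,
    Dense,
    Dropout,
    FlattenToSequence,
    GeometryError,
    Layer,
    MaxPool2D,
    ReLULayer,
    conv_output_shape,
    softmax,
)
from .lstm import LSTMLayer

__all__ = ["ConvBlockSpec", "ModelSpec", "Model", "build_model", "ConstructionError"]


class ConstructionError(ValueError):
    """A spec whose forward shape trace fails, naming the offending layer."""


@dataclass(frozen=True)
class ConvBlockSpec:
    """One conv block: Conv2D + ReLU + normalisation + optional 2x2/2 pool.

    ``norm`` is "cross_channel" (local response normalisation, window 5),
    "batch", or None.
    """

    filters: int
    kernel: int = 3
    stride: int = 1
    padding: int = 1
    norm: str | None = "batch"
    pool: bool = True


@dataclass(frozen=True)
class ModelSpec:
    input_shape: tuple[int, int, int] = (227, 227, 3)
    conv_blocks: tuple[ConvBlockSpec, ...] = (
        ConvBlockSpec(64, norm="cross_channel"),
        ConvBlockSpec(128),
        ConvBlockSpec(256),
    )
    lstm_hidden_units: int = 32
    peephole: bool = True
    fc_sizes: tuple[int, ...] = (64,)
    dropout_rate: float = 0.5
    n_classes: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.lstm_hidden_units < 1:
            raise ValueError("lstm_hidden_units must be positive")

    @classmethod
    def scaled_down(cls, image_size: int = 112) -> "ModelSpec":
        """Desk-scale preset: two light conv blocks, LSTM hidden 32."""
        return cls(
            input_shape=(image_size, image_size, 3),
            conv_blocks=(
                ConvBlockSpec(8, norm="cross_channel"),
                ConvBlockSpec(16),
            ),
            lstm_hidden_units=32,
            fc_sizes=(32,),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conv_blocks"] = [asdict(b) for b in self.conv_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["conv_blocks"] = tuple(ConvBlockSpec(**b) for b in d["conv_blocks"])
        d["input_shape"] = tuple(d["input_shape"])
        d["fc_sizes"] = tuple(d["fc_sizes"])
        return cls(**d)


class Model:
    """An ordered layer stack with a shape trace and seeded dropout."""

    def __init__(self, layers: list[Layer], spec: ModelSpec,
                 shape_trace: list[tuple[str, tuple, int]], seed: int):
        self.layers = layers
        self.spec = spec
        self.shape_trace = shape_trace
        self.seed = seed

    # -- inference ---------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (N, n_classes) for a batch of images (N, H, W, 3) in [0,1]."""
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dlogits = layer.backward(dlogits)
        return dlogits

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        out = [
            softmax(self.forward(x[i : i + batch_size], train=False))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, classes, batch_size: int = 32) -> list:
        probs = self.predict_proba(x, batch_size=batch_size)
        return [classes[i] for i in probs.argmax(axis=1)]

    # -- bookkeeping -------------------------------------------------------

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers)

    def parameters(self):
        """Yield (unique_key, layer, param_name) triples."""
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                yield f"{i}:{layer.name}:{name}", layer, name

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: layer.params[n].copy() for k, layer, n in self.parameters()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k, layer, n in self.parameters():
            layer.params[n] = state[k].copy()

    def save(self, path) -> None:
        """Checkpoint: .npz weights plus an architecture JSON sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez(path, **self.get_state())
        arch = {"spec": self.spec.to_dict(), "seed": self.seed,
                "n_params": self.n_params}
        path.with_suffix(".json").write_text(json.dumps(arch, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "Model":
        path = Path(path)
        arch = json.loads(path.with_suffix(".json").read_text())
        model = build_model(ModelSpec.from_dict(arch["spec"]), seed=arch["seed"])
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
            model.set_state({k: z[k] for k in z.files})
        return model


def build_model(spec: ModelSpec, seed: int = 0) -> Model:
    """Construct the model, validating the full forward shape trace.

    Raises :class:`ConstructionError` naming the first layer whose output
    geometry degenerates.
    """
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    trace: list[tuple[str, tuple, int]] = []
    h, w, c = spec.input_shape
    trace.append(("input", (h, w, c), 0))

    def log(layer: Layer, shape: tuple) -> None:
        layers.append(layer)
        trace.append((layer.name, shape, layer.n_params))

    for bi, blk in enumerate(spec.conv_blocks):
        try:
            h, w = conv_output_shape(ConvGeometry(h, w, blk.kernel, blk.kernel,
                                                  blk.padding, blk.stride))
        except GeometryError as exc:
            raise ConstructionError(f"conv block {bi + 1}: {exc}") from exc
        conv = Conv2D(c, blk.filters, blk.kernel, blk.stride, blk.padding, rng=rng)
        c = blk.filters
        log(conv, (h, w, c))
        log(ReLULayer(), (h, w, c))
        if blk.norm == "cross_channel":
            log(CrossChannelNorm(), (h, w, c))
        elif blk.norm == "batch":
            log(BatchNormLayer(c), (h, w, c))
        elif blk.norm is not None:
            raise ConstructionError(f"conv block {bi + 1}: unknown norm {blk.norm!r}")
        if blk.pool:
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ConstructionError(
                    f"conv block {bi + 1}: pooling collapses feature map to "
                    f"{h}x{w}"
                )
            log(MaxPool2D(2), (h, w, c))

    log(FlattenToSequence(), (h, w * c))
    lstm = LSTMLayer(w * c, spec.lstm_hidden_units, rng=rng, peephole=spec.peephole)
    log(lstm, (spec.lstm_hidden_units,))
    width = spec.lstm_hidden_units
    for size in spec.fc_sizes:
        if size < 1:
            raise ConstructionError(f"fully connected size {size} invalid")
        log(Dense(width, size, rng=rng), (size,))
        log(ReLULayer(), (size,))
        width = size
    if spec.dropout_rate > 0:
        log(Dropout(spec.dropout_rate, rng=rng), (width,))
    log(Dense(width, spec.n_classes, rng=rng), (spec.n_classes,))
    return Model(layers, spec, trace, seed)
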