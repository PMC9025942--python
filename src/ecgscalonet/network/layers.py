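"""Feed-forward layer primitives with explicit forward/backward passes.

All image tensors are channels-last ``(N, H, W, C)`` float arrays. Every
layer caches what its backward pass needs during ``forward(..., train=True)``
and accumulates parameter gradients into ``self.grads`` keyed like
``self.params``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ConvGeometry",
    "conv_output_shape",
    "relu",
    "batch_norm",
    "softmax",
    "Layer",
    "Conv2D",
    "ReLULayer",
    "BatchNormLayer",
    "CrossChannelNorm",
    "MaxPool2D",
    "FlattenToSequence",
    "Dense",
    "Dropout",
]


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------

from dataclasses import dataclass


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ConvGeometry:
    """Input/filter geometry of a 2-D convolution or pooling window."""

    input_height: int
    input_width: int
    filter_height: int
    filter_width: int
    padding: int = 0
    stride: int = 1

    def __post_init__(self) -> None:
        if min(self.input_height, self.input_width,
               self.filter_height, self.filter_width, self.stride) < 1:
            raise GeometryError("dimensions and stride must be positive")
        if self.padding < 0:
            raise GeometryError("padding must be nonnegative")


def conv_output_shape(geom: ConvGeometry) -> tuple[int, int]:
    """Output (height, width) of a convolution window sweep.

    OUT = floor((dim + 2 * padding - filter) / stride) + 1 per axis.
    """
    out_h = (geom.input_height + 2 * geom.padding - geom.filter_height) // geom.stride + 1
    out_w = (geom.input_width + 2 * geom.padding - geom.filter_width) // geom.stride + 1
    if out_h < 1 or out_w < 1:
        raise GeometryError(
            f"filter {geom.filter_height}x{geom.filter_width} does not fit input "
            f"{geom.input_height}x{geom.input_width} (pad {geom.padding}, "
            f"stride {geom.stride})"
        )
    return out_h, out_w


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def batch_norm(batch: np.ndarray, epsilon: float = 0.001) -> np.ndarray:
    """Normalise a batch per feature: (y - mean) / sqrt(var + epsilon).

    Mean and variance are taken over the batch axis (axis 0), with the
    population (divide-by-n) variance.
    """
    batch = np.asarray(batch, dtype=np.float64)
    if batch.shape[0] < 1 or batch.size == 0:
        raise ValueError("batch must contain at least one item")
    mean = batch.mean(axis=0)
    var = batch.var(axis=0)  # population variance
    return (batch - mean) / np.sqrt(var + epsilon)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction); rows sum to 1."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# im2col helpers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, fh: int, fw: int, stride: int, padding: int):
    n, h, w, c = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    oh = (h + 2 * padding - fh) // stride + 1
    ow = (w + 2 * padding - fw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (fh, fw), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (n, oh, ow, c, fh, fw)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * oh * ow, fh * fw * c)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols, x_shape, fh, fw, stride, padding, oh, ow):
    n, h, w, c = x_shape
    hp, wp = h + 2 * padding, w + 2 * padding
    dxp = np.zeros((n, hp, wp, c), dtype=dcols.dtype)
    dwin = dcols.reshape(n, oh, ow, fh, fw, c)
    for i in range(fh):
        for j in range(fw):
            dxp[:, i : i + oh * stride : stride, j : j + ow * stride : stride, :] += (
                dwin[:, :, :, i, j, :]
            )
    if padding:
        return dxp[:, padding : padding + h, padding : padding + w, :]
    return dxp


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    name: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv2D(Layer):
    """2-D convolution (channels-last) via im2col."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 stride: int = 1, padding: int = 1, *, rng: np.random.Generator):
        super().__init__()
        self.name = f"conv{kernel}x{kernel}-{filters}"
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.in_channels, self.filters = in_channels, filters
        fan_in = kernel * kernel * in_channels
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), size=(fan_in, filters)
        ).astype(np.float32)
        self.params["b"] = np.zeros(filters, dtype=np.float32)

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride, self.padding)
        out = cols @ self.params["W"] + self.params["b"]
        self._cache = (cols, x.shape, oh, ow) if train else None
        return out.reshape(x.shape[0], oh, ow, self.filters)

    def backward(self, dout):
        cols, x_shape, oh, ow = self._cache
        dflat = dout.reshape(-1, self.filters)
        self.grads["W"] = cols.T @ dflat
        self.grads["b"] = dflat.sum(axis=0)
        dcols = dflat @ self.params["W"].T
        return _col2im(dcols, x_shape, self.kernel, self.kernel,
                       self.stride, self.padding, oh, ow)


class ReLULayer(Layer):
    name = "relu"

    def forward(self, x, train=False):
        out = np.maximum(0, x)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout):
        return dout * self._mask


class BatchNormLayer(Layer):
    """Per-channel batch normalisation with learned scale/shift.

    Statistics are taken over every axis except the last (channels), with the
    population variance; running estimates (momentum 0.9) are used in eval
    mode.
    """

    def __init__(self, channels: int, epsilon: float = 0.001, momentum: float = 0.9):
        super().__init__()
        self.name = f"batchnorm-{channels}"
        self.epsilon, self.momentum = epsilon, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.epsilon)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, axes, x.shape)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv_std, axes, x_shape = self._cache
        n = np.prod([x_shape[a] for a in axes])
        self.grads["gamma"] = (dout * xhat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.params["gamma"]
        return (inv_std / n) * (
            n * dxhat
            - dxhat.sum(axis=axes, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
        )


class CrossChannelNorm(Layer):
    """Local response normalisation across channels (window of 5 by default).

    b_c = a_c / (k + alpha/n * sum_{d in window(c)} a_d^2)^beta.
    """

    def __init__(self, window: int = 5, alpha: float = 1e-4,
                 beta: float = 0.75, k: float = 2.0):
        super().__init__()
        self.name = f"crosschannelnorm-{window}"
        self.window, self.alpha, self.beta, self.k = window, alpha, beta, k

    def _window_sum(self, x):
        half = self.window // 2
        c = x.shape[-1]
        pad = np.zeros(x.shape[:-1] + (c + 2 * half,), dtype=x.dtype)
        pad[..., half : half + c] = x
        csum = np.cumsum(pad, axis=-1)
        out = np.empty_like(x)
        out[..., 0] = csum[..., self.window - 1]
        out[..., 1:] = csum[..., self.window :] - csum[..., : c - 1]
        return out

    def forward(self, x, train=False):
        s = self._window_sum(x * x)
        denom = self.k + (self.alpha / self.window) * s
        out = x * denom ** (-self.beta)
        if train:
            self._cache = (x, denom)
        return out

    def backward(self, dout):
        x, denom = self._cache
        h = dout * x * denom ** (-self.beta - 1.0)
        return dout * denom ** (-self.beta) - (
            2.0 * self.alpha * self.beta / self.window
        ) * x * self._window_sum(h)


class MaxPool2D(Layer):
    """Non-overlapping max pooling (2x2 stride 2 by default), floor semantics."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.name = f"maxpool{size}x{size}"
        self.size = size

    def forward(self, x, train=False):
        n, h, w, c = x.shape
        s = self.size
        oh, ow = h // s, w // s
        xc = x[:, : oh * s, : ow * s, :]
        win = xc.reshape(n, oh, s, ow, s, c).transpose(0, 1, 3, 5, 2, 4)
        win = win.reshape(n, oh, ow, c, s * s)
        idx = win.argmax(axis=-1)
        out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout):
        idx, x_shape = self._cache
        n, h, w, c = x_shape
        s = self.size
        oh, ow = h // s, w // s
        dwin = np.zeros((n, oh, ow, c, s * s), dtype=dout.dtype)
        np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dx[:, : oh * s, : ow * s, :] = (
            dwin.reshape(n, oh, ow, c, s, s)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, oh * s, ow * s, c)
        )
        return dx


class FlattenToSequence(Layer):
    """(N, H, W, C) -> (N, T=H, D=W*C): feature-map rows become a sequence."""

    name = "flatten-to-sequence"

    def forward(self, x, train=False):
        self._shape = x.shape
        n, h, w, c = x.shape
        return x.reshape(n, h, w * c)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator):
        super().__init__()
        self.name = f"dense-{out_features}"
        self.params["W"] = rng.normal(
            0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features)
        ).astype(np.float32)
        self.params["b"] = np.zeros(out_features, dtype=np.float32)

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout: active only in train mode; identity in eval."""

    def __init__(self, rate: float, *, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.name = f"dropout-{rate:g}"
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask
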