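"""Peephole LSTM: functional single step plus a sequence layer with BPTT.

Gate equations (sigma = logistic, all three gates read the *previous* cell
state through their peephole matrices):

    F_t = sigma(x_t W_xf + h_{t-1} W_hf + C_{t-1} W_cf + b_f)
    i_t = sigma(x_t W_xi + h_{t-1} W_hi + C_{t-1} W_ci + b_i)
    g_t = tanh (x_t W_xc + h_{t-1} W_hc + b_c)
    C_t = F_t * C_{t-1} + i_t * g_t
    o_t = sigma(x_t W_xo + h_{t-1} W_ho + C_{t-1} W_co + b_o)
    h_t = o_t * tanh(C_t)

Peepholes (the ``W_c*`` terms) can be disabled for parity with peephole-free
framework LSTMs.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .layers import Layer

__all__ = ["LSTMParams", "lstm_step", "LSTMLayer"]


def _sigmoid(z):
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LSTMParams:
    """Gate weights for input size D and hidden size H.

    ``W_x*`` are (D, H), ``W_h*`` and peephole ``W_c*`` are (H, H), biases
    are (H,).
    """

    W_xf: np.ndarray; W_hf: np.ndarray; W_cf: np.ndarray; b_f: np.ndarray
    W_xi: np.ndarray; W_hi: np.ndarray; W_ci: np.ndarray; b_i: np.ndarray
    W_xc: np.ndarray; W_hc: np.ndarray; b_c: np.ndarray
    W_xo: np.ndarray; W_ho: np.ndarray; W_co: np.ndarray; b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_hf.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_xf.shape[0]

    def __post_init__(self) -> None:
        d, h = self.W_xf.shape
        for f in fields(self):
            arr = getattr(self, f.name)
            if f.name.startswith("b_"):
                expected = (h,)
            elif f.name.startswith("W_x"):
                expected = (d, h)
            else:  # W_h* and peephole W_c*
                expected = (h, h)
            if arr.shape != expected:
                raise ValueError(
                    f"{f.name} has shape {arr.shape}, expected {expected}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{f.name} contains non-finite entries")

    @classmethod
    def init(cls, input_size: int, hidden_size: int, *,
             rng: np.random.Generator, peephole: bool = True) -> "LSTMParams":
        """Variance-scaled (fan-in) initialisation; forget bias starts at 1."""
        def wx():
            return rng.normal(0, np.sqrt(1.0 / input_size),
                              (input_size, hidden_size)).astype(np.float64)

        def wh():
            return rng.normal(0, np.sqrt(1.0 / hidden_size),
                              (hidden_size, hidden_size)).astype(np.float64)

        def wc():
            if not peephole:
                return np.zeros((hidden_size, hidden_size))
            return rng.normal(0, np.sqrt(1.0 / hidden_size),
                              (hidden_size, hidden_size)).astype(np.float64)

        z = np.zeros(hidden_size)
        return cls(
            W_xf=wx(), W_hf=wh(), W_cf=wc(), b_f=np.ones(hidden_size),
            W_xi=wx(), W_hi=wh(), W_ci=wc(), b_i=z.copy(),
            W_xc=wx(), W_hc=wh(), b_c=z.copy(),
            W_xo=wx(), W_ho=wh(), W_co=wc(), b_o=z.copy(),
        )


def lstm_step(
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    params: LSTMParams,
    *,
    peephole: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM time step; returns (h_t, c_t). Inputs may be batched (N, .)."""
    p = params
    if x_t.shape[-1] != p.input_size or h_prev.shape[-1] != p.hidden_size:
        raise ValueError(
            f"shape mismatch: x_t {x_t.shape}, h_prev {h_prev.shape} vs params "
            f"(D={p.input_size}, H={p.hidden_size})"
        )
    peep = (c_prev if peephole else 0.0)
    f_t = _sigmoid(x_t @ p.W_xf + h_prev @ p.W_hf + (peep @ p.W_cf if peephole else 0.0) + p.b_f)
    i_t = _sigmoid(x_t @ p.W_xi + h_prev @ p.W_hi + (peep @ p.W_ci if peephole else 0.0) + p.b_i)
    g_t = np.tanh(x_t @ p.W_xc + h_prev @ p.W_hc + p.b_c)
    c_t = f_t * c_prev + i_t * g_t
    o_t = _sigmoid(x_t @ p.W_xo + h_prev @ p.W_ho + (peep @ p.W_co if peephole else 0.0) + p.b_o)
    h_t = o_t * np.tanh(c_t)
    return h_t, c_t


class LSTMLayer(Layer):
    """Single LSTM over a feature sequence (N, T, D); emits the last hidden
    state (N, H). Backward is full backpropagation through time."""

    def __init__(self, input_size: int, hidden_size: int, *,
                 rng: np.random.Generator, peephole: bool = True):
        super().__init__()
        self.name = f"lstm-{hidden_size}"
        self.peephole = peephole
        self.hidden_size = hidden_size
        self.input_size = input_size
        p = LSTMParams.init(input_size, hidden_size, rng=rng, peephole=peephole)
        for f in fields(LSTMParams):
            self.params[f.name] = getattr(p, f.name)

    def _p(self) -> LSTMParams:
        return LSTMParams(**self.params)

    def forward(self, x, train=False):
        n, T, d = x.shape
        H = self.hidden_size
        p = self._p()
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        for t in range(T):
            x_t = x[:, t, :]
            c_prev = c
            h_prev = h
            peep = c_prev if self.peephole else None
            f_t = _sigmoid(x_t @ p.W_xf + h_prev @ p.W_hf
                           + (c_prev @ p.W_cf if self.peephole else 0.0) + p.b_f)
            i_t = _sigmoid(x_t @ p.W_xi + h_prev @ p.W_hi
                           + (c_prev @ p.W_ci if self.peephole else 0.0) + p.b_i)
            g_t = np.tanh(x_t @ p.W_xc + h_prev @ p.W_hc + p.b_c)
            c = f_t * c_prev + i_t * g_t
            o_t = _sigmoid(x_t @ p.W_xo + h_prev @ p.W_ho
                           + (c_prev @ p.W_co if self.peephole else 0.0) + p.b_o)
            h = o_t * np.tanh(c)
            if train:
                cache.append((x_t, h_prev, c_prev, f_t, i_t, g_t, o_t, c))
        if train:
            self._cache = (cache, x.shape)
        return h

    def backward(self, dout):
        cache, x_shape = self._cache
        n, T, d = x_shape
        p = self._p()
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])
        dx = np.zeros(x_shape)
        dh = dout.astype(np.float64)
        dc = np.zeros_like(dh)
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, f_t, i_t, g_t, o_t, c_t = cache[t]
            tanh_c = np.tanh(c_t)
            do = dh * tanh_c
            dc = dc + dh * o_t * (1.0 - tanh_c**2)
            dzo = do * o_t * (1.0 - o_t)
            df = dc * c_prev
            di = dc * g_t
            dg = dc * i_t
            dzf = df * f_t * (1.0 - f_t)
            dzi = di * i_t * (1.0 - i_t)
            dzg = dg * (1.0 - g_t**2)

            self.grads["W_xf"] += x_t.T @ dzf
            self.grads["W_hf"] += h_prev.T @ dzf
            self.grads["b_f"] += dzf.sum(axis=0)
            self.grads["W_xi"] += x_t.T @ dzi
            self.grads["W_hi"] += h_prev.T @ dzi
            self.grads["b_i"] += dzi.sum(axis=0)
            self.grads["W_xc"] += x_t.T @ dzg
            self.grads["W_hc"] += h_prev.T @ dzg
            self.grads["b_c"] += dzg.sum(axis=0)
            self.grads["W_xo"] += x_t.T @ dzo
            self.grads["W_ho"] += h_prev.T @ dzo
            self.grads["b_o"] += dzo.sum(axis=0)

            dx[:, t, :] = dzf @ p.W_xf.T + dzi @ p.W_xi.T + dzg @ p.W_xc.T + dzo @ p.W_xo.T
            dh = dzf @ p.W_hf.T + dzi @ p.W_hi.T + dzg @ p.W_hc.T + dzo @ p.W_ho.T
            dc_prev = dc * f_t
            if self.peephole:
                self.grads["W_cf"] += c_prev.T @ dzf
                self.grads["W_ci"] += c_prev.T @ dzi
                self.grads["W_co"] += c_prev.T @ dzo
                dc_prev = dc_prev + dzf @ p.W_cf.T + dzi @ p.W_ci.T + dzo @ p.W_co.T
            dc = dc_prev
        return dx
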