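"""Minimal numpy building blocks for 1-D sequence classification.

Implements exactly the layer types the sleep-stage classifier needs — 1-D
valid convolution, ReLU, max-pooling, (bidirectional) LSTM and a dense
softmax head — with hand-written backward passes and an Adam optimizer.
Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, time, features) for recurrent ones.  Everything is plain
float64 numpy; the layers are deliberately small-scale and favour clarity
over throughput.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: parameterized layers expose ``params``/``grads`` dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Valid 1-D convolution, stride 1.  x: (B, C_in, L) -> (B, C_out, L-K+1)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.params = {
            "W": scale * rng.standard_normal((c_out, c_in, kernel)),
            "b": np.zeros(c_out),
        }
        self.kernel = kernel

    def forward(self, x):
        self._x = x
        win = sliding_window_view(x, self.kernel, axis=2)  # (B, C_in, L', K)
        return np.einsum("bclk,ock->bol", win, self.params["W"]) + self.params["b"][:, None]

    def backward(self, dy):
        x, k = self._x, self.kernel
        win = sliding_window_view(x, k, axis=2)
        self.grads["W"] = np.einsum("bclk,bol->ock", win, dy)
        self.grads["b"] = dy.sum(axis=(0, 2))
        dy_pad = np.pad(dy, ((0, 0), (0, 0), (k - 1, k - 1)))
        win_dy = sliding_window_view(dy_pad, k, axis=2)  # (B, C_out, L, K)
        w_flip = self.params["W"][:, :, ::-1]
        return np.einsum("bolk,ock->bcl", win_dy, w_flip)


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (trailing remainder
    is dropped, as in 'valid' pooling)."""

    def __init__(self, pool: int):
        super().__init__()
        self.pool = pool

    def forward(self, x):
        b, c, length = x.shape
        n = length // self.pool
        self._in_len = length
        xr = x[:, :, : n * self.pool].reshape(b, c, n, self.pool)
        self._argmax = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, dy):
        b, c, n = dy.shape
        dxr = np.zeros((b, c, n, self.pool))
        bi, ci, ni = np.ogrid[:b, :c, :n]
        dxr[bi, ci, ni, self._argmax] = dy
        dx = np.zeros((b, c, self._in_len))
        dx[:, :, : n * self.pool] = dxr.reshape(b, c, n * self.pool)
        return dx


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class _LSTMDirection(Layer):
    """Single-direction LSTM returning the full hidden sequence.

    x: (B, T, F) -> (B, T, H).  Gate order in the fused weight matrices is
    input, forget, cell, output.
    """

    def __init__(self, f_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        sx = np.sqrt(1.0 / f_in)
        sh = np.sqrt(1.0 / hidden)
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        self.params = {
            "Wx": sx * rng.standard_normal((f_in, 4 * hidden)),
            "Wh": sh * rng.standard_normal((hidden, 4 * hidden)),
            "b": b,
        }
        self.hidden = hidden

    def forward(self, x):
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H))
        for t in range(T):
            z = x[:, t] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t] = h
        return hs

    def backward(self, dhs):
        x = self._x
        B, T, F = x.shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.empty_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            dh = dhs[:, t] + dh_next
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class BiLSTM(Layer):
    """Bidirectional LSTM.  x: (B, T, F) -> (B, T, 2H) when returning
    sequences, otherwise the concatenated final states (B, 2H)."""

    def __init__(self, f_in: int, hidden: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        super().__init__()
        self.fw = _LSTMDirection(f_in, hidden, rng)
        self.bw = _LSTMDirection(f_in, hidden, rng)
        self.return_sequences = return_sequences
        self.hidden = hidden

    @property
    def params(self):
        return {f"fw_{k}": v for k, v in self.fw.params.items()} | {
            f"bw_{k}": v for k, v in self.bw.params.items()
        }

    @params.setter
    def params(self, value):  # base-class __init__ assigns {}; sub-layers own storage
        pass

    @property
    def grads(self):
        return {f"fw_{k}": v for k, v in self.fw.grads.items()} | {
            f"bw_{k}": v for k, v in self.bw.grads.items()
        }

    @grads.setter
    def grads(self, value):
        pass

    def forward(self, x):
        self._T = x.shape[1]
        hs_fw = self.fw.forward(x)
        hs_bw = self.bw.forward(x[:, ::-1])
        if self.return_sequences:
            return np.concatenate([hs_fw, hs_bw[:, ::-1]], axis=2)
        return np.concatenate([hs_fw[:, -1], hs_bw[:, -1]], axis=1)

    def backward(self, dy):
        H = self.hidden
        if self.return_sequences:
            d_fw = dy[:, :, :H]
            d_bw = dy[:, ::-1, H:]
        else:
            B = dy.shape[0]
            d_fw = np.zeros((B, self._T, H))
            d_bw = np.zeros((B, self._T, H))
            d_fw[:, -1] = dy[:, :H]
            d_bw[:, -1] = dy[:, H:]
        dx_fw = self.fw.backward(d_fw)
        dx_bw = self.bw.backward(d_bw)
        return dx_fw + dx_bw[:, ::-1]


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": np.sqrt(2.0 / f_in) * rng.standard_normal((f_in, f_out)),
            "b": np.zeros(f_out),
        }

    def forward(self, x):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(p[np.arange(n), labels] + 1e-12).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


class Adam:
    """Adam optimizer over the parameter dicts of a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for l, m, v in zip(self.layers, self.m, self.v):
            grads = l.grads
            for k, p in l.params.items():
                g = grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                mhat = m[k] / (1 - b1**self.t)
                vhat = v[k] / (1 - b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
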