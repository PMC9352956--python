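"""Minimal neural-network primitives on numpy arrays.

Each layer implements ``forward`` and ``backward`` with explicit caches,
which keeps the whole classifier runnable and exactly reproducible on a
single CPU.  Shapes follow the torch convention ``(batch, channel, H, W)``
for images and ``(batch, time, features)`` for sequences.  Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numba
import numpy as np

try:  # multithreaded BLAS thrashes the skinny GEMMs this network is made of
    from threadpoolctl import threadpool_limits as _threadpool_limits

    def single_thread_blas():
        return _threadpool_limits(limits=1, user_api="blas")
except Exception:  # pragma: no cover - threadpoolctl ships with scikit-learn
    from contextlib import nullcontext as single_thread_blas

__all__ = [
    "single_thread_blas",
    "Conv2dSame",
    "MaxPool2d",
    "ReLU",
    "Linear",
    "LSTM",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dz).

    Uses the log-sum-exp form so large |z| cannot overflow.
    """
    z = z.ravel()
    y = y.ravel().astype(z.dtype)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    dz = (sigmoid(z) - y) / z.size
    return float(loss.mean()), dz


@numba.njit(cache=True, fastmath=True)
def _conv_fwd(xp, weight, bias):
    """'Same' correlation of a padded NHWC array with (k, k, Ci, Co)."""
    b, hp, wp, ci = xp.shape
    k, co = weight.shape[0], weight.shape[3]
    h, w = hp - k + 1, wp - k + 1
    out = np.empty((b, h, w, co), dtype=xp.dtype)
    acc = np.empty(co, dtype=xp.dtype)
    for n in range(b):
        for y in range(h):
            for x in range(w):
                for o in range(co):
                    acc[o] = bias[o]
                for i in range(k):
                    for j in range(k):
                        for c in range(ci):
                            v = xp[n, y + i, x + j, c]
                            if v != 0.0:
                                for o in range(co):
                                    acc[o] += v * weight[i, j, c, o]
                out[n, y, x] = acc
    return out


@numba.njit(cache=True, fastmath=True)
def _conv_bwd_w(xp, dout, k):
    """Weight/bias gradients of the padded 'same' correlation."""
    b, hp, wp, ci = xp.shape
    h, w, co = dout.shape[1], dout.shape[2], dout.shape[3]
    dW = np.zeros((k, k, ci, co), dtype=xp.dtype)
    db = np.zeros(co, dtype=xp.dtype)
    for n in range(b):
        for y in range(h):
            for x in range(w):
                g = dout[n, y, x]
                for o in range(co):
                    db[o] += g[o]
                for i in range(k):
                    for j in range(k):
                        for c in range(ci):
                            v = xp[n, y + i, x + j, c]
                            if v != 0.0:
                                for o in range(co):
                                    dW[i, j, c, o] += v * g[o]
    return dW, db


@numba.njit(cache=True, fastmath=True)
def _conv_bwd_dx(dout, weight):
    """Adjoint of the padded 'same' correlation: scatter dout back through
    the kernel; (B, H, W, Co) x (k, k, Ci, Co) -> (B, H+2p, W+2p, Ci)."""
    b, h, w, co = dout.shape
    k, ci = weight.shape[0], weight.shape[2]
    dxp = np.zeros((b, h + k - 1, w + k - 1, ci), dtype=dout.dtype)
    for n in range(b):
        for y in range(h):
            for x in range(w):
                for i in range(k):
                    for j in range(k):
                        for c in range(ci):
                            s = dout.dtype.type(0)
                            for o in range(co):
                                s += dout[n, y, x, o] * weight[i, j, c, o]
                            dxp[n, y + i, x + j, c] += s
    return dxp


@numba.njit(cache=True)
def _pool_fwd(x, s):
    b, h, w, c = x.shape
    hh, ww = h // s, w // s
    out = np.empty((b, hh, ww, c), dtype=x.dtype)
    arg = np.empty((b, hh, ww, c), dtype=np.uint8)
    for n in range(b):
        for y in range(hh):
            for x0 in range(ww):
                for ch in range(c):
                    best = x[n, y * s, x0 * s, ch]
                    bi = 0
                    for i in range(s):
                        for j in range(s):
                            v = x[n, y * s + i, x0 * s + j, ch]
                            if v > best:
                                best = v
                                bi = i * s + j
                    out[n, y, x0, ch] = best
                    arg[n, y, x0, ch] = bi
    return out, arg


@numba.njit(cache=True)
def _pool_bwd(dout, arg, s):
    b, hh, ww, c = dout.shape
    dx = np.zeros((b, hh * s, ww * s, c), dtype=dout.dtype)
    for n in range(b):
        for y in range(hh):
            for x0 in range(ww):
                for ch in range(c):
                    bi = arg[n, y, x0, ch]
                    dx[n, y * s + bi // s, x0 * s + bi % s, ch] = \
                        dout[n, y, x0, ch]
    return dx


class Conv2dSame:
    """k x k convolution, stride 1, zero 'same' padding (odd k), NHWC.

    Direct jitted kernels (no patch matrix): on one CPU this keeps a
    training step in seconds, avoids hundreds of MB of im2col
    intermediates, and exploits the sparsity of binarized motion images
    in the first layer.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dtype=np.float32, need_dx: bool = True):
        if k % 2 != 1:
            raise ValueError("kernel size must be odd for 'same' padding")
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init for ReLU stacks
        self.W = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.pad = k, (k - 1) // 2
        self.need_dx = need_dx  # False for the input layer: skip dead work
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._cache = xp
        return _conv_fwd(xp, self.W, self.b)

    def backward(self, dout: np.ndarray):
        xp = self._cache
        dout = np.ascontiguousarray(dout)
        dW, db = _conv_bwd_w(xp, dout, self.k)
        if not self.need_dx:
            return None, {"W": dW, "b": db}
        p = self.pad
        h, w = dout.shape[1], dout.shape[2]
        dxp = _conv_bwd_dx(dout, self.W)
        return np.ascontiguousarray(dxp[:, p:p + h, p:p + w, :]), \
            {"W": dW, "b": db}


class MaxPool2d:
    """s x s max pooling, stride s, NHWC; gradient goes to the first
    maximal element of each window."""

    def __init__(self, size: int = 2):
        self.size = size
        self._arg = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        if h % self.size or w % self.size:
            raise ValueError(
                f"spatial dims {(h, w)} not divisible by pool {self.size}")
        out, self._arg = _pool_fwd(np.ascontiguousarray(x), self.size)
        return out

    def backward(self, dout: np.ndarray):
        return _pool_bwd(np.ascontiguousarray(dout), self._arg, self.size), {}


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray):
        return dout * self._mask, {}


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32, relu_gain: bool = True):
        scale = np.sqrt((2.0 if relu_gain else 1.0) / d_in)
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray):
        dW = self._x.T @ dout
        db = dout.sum(axis=0)
        return dout @ self.W.T, {"W": dW, "b": db}


class LSTM:
    """Single-layer LSTM over (batch, time, features); returns all hidden states.

    Gate order in the packed weight matrices is input, forget, cell, output.
    The forget-gate bias starts at 1 so early gradients flow through time.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator,
                 dtype=np.float32):
        sx = np.sqrt(1.0 / d_in)
        sh = np.sqrt(1.0 / units)
        self.Wx = (rng.standard_normal((d_in, 4 * units)) * sx).astype(dtype)
        self.Wh = (rng.standard_normal((units, 4 * units)) * sh).astype(dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units:2 * units] = 1.0
        self.units = units
        self._cache = None

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        h = np.zeros((b, u), dtype=x.dtype)
        c = np.zeros((b, u), dtype=x.dtype)
        hs = np.empty((b, t, u), dtype=x.dtype)
        steps = []
        for k in range(t):
            z = x[:, k] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            hs[:, k] = h
            steps.append((x[:, k], h_prev, c_prev, i, f, g, o, tc))
        self._cache = steps
        return hs

    def backward(self, dhs: np.ndarray):
        steps = self._cache
        b, t, u = dhs.shape
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty((b, t, self.Wx.shape[0]), dtype=dhs.dtype)
        dh_next = np.zeros((b, u), dtype=dhs.dtype)
        dc_next = np.zeros((b, u), dtype=dhs.dtype)
        for k in reversed(range(t)):
            xk, h_prev, c_prev, i, f, g, o, tc = steps[k]
            dh = dhs[:, k] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dWx += xk.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, k] = dz @ self.Wx.T
            dh_next = dz @ self.Wh.T
            dc_next = dc * f
        self._cache = None
        return dx, {"Wx": dWx, "Wh": dWh, "b": db}


class Adam:
    """Adam over a flat ``name -> array`` parameter dict (in-place updates)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * (g * g)
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
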