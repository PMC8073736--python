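"""Differentiable layers for the small feed-forward / recurrent engine.

All layers operate on float64 numpy arrays with the batch axis first and use
channels-last image layout (N, H, W, C). Convolutions have stride 1 and
'same' or 'valid' padding; pooling is non-overlapping 'valid'. Every layer
implements ``forward(x, training)`` and ``backward(dy)``; parameters and
their gradients are exposed as parallel lists for the optimizer. Gradients
of every layer are validated against central differences in the test suite.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, shape: Tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


# ---------------------------------------------------------------------------
# stride-1 conv primitives shared by Conv2D and ConvLSTM2D

def _pad_same(x: np.ndarray, kh: int, kw: int):
    pt, pl = (kh - 1) // 2, (kw - 1) // 2
    pb, pr = kh - 1 - pt, kw - 1 - pl
    return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))


def conv2d_forward(x: np.ndarray, w: np.ndarray, b: Optional[np.ndarray],
                   padding: str) -> Tuple[np.ndarray, np.ndarray]:
    """Stride-1 2-D convolution. x:(N,H,W,C), w:(kh,kw,C,F) → (y, padded x)."""
    kh, kw = w.shape[:2]
    xp = _pad_same(x, kh, kw) if padding == "same" else x
    ho, wo = xp.shape[1] - kh + 1, xp.shape[2] - kw + 1
    y = np.zeros((x.shape[0], ho, wo, w.shape[3]))
    for i in range(kh):
        for j in range(kw):
            y += np.tensordot(xp[:, i:i + ho, j:j + wo, :], w[i, j], axes=([3], [0]))
    if b is not None:
        y += b
    return y, xp


def conv2d_backward(dy: np.ndarray, xp: np.ndarray, w: np.ndarray,
                    x_shape: Tuple[int, ...], padding: str):
    """Gradients of conv2d_forward w.r.t. input, weights and bias."""
    kh, kw = w.shape[:2]
    ho, wo = dy.shape[1], dy.shape[2]
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i:i + ho, j:j + wo, :]
            dw[i, j] = np.tensordot(patch, dy, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, i:i + ho, j:j + wo, :] += np.tensordot(dy, w[i, j], axes=([3], [1]))
    db = dy.sum(axis=(0, 1, 2))
    if padding == "same":
        pt, pl = (kh - 1) // 2, (kw - 1) // 2
        dx = dxp[:, pt:pt + x_shape[1], pl:pl + x_shape[2], :]
    else:
        dx = dxp
    return dx, dw, db


# ---------------------------------------------------------------------------


class Layer:
    """Base layer: stateless by default."""

    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Stride-1 2-D convolution, channels last."""

    def __init__(self, in_channels: int, filters: int, kernel: Tuple[int, int],
                 padding: str = "same", rng: Optional[np.random.Generator] = None):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        fan_in, fan_out = kh * kw * in_channels, kh * kw * filters
        self.w = _glorot(rng, (kh, kw, in_channels, filters), fan_in, fan_out)
        self.b = np.zeros(filters)
        self.padding = padding
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x_shape = x.shape
        y, self._xp = conv2d_forward(x, self.w, self.b, self.padding)
        return y

    def backward(self, dy):
        dx, dw, db = conv2d_backward(dy, self._xp, self.w, self._x_shape, self.padding)
        self.grads[0][...] = dw
        self.grads[1][...] = db
        return dx


class BatchNorm(Layer):
    """Per-feature batch normalization (over batch and any spatial axes).

    Training uses mini-batch statistics and updates exponential running
    statistics (momentum 0.9) used at inference.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._axes = axes
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        axes = self._axes
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        if not self._training:
            return dy * self.gamma / self._std
        m = np.prod([dy.shape[a] for a in axes])
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes)
              - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2D(Layer):
    """Non-overlapping average pooling; trailing rows/cols are cropped."""

    def __init__(self, pool: Tuple[int, int]):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        ph, pw = self.pool
        n, h, w, c = x.shape
        ho, wo = h // ph, w // pw
        if ho < 1 or wo < 1:
            raise ValueError(f"input {x.shape} too small for pool {self.pool}")
        self._x_shape = x.shape
        return (x[:, :ho * ph, :wo * pw, :]
                .reshape(n, ho, ph, wo, pw, c).mean(axis=(2, 4)))

    def backward(self, dy):
        ph, pw = self.pool
        n, ho, wo, c = dy.shape
        dx = np.zeros(self._x_shape)
        spread = np.repeat(np.repeat(dy, ph, axis=1), pw, axis=2) / (ph * pw)
        dx[:, :ho * ph, :wo * pw, :] = spread
        return dx


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, units: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.w = _glorot(rng, (in_features, units), in_features, units)
        self.b = np.zeros(units)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


class Softmax(Layer):
    """Final probability layer. During training the network pairs the
    pre-softmax logits directly with the cross-entropy loss, so this layer's
    backward is only exercised by generic probability-gradient paths."""

    def forward(self, x, training=False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        self._p = e / e.sum(axis=-1, keepdims=True)
        return self._p

    def backward(self, dy):
        p = self._p
        return p * (dy - (dy * p).sum(axis=-1, keepdims=True))


class LSTM(Layer):
    """Single recurrent layer over (N, T, F) input, returning the last
    hidden state (N, units). Gate order i, f, g, o; forget bias +1."""

    def __init__(self, in_features: int, units: int,
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        u = units
        self.wx = _glorot(rng, (in_features, 4 * u), in_features, 4 * u)
        self.wh = _glorot(rng, (u, 4 * u), u, 4 * u)
        self.b = np.zeros(4 * u)
        self.b[u:2 * u] = 1.0  # forget-gate bias
        self.units = u
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        for step in range(t):
            z = x[:, step] @ self.wx + h @ self.wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        return h

    def backward(self, dy):
        x = self._x
        n, t, fdim = x.shape
        u = self.units
        dwx, dwh, db = (np.zeros_like(self.wx), np.zeros_like(self.wh),
                        np.zeros_like(self.b))
        dx = np.zeros_like(x)
        dh, dc = dy.copy(), np.zeros((n, u))
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            do = dh * tc
            dc = dc + dh * o * (1 - tc ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * f * (1 - f),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=1)
            dwx += x[:, step].T @ dz
            dwh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.T
            dh = dz @ self.wh.T
            dc = dc * f
        self.grads[0][...] = dwx
        self.grads[1][...] = dwh
        self.grads[2][...] = db
        return dx


class ConvLSTM2D(Layer):
    """Convolutional LSTM over (N, T, H, W, C) input.

    Input-to-state and state-to-state transitions are stride-1 'same'
    convolutions; the full hidden-state sequence (N, T, H, W, filters) is
    returned.
    """

    def __init__(self, in_channels: int, filters: int, kernel: Tuple[int, int],
                 rng: Optional[np.random.Generator] = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = kernel
        self.wx = _glorot(rng, (kh, kw, in_channels, 4 * filters),
                          kh * kw * in_channels, kh * kw * 4 * filters)
        self.wh = _glorot(rng, (kh, kw, filters, 4 * filters),
                          kh * kw * filters, kh * kw * 4 * filters)
        self.b = np.zeros(4 * filters)
        self.b[filters:2 * filters] = 1.0
        self.filters = filters
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, training=False):
        n, t, hh, ww, _ = x.shape
        f = self.filters
        h = np.zeros((n, hh, ww, f))
        c = np.zeros((n, hh, ww, f))
        self._x = x
        self._cache = []
        out = np.zeros((n, t, hh, ww, f))
        for step in range(t):
            zx, xp = conv2d_forward(x[:, step], self.wx, self.b, "same")
            zh, hp = conv2d_forward(h, self.wh, None, "same")
            z = zx + zh
            i = _sigmoid(z[..., :f])
            fg = _sigmoid(z[..., f:2 * f])
            g = np.tanh(z[..., 2 * f:3 * f])
            o = _sigmoid(z[..., 3 * f:])
            c_new = fg * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((xp, hp, h, c, i, fg, g, o, tc))
            out[:, step] = h_new
            h, c = h_new, c_new
        return out

    def backward(self, dy):
        x = self._x
        n, t, hh, ww, cin = x.shape
        f = self.filters
        dwx = np.zeros_like(self.wx)
        dwh = np.zeros_like(self.wh)
        db = np.zeros_like(self.b)
        dx = np.zeros_like(x)
        dh = np.zeros((n, hh, ww, f))
        dc = np.zeros((n, hh, ww, f))
        for step in range(t - 1, -1, -1):
            xp, hp, h_prev, c_prev, i, fg, g, o, tc = self._cache[step]
            dh_t = dh + dy[:, step]
            do = dh_t * tc
            dc = dc + dh_t * o * (1 - tc ** 2)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate([
                di * i * (1 - i),
                df * fg * (1 - fg),
                dg * (1 - g ** 2),
                do * o * (1 - o),
            ], axis=-1)
            dx_t, dwx_t, db_t = conv2d_backward(
                dz, xp, self.wx, x[:, step].shape, "same")
            dh, dwh_t, _ = conv2d_backward(
                dz, hp, self.wh, h_prev.shape, "same")
            dwx += dwx_t
            dwh += dwh_t
            db += db_t
            dx[:, step] = dx_t
            dc = dc * fg
        self.grads[0][...] = dwx
        self.grads[1][...] = dwh
        self.grads[2][...] = db
        return dx
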