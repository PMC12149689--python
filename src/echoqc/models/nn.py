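"""Minimal numpy neural-network primitives with explicit backward passes.

Deliberately small: 3x3/1x1 convolutions via im2col, ReLU, 2x2 max-pool,
linear layers, a bidirectional Elman recurrent stack, and Adam.  Everything
is float64-free (float32) and seeded, so training traces are reproducible
bit-for-bit on one thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Conv2d", "ReLU", "MaxPool2", "Linear", "BiRNN", "Adam",
           "softmax", "sigmoid", "softmax_ce", "bce_logits", "mse_masked"]


class Param:
    """A weight tensor plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def im2col(x: np.ndarray, k: int, pad: int, dilation: int = 1) -> np.ndarray:
    """(N,C,H,W) -> (N, H*W, C*k*k) patches for stride-1 kxk convolution."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    span = (k - 1) * dilation + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (span, span), axis=(2, 3))
    if dilation > 1:
        windows = windows[..., ::dilation, ::dilation]
    return windows.reshape(n, c, h, w, k * k).transpose(0, 2, 3, 1, 4).reshape(n, h * w, c * k * k)


def col2im(cols: np.ndarray, x_shape, k: int, pad: int, dilation: int = 1) -> np.ndarray:
    """Adjoint of :func:`im2col` (scatter-add patches back)."""
    n, c, h, w = x_shape
    out = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    cols = cols.reshape(n, h, w, c, k, k)
    for di in range(k):
        for dj in range(k):
            oi, oj = di * dilation, dj * dilation
            out[:, :, oi : oi + h, oj : oj + w] += cols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv2d:
    """Stride-1 same-padding convolution (k in {1, 3}), optionally dilated."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1):
        self.k, self.dilation = k, dilation
        self.pad = (k // 2) * dilation
        self.w = Param(_kaiming(rng, (c_out, c_in * k * k), c_in * k * k))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = im2col(x, self.k, self.pad, self.dilation)  # (N, HW, C k k)
        out = cols @ self.w.value.T + self.b.value  # (N, HW, c_out)
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, co, h, w = dout.shape
        dflat = dout.reshape(n, co, h * w).transpose(0, 2, 1)  # (N, HW, co)
        self.w.grad += np.einsum("npo,npk->ok", dflat, cols, optimize=True)
        self.b.grad += dflat.sum(axis=(0, 1))
        dcols = dflat @ self.w.value  # (N, HW, Ckk)
        return col2im(dcols, x_shape, self.k, self.pad, self.dilation)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2:
    """2x2 max pooling, stride 2 (even spatial dims assumed)."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._cache = (x.shape, xr, out)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_shape, xr, out = self._cache
        # ties (rare with float inputs) route gradient to every argmax
        mask = xr == out[:, :, :, None, :, None]
        dx = mask * dout[:, :, :, None, :, None]
        return dx.reshape(x_shape)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Param(_kaiming(rng, (d_out, d_in), d_in))
        self.b = Param(np.zeros(d_out, dtype=np.float32))
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.w.grad += d2.T @ x2
        self.b.grad += d2.sum(axis=0)
        return dout @ self.w.value


class _RNNCellDirection:
    """One Elman (tanh) recurrence over a (T, D) sequence, one direction."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, reverse: bool):
        self.wx = Param(_kaiming(rng, (hidden, d_in), d_in))
        self.wh = Param(
            rng.normal(0.0, 1.0 / np.sqrt(hidden), size=(hidden, hidden)).astype(np.float32)
        )
        self.b = Param(np.zeros(hidden, dtype=np.float32))
        self.reverse = reverse
        self._cache = None

    def params(self):
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        seq = x[::-1] if self.reverse else x
        T = seq.shape[0]
        hidden = self.b.value.shape[0]
        hs = np.zeros((T + 1, hidden), dtype=np.float32)
        for t in range(T):
            hs[t + 1] = np.tanh(
                seq[t] @ self.wx.value.T + hs[t] @ self.wh.value.T + self.b.value
            )
        self._cache = (seq, hs)
        out = hs[1:]
        return out[::-1] if self.reverse else out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        seq, hs = self._cache
        dseq = dout[::-1] if self.reverse else dout
        T = seq.shape[0]
        dx = np.zeros_like(seq)
        dh_next = np.zeros(self.b.value.shape[0], dtype=np.float32)
        for t in range(T - 1, -1, -1):
            dh = dseq[t] + dh_next
            dz = dh * (1.0 - hs[t + 1] ** 2)
            self.wx.grad += np.outer(dz, seq[t])
            self.wh.grad += np.outer(dz, hs[t])
            self.b.grad += dz
            dx[t] = dz @ self.wx.value
            dh_next = dz @ self.wh.value
        return dx[::-1] if self.reverse else dx


class BiRNN:
    """Stacked bidirectional Elman recurrence: (T, D) -> (T, 2*hidden)."""

    def __init__(self, d_in: int, hidden: int, n_layers: int, rng: np.random.Generator):
        self.layers: list[tuple[_RNNCellDirection, _RNNCellDirection]] = []
        d = d_in
        for _ in range(n_layers):
            fwd = _RNNCellDirection(d, hidden, rng, reverse=False)
            bwd = _RNNCellDirection(d, hidden, rng, reverse=True)
            self.layers.append((fwd, bwd))
            d = 2 * hidden

    def params(self):
        out = []
        for fwd, bwd in self.layers:
            out.extend(fwd.params())
            out.extend(bwd.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x.astype(np.float32)
        for fwd, bwd in self.layers:
            h = np.concatenate([fwd.forward(h), bwd.forward(h)], axis=1)
        return h

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = dout
        for fwd, bwd in reversed(self.layers):
            hidden = fwd.b.value.shape[0]
            d = fwd.backward(d[:, :hidden]) + bwd.backward(d[:, hidden:])
        return d


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_ce(logits: np.ndarray, targets: np.ndarray, weights: np.ndarray | None = None):
    """Cross-entropy over the last axis; ``targets`` holds class indices.

    Returns (loss, dlogits).  ``weights`` optionally reweights each sample.
    """
    p = softmax(logits)
    flat_p = p.reshape(-1, p.shape[-1])
    flat_t = targets.reshape(-1)
    n = flat_t.shape[0]
    w = np.ones(n, dtype=np.float32) if weights is None else weights.reshape(-1)
    wsum = w.sum()
    picked = flat_p[np.arange(n), flat_t]
    loss = float(-(w * np.log(picked + 1e-12)).sum() / wsum)
    dflat = flat_p.copy()
    dflat[np.arange(n), flat_t] -= 1.0
    dflat *= (w / wsum)[:, None]
    return loss, dflat.reshape(logits.shape)


def sigmoid(z: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    return expit(z)


def bce_logits(logits: np.ndarray, targets: np.ndarray, mask: np.ndarray | None = None):
    """Element-wise binary cross-entropy with logits; returns (loss, dlogits)."""
    p = sigmoid(logits)
    if mask is None:
        mask = np.ones_like(logits)
    denom = float(mask.sum()) + 1e-12
    loss = float(
        (-(targets * np.log(p + 1e-12) + (1 - targets) * np.log(1 - p + 1e-12)) * mask).sum()
        / denom
    )
    dlogits = (p - targets) * mask / denom
    return loss, dlogits.astype(np.float32)


def mse_masked(pred: np.ndarray, target: np.ndarray, mask: np.ndarray):
    m = mask.astype(np.float32)
    denom = float(m.sum()) + 1e-12
    diff = (pred - target) * m
    loss = float((diff**2).sum() / denom)
    return loss, (2.0 * diff / denom).astype(np.float32)
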