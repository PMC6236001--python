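"""Vectorized trainable layers (numpy, NCHW layout).

Forward passes take a ``mode`` ("train" | "inference") and an optional rng;
``backward`` consumes the upstream gradient and fills per-parameter
gradients in ``layer.grads``.  Convolution is implemented with im2col over
sliding windows; pooling gathers (k*k)-windows per output position and
keeps a validity mask so zero-padded positions are excluded from average
denominators and from stochastic-pooling probabilities.

Stochastic pooling samples one location per region at train time (gradient
routed to the sampled location, as in max pooling) and uses the
probability-weighted expectation sum_i chi_i^2 / sum_i chi_i at inference,
which is deterministic.
"""

from __future__ import annotations

from math import ceil
from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import errors
from .nn_ops import same_pad_amounts


def _pad_nchw(x: np.ndarray, pads: tuple[int, int, int, int], value: float = 0.0) -> np.ndarray:
    pt, pb, pl, pr = pads
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)), constant_values=value)


def _windows(xp: np.ndarray, k: int, stride: int, out_h: int, out_w: int) -> np.ndarray:
    """(N, C, out_h, out_w, k, k) strided view of padded NCHW input."""
    sw = sliding_window_view(xp, (k, k), axis=(2, 3))
    return sw[:, :, : (out_h - 1) * stride + 1 : stride, : (out_w - 1) * stride + 1 : stride]


class Layer:
    """Base layer: no parameters, identity shape bookkeeping."""

    def params(self) -> Iterator[tuple[np.ndarray, np.ndarray]]:
        yield from ()

    def forward(self, x: np.ndarray, mode: str, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """3x3-style strided convolution with 'same' zero padding, He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}
        self.in_ch, self.out_ch, self.kernel, self.stride = in_ch, out_ch, kernel, stride

    def params(self):
        yield self.W, self.grads["W"]
        yield self.b, self.grads["b"]

    def forward(self, x, mode, rng=None):
        if x.shape[1] != self.in_ch:
            raise errors.ChannelMismatch(
                f"expected {self.in_ch} input channels, got {x.shape[1]}"
            )
        n, _, h, w = x.shape
        k, s = self.kernel, self.stride
        out_h, out_w = ceil(h / s), ceil(w / s)
        pads = (*same_pad_amounts(h, k, s), *same_pad_amounts(w, k, s))
        xp = _pad_nchw(x, pads)
        win = _windows(xp, k, s, out_h, out_w)            # N,C,oh,ow,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * out_h * out_w, -1)
        out = cols @ self.W.reshape(self.out_ch, -1).T + self.b
        self._cache = (cols, x.shape, pads, (out_h, out_w))
        return out.reshape(n, out_h, out_w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, x_shape, pads, (out_h, out_w) = self._cache
        n, c, h, w = x_shape
        k, s = self.kernel, self.stride
        g = grad.transpose(0, 2, 3, 1).reshape(-1, self.out_ch)  # N*oh*ow, Z
        self.grads["W"][...] = (g.T @ cols).reshape(self.W.shape)
        self.grads["b"][...] = g.sum(axis=0)
        dcols = (g @ self.W.reshape(self.out_ch, -1)).reshape(n, out_h, out_w, c, k, k)
        pt, pb, pl, pr = pads
        dxp = np.zeros((n, c, h + pt + pb, w + pl + pr))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + (out_h - 1) * s + 1 : s, j : j + (out_w - 1) * s + 1 : s] += (
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        return dxp[:, :, pt : pt + h, pl : pl + w]


class BatchNorm2D(Layer):
    """Per-channel batch normalization over (N, H, W) with running moments."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.eps, self.momentum = eps, momentum
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.grads = {"gamma": np.zeros_like(self.gamma), "beta": np.zeros_like(self.beta)}

    def params(self):
        yield self.gamma, self.grads["gamma"]
        yield self.beta, self.grads["beta"]

    def forward(self, x, mode, rng=None):
        axes = (0, 2, 3)
        if mode == "train":
            if x.shape[0] < 2:
                raise errors.BatchTooSmall("train-mode batch norm needs batch size >= 2")
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        self._cache = (xhat, inv_std, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, grad):
        xhat, inv_std, m = self._cache
        axes = (0, 2, 3)
        self.grads["gamma"][...] = (grad * xhat).sum(axis=axes)
        self.grads["beta"][...] = grad.sum(axis=axes)
        g = self.gamma[:, None, None]
        dxhat = grad * g
        return (
            inv_std[:, None, None]
            / m
            * (m * dxhat - dxhat.sum(axis=axes)[:, None, None]
               - xhat * (dxhat * xhat).sum(axis=axes)[:, None, None])
        )


class ReLU(Layer):
    def forward(self, x, mode, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Pool2D(Layer):
    """3x3 stride-2 style pooling, modes max | average | stochastic."""

    def __init__(self, kernel: int, stride: int, mode: str):
        if mode not in ("max", "average", "stochastic"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.kernel, self.stride, self.mode = kernel, stride, mode

    def forward(self, x, mode, rng=None):
        n, c, h, w = x.shape
        k, s = self.kernel, self.stride
        out_h, out_w = ceil(h / s), ceil(w / s)
        pads = (*same_pad_amounts(h, k, s), *same_pad_amounts(w, k, s))
        fill = -np.inf if self.mode == "max" else 0.0
        xp = _pad_nchw(x, pads, value=fill)
        win = _windows(xp, k, s, out_h, out_w).reshape(n, c, out_h, out_w, k * k)
        pt, pb, pl, pr = pads
        valid = np.pad(np.ones((h, w), bool), ((pt, pb), (pl, pr)))
        vwin = (
            sliding_window_view(valid, (k, k))[
                : (out_h - 1) * s + 1 : s, : (out_w - 1) * s + 1 : s
            ].reshape(out_h, out_w, k * k)
        )
        self._geom = (x.shape, pads, (out_h, out_w))
        if self.mode == "max":
            idx = win.argmax(axis=-1)
            out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
            self._sel = idx
            return out
        if self.mode == "average":
            counts = vwin.sum(axis=-1)                    # oh, ow
            out = win.sum(axis=-1) / counts
            self._counts, self._vwin = counts, vwin
            return out
        # stochastic: chi assumed >= 0 (post-ReLU); padded zeros carry no mass
        totals = win.sum(axis=-1)
        if mode == "train":
            if rng is None:
                raise ValueError("train-mode stochastic pooling requires an rng")
            cum = np.cumsum(win, axis=-1)
            u = rng.random(totals.shape) * totals
            idx = (cum > u[..., None]).argmax(axis=-1)
            out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
            out = np.where(totals > 0, out, 0.0)
            self._sel = idx
            self._dead = totals == 0
            return out
        # inference: expectation sum chi^2 / sum chi
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(totals > 0, (win * win).sum(axis=-1) / np.where(totals > 0, totals, 1.0), 0.0)
        self._sel = None
        return out

    def backward(self, grad):
        x_shape, pads, (out_h, out_w) = self._geom
        n, c, h, w = x_shape
        k, s = self.kernel, self.stride
        pt, pb, pl, pr = pads
        dxp = np.zeros((n, c, h + pt + pb, w + pl + pr))
        if self.mode == "average":
            dwin = (grad / self._counts)[..., None] * self._vwin
            dwin = dwin.reshape(n, c, out_h, out_w, k, k)
        else:
            if self._sel is None:
                raise RuntimeError("no cached selection; backward follows a train-mode forward")
            g = grad
            if self.mode == "stochastic":
                g = np.where(self._dead, 0.0, grad)
            onehot = np.arange(k * k) == self._sel[..., None]
            dwin = (g[..., None] * onehot).reshape(n, c, out_h, out_w, k, k)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + (out_h - 1) * s + 1 : s, j : j + (out_w - 1) * s + 1 : s] += (
                    dwin[:, :, :, :, i, j]
                )
        return dxp[:, :, pt : pt + h, pl : pl + w]


class Flatten(Layer):
    def forward(self, x, mode, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    """Fully-connected layer y = x W^T + b with W of shape (out, in)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.grads = {"W": np.zeros_like(self.W), "b": np.zeros_like(self.b)}

    def params(self):
        yield self.W, self.grads["W"]
        yield self.b, self.grads["b"]

    def forward(self, x, mode, rng=None):
        if x.shape[1] != self.W.shape[1]:
            raise errors.DimensionMismatch(
                f"expected input dim {self.W.shape[1]}, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, grad):
        self.grads["W"][...] = grad.T @ self._x
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.W


class Dropout(Layer):
    """Inverted dropout: identity at inference."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("drop probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, mode, rng=None):
        if mode != "train" or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("train-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and gradient w.r.t. the logits."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    probs = e / e.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.clip(probs[np.arange(n), labels], 1e-12, None)).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return float(loss), dlogits / n
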