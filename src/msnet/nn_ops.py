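"""Layer-level mathematics: convolution shape arithmetic, convolution,
ReLU, batch normalization, dropout, softmax, and the three pooling
operators including stochastic pooling.

These are pure, numpy-level reference operators.  The trainable network in
:mod:`msnet.layers` uses vectorized versions of the same mathematics; the
functions here define the contracts and serve as the readable single-region
forms.

Stochastic pooling replaces the deterministic max/average reduction of a
pooling region by sampling: each activation chi_i in region R_j is selected
with probability p_i = chi_i / sum_k chi_k (so regions are assumed
non-negative, i.e. post-ReLU).  At training time one location is sampled
per region; at inference the probability-weighted expectation
sum_i p_i * chi_i is used, which is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor
from typing import Literal

import numpy as np

from . import errors

PadMode = Literal["same"] | int


@dataclass(frozen=True)
class ConvSpec:
    """Convolution hyperparameters: filter size, channels, stride, padding."""

    filter_height: int = 3
    filter_width: int = 3
    in_channels: int = 1
    num_filters: int = 8
    stride: int = 1
    padding: PadMode = "same"

    def __post_init__(self) -> None:
        if min(self.filter_height, self.filter_width, self.stride) < 1:
            raise ValueError("filter size and stride must be >= 1")
        if self.num_filters < 1:
            raise ValueError("num_filters must be >= 1")
        if isinstance(self.padding, int) and self.padding < 0:
            raise ValueError("explicit padding must be >= 0")


@dataclass(frozen=True)
class PoolSpec:
    """Pooling hyperparameters; padding is always 'same'."""

    kernel: int = 3
    stride: int = 2
    mode: Literal["max", "average", "stochastic"] = "max"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")


@dataclass
class BNState:
    """Per-channel batch-normalization parameters and running moments."""

    scale: np.ndarray
    offset: np.ndarray
    epsilon: float = 1e-5
    running_mean: np.ndarray | None = None
    running_var: np.ndarray | None = None
    momentum: float = 0.1

    @classmethod
    def init(cls, channels: int, epsilon: float = 1e-5, momentum: float = 0.1) -> "BNState":
        return cls(
            scale=np.ones(channels),
            offset=np.zeros(channels),
            epsilon=epsilon,
            running_mean=np.zeros(channels),
            running_var=np.ones(channels),
            momentum=momentum,
        )


@dataclass(frozen=True)
class DropoutSpec:
    """Dropout probability and mode."""

    drop_probability: float = 0.5
    mode: Literal["train", "inference"] = "train"

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_probability < 1.0:
            raise ValueError("drop probability must lie in [0, 1)")


def conv_out_shape(spec: ConvSpec, in_h: int, in_w: int) -> tuple[int, int]:
    """Output spatial size of a strided convolution.

    Explicit padding N: ``1 + floor((2N + H_I - H_F) / M)`` per axis.
    'same' padding: ``ceil(H_I / M)``.
    """
    if in_h < 1 or in_w < 1:
        raise ValueError("input size must be >= 1")
    if spec.padding == "same":
        out = (ceil(in_h / spec.stride), ceil(in_w / spec.stride))
    else:
        n = spec.padding
        out = (
            1 + floor((2 * n + in_h - spec.filter_height) / spec.stride),
            1 + floor((2 * n + in_w - spec.filter_width) / spec.stride),
        )
    if min(out) < 1:
        raise errors.NonPositiveOutput(f"output shape {out} is degenerate")
    return out


def same_pad_amounts(in_size: int, kernel: int, stride: int) -> tuple[int, int]:
    """(before, after) zero-padding for 'same' output size ceil(in/stride)."""
    out = ceil(in_size / stride)
    total = max((out - 1) * stride + kernel - in_size, 0)
    before = total // 2
    return before, total - before


def conv2d(inputs: np.ndarray, filters: np.ndarray, spec: ConvSpec) -> np.ndarray:
    """2-D cross-correlation of an H x W x D map with Z filters.

    ``inputs`` has shape (H, W, D); ``filters`` has shape (Z, H_F, W_F, D).
    Returns an (H_O, W_O, Z) map with stride and padding taken from ``spec``.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    filters = np.asarray(filters, dtype=np.float64)
    if inputs.ndim == 2:
        inputs = inputs[:, :, None]
    if filters.shape[-1] != inputs.shape[-1]:
        raise errors.ChannelMismatch(
            f"filter depth {filters.shape[-1]} != input depth {inputs.shape[-1]}"
        )
    h, w, _ = inputs.shape
    z, kh, kw, _ = filters.shape
    out_h, out_w = conv_out_shape(spec, h, w)
    if spec.padding == "same":
        pt, pb = same_pad_amounts(h, kh, spec.stride)
        pl, pr = same_pad_amounts(w, kw, spec.stride)
    else:
        pt = pb = pl = pr = spec.padding
    padded = np.pad(inputs, ((pt, pb), (pl, pr), (0, 0)), mode="constant")
    out = np.empty((out_h, out_w, z))
    for i in range(out_h):
        for j in range(out_w):
            patch = padded[
                i * spec.stride : i * spec.stride + kh,
                j * spec.stride : j * spec.stride + kw,
                :,
            ]
            out[i, j, :] = np.tensordot(filters, patch, axes=([1, 2, 3], [0, 1, 2]))
    return out


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def batch_norm(
    batch: np.ndarray, state: BNState, mode: Literal["train", "inference"] = "train"
) -> np.ndarray:
    """Normalize a mini-batch per channel, then apply the learned affine.

    ``batch`` has shape (m, ...) with the channel as the LAST axis, or is a
    1-D vector treated as one channel.  Train mode standardizes with the
    batch mean/variance (biased, 1/m) and updates the running moments by an
    exponential moving average; inference mode uses the running moments.
    """
    batch = np.asarray(batch, dtype=np.float64)
    squeeze = batch.ndim == 1
    if squeeze:
        batch = batch[:, None]
    m = batch.shape[0]
    axes = tuple(range(batch.ndim - 1))
    if mode == "train":
        if m < 2:
            raise errors.BatchTooSmall("train-mode batch norm needs m >= 2")
        mean = batch.mean(axis=axes)
        var = batch.var(axis=axes)
        if state.running_mean is not None:
            state.running_mean = (1 - state.momentum) * state.running_mean + state.momentum * mean
            state.running_var = (1 - state.momentum) * state.running_var + state.momentum * var
    else:
        if state.running_mean is None or state.running_var is None:
            raise ValueError("inference-mode batch norm needs initialized running moments")
        mean, var = state.running_mean, state.running_var
    normed = (batch - mean) / np.sqrt(var + state.epsilon)
    out = state.scale * normed + state.offset
    return out[:, 0] if squeeze else out


def dropout(
    x: np.ndarray, spec: DropoutSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Inverted dropout: zero units w.p. p at train time, scale survivors by
    1/(1-p); inference is the identity."""
    x = np.asarray(x, dtype=np.float64)
    if spec.mode == "inference" or spec.drop_probability == 0.0:
        return x.copy()
    if rng is None:
        raise ValueError("train-mode dropout requires an rng")
    keep = rng.random(x.shape) >= spec.drop_probability
    return x * keep / (1.0 - spec.drop_probability)


def pool_deterministic(activation_map: np.ndarray, spec: PoolSpec) -> np.ndarray:
    """Max or average pooling of an (H, W) or (H, W, C) map, 'same' padding.

    Padded positions are excluded both from max candidates and from the
    average denominator.
    """
    if spec.mode not in ("max", "average"):
        raise ValueError("pool_deterministic handles 'max' and 'average' only")
    x = np.asarray(activation_map, dtype=np.float64)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    regions, mask = _pool_regions(x, spec)
    if spec.mode == "max":
        filled = np.where(mask, regions, -np.inf)
        out = filled.max(axis=-1)
    else:
        out = (regions * mask).sum(axis=-1) / mask.sum(axis=-1)
    return out[:, :, 0] if squeeze else out


def _pool_regions(x: np.ndarray, spec: PoolSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gather (out_h, out_w, C, k*k) pooling regions and their validity mask."""
    h, w, c = x.shape
    k, s = spec.kernel, spec.stride
    out_h, out_w = ceil(h / s), ceil(w / s)
    pt, pb = same_pad_amounts(h, k, s)
    pl, pr = same_pad_amounts(w, k, s)
    padded = np.pad(x, ((pt, pb), (pl, pr), (0, 0)), mode="constant")
    valid = np.pad(np.ones((h, w), bool), ((pt, pb), (pl, pr)), mode="constant")
    regions = np.empty((out_h, out_w, c, k * k))
    mask = np.empty((out_h, out_w, 1, k * k), bool)
    for i in range(out_h):
        for j in range(out_w):
            patch = padded[i * s : i * s + k, j * s : j * s + k, :]
            regions[i, j] = patch.reshape(-1, c).T
            mask[i, j, 0] = valid[i * s : i * s + k, j * s : j * s + k].reshape(-1)
    return regions, mask


def stochastic_pool_probs(region: np.ndarray) -> np.ndarray:
    """Selection probabilities p_i = chi_i / sum_k chi_k for one region.

    An all-zero region yields uniform probabilities by convention.
    """
    region = np.asarray(region, dtype=np.float64).ravel()
    if (region < 0).any():
        raise errors.NegativeActivation("stochastic pooling requires chi >= 0")
    total = region.sum()
    if total == 0:
        return np.full(region.size, 1.0 / region.size)
    return region / total


def stochastic_pool_sample(region: np.ndarray, rng: np.random.Generator) -> float:
    """Sample one activation chi_l with l ~ multinomial(p) over the region.

    The region is scanned left-to-right, top-to-bottom; an all-zero region
    returns 0 (every candidate value is 0).
    """
    flat = np.asarray(region, dtype=np.float64).ravel()
    probs = stochastic_pool_probs(flat)
    idx = rng.choice(flat.size, p=probs)
    return float(flat[idx])


def stochastic_pool_expect(region: np.ndarray) -> float:
    """Probability-weighted expectation sum_i p_i * chi_i (inference path)."""
    flat = np.asarray(region, dtype=np.float64).ravel()
    probs = stochastic_pool_probs(flat)
    return float(probs @ flat)


def fc_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Affine map y = W x + b with W of shape (n, m)."""
    x = np.asarray(x, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    bias = np.asarray(bias, dtype=np.float64)
    if weights.shape[1] != x.shape[-1] or weights.shape[0] != bias.shape[0]:
        raise errors.DimensionMismatch(
            f"W {weights.shape}, x {x.shape}, b {bias.shape} are incompatible"
        )
    return x @ weights.T + bias


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stabilized softmax along ``axis``."""
    z = np.asarray(z, dtype=np.float64)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)
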