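"""The 14-layer network: 11 convolutional and 3 fully-connected layers.

Counting convention: only conv and FC layers are counted; batch norm, ReLU,
pooling, dropout and softmax are uncounted sublayers.  The default
architecture takes a 256x256 single-channel slice through six stride-2
stages (conv_1, pool_1, conv_2, pool_2, pool_3, pool_4), so the spatial
side shrinks 256 -> 128 -> 64 -> 32 -> 16 -> 8 -> 4 and the final 4x4x64
map flattens to the 1024-unit input of the first FC layer.  Every conv
layer is followed by batch normalization and ReLU; the first two FC layers
are each followed by ReLU and dropout (p = 0.5); the last FC layer feeds a
softmax over the two classes (HC, MS).

The architecture is declarative: an :class:`ArchitectureConfig` is a list
of conv / pool / FC / dropout entries, also expressible as YAML
(``arch/msnet14.yaml`` ships the default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import yaml

from . import errors
from .layers import (
    BatchNorm2D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    Layer,
    Pool2D,
    ReLU,
)
from .nn_ops import ConvSpec, PoolSpec

PoolingMode = Literal["max", "average", "stochastic"]


@dataclass(frozen=True)
class FCSpec:
    """Fully-connected layer: output width; ReLU unless it is the last layer."""

    out_features: int


@dataclass(frozen=True)
class DropSpec:
    """Dropout between FC layers."""

    probability: float = 0.5


LayerSpec = ConvSpec | PoolSpec | FCSpec | DropSpec


@dataclass(frozen=True)
class ArchitectureConfig:
    input_height: int
    input_width: int
    input_channels: int
    layer_sequence: tuple[LayerSpec, ...]
    pooling_mode: PoolingMode = "stochastic"
    batch_norm: bool = True

    def with_pooling(self, mode: PoolingMode) -> "ArchitectureConfig":
        return replace(self, pooling_mode=mode)


def default_config(pooling_mode: PoolingMode = "stochastic",
                   batch_norm: bool = True) -> ArchitectureConfig:
    """The full 14-layer architecture on a 256x256x1 input."""
    conv = lambda cin, cout, stride=1: ConvSpec(3, 3, cin, cout, stride, "same")
    pool = PoolSpec(3, 2, pooling_mode)
    seq: tuple[LayerSpec, ...] = (
        conv(1, 8, 2), pool,
        conv(8, 8, 2), pool,
        conv(8, 16), conv(16, 16), conv(16, 16), pool,
        conv(16, 32), conv(32, 32), conv(32, 32),
        conv(32, 64), conv(64, 64), conv(64, 64), pool,
        FCSpec(20), DropSpec(0.5),
        FCSpec(10), DropSpec(0.5),
        FCSpec(2),
    )
    return ArchitectureConfig(256, 256, 1, seq, pooling_mode, batch_norm)


def small_config(input_side: int = 64, pooling_mode: PoolingMode = "stochastic",
                 batch_norm: bool = True) -> ArchitectureConfig:
    """A reduced variant for small synthetic images: 3 conv + 2 FC layers."""
    seq: tuple[LayerSpec, ...] = (
        ConvSpec(3, 3, 1, 8, 2, "same"), PoolSpec(3, 2, pooling_mode),
        ConvSpec(3, 3, 8, 16, 2, "same"), PoolSpec(3, 2, pooling_mode),
        ConvSpec(3, 3, 16, 16, 1, "same"),
        FCSpec(32), DropSpec(0.5),
        FCSpec(2),
    )
    return ArchitectureConfig(input_side, input_side, 1, seq, pooling_mode, batch_norm)


def shape_trace(config: ArchitectureConfig) -> list[tuple[str, tuple[int, int, int]]]:
    """Per-layer output shapes (h, w, c); validates channel chaining.

    The flatten dimension entering the first FC layer is
    ``h * w * c`` of the last spatial entry.
    """
    h, w, c = config.input_height, config.input_width, config.input_channels
    trace: list[tuple[str, tuple[int, int, int]]] = [("input", (h, w, c))]
    n_conv = n_pool = n_fc = 0
    flat: int | None = None
    for spec in config.layer_sequence:
        if isinstance(spec, ConvSpec):
            if flat is not None:
                raise errors.InconsistentChaining("conv layer after flatten")
            if spec.in_channels != c:
                raise errors.InconsistentChaining(
                    f"conv expects {spec.in_channels} channels, gets {c}"
                )
            from .nn_ops import conv_out_shape

            h, w = conv_out_shape(spec, h, w)
            c = spec.num_filters
            n_conv += 1
            trace.append((f"conv_{n_conv}", (h, w, c)))
        elif isinstance(spec, PoolSpec):
            h = -(-h // spec.stride)
            w = -(-w // spec.stride)
            n_pool += 1
            trace.append((f"pool_{n_pool}", (h, w, c)))
        elif isinstance(spec, FCSpec):
            if flat is None:
                flat = h * w * c
                trace.append(("flatten", (1, 1, flat)))
            n_fc += 1
            trace.append((f"fc_{n_fc}", (1, 1, spec.out_features)))
            flat = spec.out_features
        elif isinstance(spec, DropSpec):
            continue
        else:  # pragma: no cover
            raise TypeError(f"unknown layer spec {spec!r}")
    return trace


def flatten_dim(config: ArchitectureConfig) -> int:
    """Feature-vector length entering the first fully-connected layer."""
    for name, (h, w, c) in shape_trace(config):
        if name == "flatten":
            return h * w * c
    raise ValueError("config has no fully-connected layer")


class Network:
    """An instantiated, trainable network built from an ArchitectureConfig."""

    def __init__(self, config: ArchitectureConfig, layers: list[Layer]):
        self.config = config
        self.layers = layers

    def params(self):
        for layer in self.layers:
            yield from layer.params()

    def num_params(self) -> int:
        return sum(p.size for p, _ in self.params())

    def forward_logits(self, x: np.ndarray, mode: str = "inference",
                       rng: np.random.Generator | None = None) -> np.ndarray:
        if x.shape[2:] != (self.config.input_height, self.config.input_width):
            raise errors.ShapeMismatch(
                f"expected {self.config.input_height}x{self.config.input_width} images, "
                f"got {x.shape[2:]}"
            )
        out = x
        for layer in self.layers:
            out = layer.forward(out, mode, rng)
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.layers):
            grad = layer.backward(grad)


def build(config: ArchitectureConfig, init_seed: int = 0) -> Network:
    """Instantiate the network with He-style seeded random initialization."""
    shape_trace(config)  # validates chaining before any allocation
    rng = np.random.default_rng(init_seed)
    h, w, c = config.input_height, config.input_width, config.input_channels
    layers: list[Layer] = []
    flat: int | None = None
    fc_specs = [s for s in config.layer_sequence if isinstance(s, FCSpec)]
    n_fc_seen = 0
    for spec in config.layer_sequence:
        if isinstance(spec, ConvSpec):
            layers.append(Conv2D(spec.in_channels, spec.num_filters, spec.filter_height,
                                 spec.stride, rng))
            if config.batch_norm:
                layers.append(BatchNorm2D(spec.num_filters))
            layers.append(ReLU())
            h = -(-h // spec.stride)
            w = -(-w // spec.stride)
            c = spec.num_filters
        elif isinstance(spec, PoolSpec):
            layers.append(Pool2D(spec.kernel, spec.stride, config.pooling_mode))
            h = -(-h // spec.stride)
            w = -(-w // spec.stride)
        elif isinstance(spec, FCSpec):
            if flat is None:
                layers.append(Flatten())
                flat = h * w * c
            layers.append(Dense(flat, spec.out_features, rng))
            n_fc_seen += 1
            if n_fc_seen < len(fc_specs):
                layers.append(ReLU())
            flat = spec.out_features
        elif isinstance(spec, DropSpec):
            layers.append(Dropout(spec.probability))
    return Network(config, layers)


def forward(network: Network, images: Sequence[np.ndarray] | np.ndarray,
            mode: str = "inference",
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Class-probability pairs (HC, MS) for a batch of grayscale images."""
    if isinstance(images, np.ndarray) and images.ndim == 4:
        x = images
    else:
        x = np.stack([np.asarray(im, dtype=np.float64) for im in images])[:, None]
    logits = network.forward_logits(x, mode, rng)
    from .nn_ops import softmax

    return softmax(logits, axis=1)


# --- YAML round-trip -------------------------------------------------------

def config_to_dict(config: ArchitectureConfig) -> dict:
    seq = []
    for s in config.layer_sequence:
        if isinstance(s, ConvSpec):
            seq.append({"type": "conv", "kernel": [s.filter_height, s.filter_width],
                        "in_channels": s.in_channels, "filters": s.num_filters,
                        "stride": s.stride, "padding": s.padding})
        elif isinstance(s, PoolSpec):
            seq.append({"type": "pool", "kernel": s.kernel, "stride": s.stride})
        elif isinstance(s, FCSpec):
            seq.append({"type": "fc", "out_features": s.out_features})
        elif isinstance(s, DropSpec):
            seq.append({"type": "dropout", "probability": s.probability})
    return {
        "input": {"height": config.input_height, "width": config.input_width,
                  "channels": config.input_channels},
        "pooling_mode": config.pooling_mode,
        "batch_norm": config.batch_norm,
        "layers": seq,
    }


def config_from_dict(d: dict) -> ArchitectureConfig:
    seq: list[LayerSpec] = []
    mode = d.get("pooling_mode", "stochastic")
    for s in d["layers"]:
        t = s["type"]
        if t == "conv":
            kh, kw = s["kernel"]
            seq.append(ConvSpec(kh, kw, s["in_channels"], s["filters"],
                                s.get("stride", 1), s.get("padding", "same")))
        elif t == "pool":
            seq.append(PoolSpec(s.get("kernel", 3), s.get("stride", 2), mode))
        elif t == "fc":
            seq.append(FCSpec(s["out_features"]))
        elif t == "dropout":
            seq.append(DropSpec(s.get("probability", 0.5)))
        else:
            raise ValueError(f"unknown layer type {t!r}")
    inp = d["input"]
    return ArchitectureConfig(inp["height"], inp["width"], inp["channels"],
                              tuple(seq), mode, d.get("batch_norm", True))


def load_config(path: str | Path | None = None) -> ArchitectureConfig:
    """Load an architecture YAML; default is the shipped msnet14 file."""
    if path is None:
        text = resources.files("msnet").joinpath("arch/msnet14.yaml").read_text()
    else:
        text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text))


def save_config(config: ArchitectureConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
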