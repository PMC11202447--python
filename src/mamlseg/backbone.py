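"""Enhanced residual 3D U-Net backbone.

The network is a U-shaped fully convolutional segmenter for single-channel
volumes:

* the encoder is a stack of residual units whose first convolution carries a
  stride of two, halving each spatial axis per level (no pooling);
* the decoder mirrors it with stride-two transpose convolutions, each level
  concatenating the skip connection from the matching encoder level before a
  single-subunit residual refinement;
* activations are PReLU with one learned slope per layer, normalization is
  per-sample instance normalization with affine scale/shift (a BatchNorm-style
  variant pooling statistics over the batch is available behind
  ``norm="batch"``), and dropout regularizes the first convolution of each
  residual unit.

With the default widths (16, 32, 64, 128, 256), strides (2, 2, 2, 2) and two
residual subunits per level, a 1-in / 2-out network has exactly 4,808,917
learnable scalars (convolution and transpose-convolution weights and biases,
normalization scales and shifts, and PReLU slopes).
"""

from __future__ import annotations

import json
from collections import OrderedDict
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np

from .nn.layers import ConvUnit, Module, ResidualUnit, Sequential, SkipConnection

__all__ = [
    "BackboneConfig",
    "ModelState",
    "Backbone",
    "build_backbone",
    "forward",
    "count_parameters",
    "prelu",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture hyperparameters of the residual 3D U-Net."""

    spatial_dims: int = 3
    in_channels: int = 1
    out_channels: int = 2
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    strides: tuple[int, ...] = (2, 2, 2, 2)
    num_res_units: int = 2
    dropout: float = 0.1
    norm: str = "instance"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(int(c) for c in self.channels))
        object.__setattr__(self, "strides", tuple(int(s) for s in self.strides))
        if self.spatial_dims != 3:
            raise ValueError("only spatial_dims=3 is supported")
        if len(self.strides) != len(self.channels) - 1:
            raise ValueError(
                f"len(strides)={len(self.strides)} must equal "
                f"len(channels)-1={len(self.channels) - 1}")
        if len(self.channels) < 2:
            raise ValueError("need at least 2 channel levels")
        if any(c < 1 for c in self.channels) or any(s < 1 for s in self.strides):
            raise ValueError("channels and strides must all be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.norm not in ("instance", "batch"):
            raise ValueError(f"norm must be 'instance' or 'batch', got {self.norm!r}")
        if self.num_res_units < 1:
            raise ValueError("num_res_units must be >= 1")

    @property
    def np_dtype(self) -> np.dtype:
        return np.dtype(self.dtype)

    @property
    def stride_product(self) -> int:
        return int(np.prod(self.strides))


@dataclass
class ModelState:
    """A backbone architecture plus one concrete parameter vector."""

    config: BackboneConfig
    params: "OrderedDict[str, np.ndarray]"

    def copy(self) -> "ModelState":
        return ModelState(self.config, OrderedDict((k, v.copy()) for k, v in self.params.items()))


class Backbone:
    """Computational engine for a :class:`BackboneConfig`.

    Holds the layer tree; parameters flow in and out as flat named dicts so
    the same engine can evaluate many parameter vectors (the meta-learning
    loop's ``theta`` and its adapted copies).
    """

    def __init__(self, cfg: BackboneConfig) -> None:
        self.cfg = cfg
        batch_stats = cfg.norm == "batch"

        def make_block(cin: int, cout: int, channels: tuple[int, ...],
                       strides: tuple[int, ...], is_top: bool) -> Module:
            c, s = channels[0], strides[0]
            if len(channels) > 2:
                sub = make_block(c, c, channels[1:], strides[1:], False)
                upc = c * 2
            else:
                sub = ResidualUnit(c, channels[1], stride=1,
                                   subunits=cfg.num_res_units, dropout=cfg.dropout,
                                   batch_stats=batch_stats)
                upc = c + channels[1]
            down = ResidualUnit(cin, c, stride=s, subunits=cfg.num_res_units,
                                dropout=cfg.dropout, batch_stats=batch_stats)
            up = Sequential([
                ("upconv", ConvUnit(upc, cout, stride=s, transpose=True,
                                    batch_stats=batch_stats)),
                ("refine", ResidualUnit(cout, cout, stride=1, subunits=1,
                                        dropout=cfg.dropout, last_conv_only=is_top,
                                        batch_stats=batch_stats)),
            ])
            return Sequential([("down", down), ("skip", SkipConnection(sub)), ("up", up)])

        self.net = make_block(cfg.in_channels, cfg.out_channels,
                              cfg.channels, cfg.strides, True)

    # -- parameter plumbing -------------------------------------------------
    def init_params(self, seed: int) -> "OrderedDict[str, np.ndarray]":
        rng = np.random.default_rng(seed)
        self.net.init(rng, self.cfg.np_dtype)
        return OrderedDict((k, v.copy()) for k, v in self.net.named_params().items())

    def set_params(self, params: dict) -> None:
        self.net.set_params(params)

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def grads(self) -> "OrderedDict[str, np.ndarray]":
        return self.net.named_grads()

    # -- computation --------------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5:
            raise ValueError(f"expected input (B, C, D, H, W), got shape {x.shape}")
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} input channels, got {x.shape[1]}")
        sp = self.cfg.stride_product
        for axis, n in zip("DHW", x.shape[2:]):
            if n % sp != 0:
                raise ValueError(
                    f"spatial axis {axis} has extent {n}, not divisible by the "
                    f"stride product {sp}")

    def forward(self, params: dict, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-voxel class logits, same spatial shape as the input."""
        self._check_shape(x)
        self.set_params(params)
        return self.net.forward(x.astype(self.cfg.np_dtype, copy=False),
                                train=train, rng=rng)

    def backward(self, glogits: np.ndarray) -> "OrderedDict[str, np.ndarray]":
        """Backprop ``dLoss/dlogits`` through the cached forward; returns grads."""
        self.zero_grad()
        self.net.backward(glogits)
        return self.grads()


@lru_cache(maxsize=8)
def get_engine(cfg: BackboneConfig) -> Backbone:
    return Backbone(cfg)


def build_backbone(cfg: BackboneConfig | None = None, rng_seed: int = 0) -> ModelState:
    """Construct a seeded, reproducibly initialized :class:`ModelState`."""
    cfg = cfg or BackboneConfig()
    return ModelState(cfg, get_engine(cfg).init_params(rng_seed))


def forward(state: ModelState, batch: np.ndarray, train_mode: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Run the network on ``batch (B, C, D, H, W)``; evaluation mode is deterministic."""
    return get_engine(state.config).forward(state.params, batch, train=train_mode, rng=rng)


def count_parameters(state: ModelState) -> int:
    """Total number of learnable scalars (weights, biases, norm affines, PReLU slopes)."""
    return int(sum(v.size for v in state.params.values()))


def prelu(y: np.ndarray | float, slope: float) -> np.ndarray | float:
    """Parametric ReLU: ``y`` for ``y > 0``, ``slope * y`` otherwise."""
    y_arr = np.asarray(y)
    out = np.where(y_arr > 0, y_arr, slope * y_arr)
    return out.item() if np.isscalar(y) or y_arr.ndim == 0 else out


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(state: ModelState, path: str | Path) -> None:
    """Save params + config as a named-array archive (.npz)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(state.config))
    arrays = {f"param:{k}": v for k, v in state.params.items()}
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path: str | Path,
                    expect_config: BackboneConfig | None = None) -> ModelState:
    """Load a checkpoint; raises if it does not match ``expect_config``."""
    path = Path(path)
    with np.load(path) as data:
        cfg_json = bytes(data["__config__"]).decode()
        cfg_dict = json.loads(cfg_json)
        cfg_dict["channels"] = tuple(cfg_dict["channels"])
        cfg_dict["strides"] = tuple(cfg_dict["strides"])
        cfg = BackboneConfig(**cfg_dict)
        params = OrderedDict(
            (k[len("param:"):], data[k]) for k in data.files if k.startswith("param:"))
    if expect_config is not None and cfg != expect_config:
        raise ValueError(
            f"checkpoint at {path} was built for config {cfg}, which does not "
            f"match the requested config {expect_config}")
    # preserve the engine's parameter ordering
    order = get_engine(cfg).init_params(0).keys()
    return ModelState(cfg, OrderedDict((k, params[k]) for k in order))
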