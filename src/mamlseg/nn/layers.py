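"""Composable network layers with explicit reverse-mode gradients.

Each :class:`Module` owns named parameter arrays (``self.p``) and matching
gradient accumulators (``self.g``).  ``forward`` caches whatever its
``backward`` needs; a forward immediately followed by a backward therefore
forms one reverse-mode sweep.  Parameters are addressed by slash-separated
paths (``"down0/unit0/conv/w"``) so a whole network can be read or written as
a flat ordered dict — the representation the meta-learning loop manipulates.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F

_EPS = 1e-5


class Module:
    def __init__(self) -> None:
        self.p: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.g: "OrderedDict[str, np.ndarray]" = OrderedDict()
        self.children: "OrderedDict[str, Module]" = OrderedDict()
        self._cache: dict = {}

    def add(self, name: str, child: "Module") -> "Module":
        self.children[name] = child
        return child

    def named_params(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for k, v in self.p.items():
            out[prefix + k] = v
        for cname, child in self.children.items():
            out.update(child.named_params(prefix + cname + "/"))
        return out

    def named_grads(self, prefix: str = "") -> "OrderedDict[str, np.ndarray]":
        out: "OrderedDict[str, np.ndarray]" = OrderedDict()
        for k, v in self.g.items():
            out[prefix + k] = v
        for cname, child in self.children.items():
            out.update(child.named_grads(prefix + cname + "/"))
        return out

    def set_params(self, params: dict, prefix: str = "") -> None:
        for k in self.p:
            self.p[k] = params[prefix + k]
        for cname, child in self.children.items():
            child.set_params(params, prefix + cname + "/")

    def zero_grad(self) -> None:
        self.g = OrderedDict((k, np.zeros_like(v)) for k, v in self.p.items())
        for child in self.children.values():
            child.zero_grad()

    def init(self, rng: np.random.Generator, dtype: np.dtype) -> None:
        for child in self.children.values():
            child.init(rng, dtype)

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Module):
    """3D convolution (or transpose convolution) with bias, 'same'-style padding."""

    def __init__(self, cin: int, cout: int, kernel: int = 3, stride: int = 1,
                 transpose: bool = False) -> None:
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, kernel, stride
        self.transpose = transpose

    def init(self, rng: np.random.Generator, dtype: np.dtype) -> None:
        fan_in = self.cin * self.k ** 3
        # He initialization adjusted for PReLU(0.25) nonlinearities
        std = np.sqrt(2.0 / ((1 + 0.25 ** 2) * fan_in))
        shape = ((self.cin, self.cout) if self.transpose else (self.cout, self.cin)) + (self.k,) * 3
        self.p["w"] = rng.normal(0.0, std, size=shape).astype(dtype)
        bound = 1.0 / np.sqrt(fan_in)
        self.p["b"] = rng.uniform(-bound, bound, size=self.cout).astype(dtype)

    def forward(self, x, train=False, rng=None):
        self._cache["x"] = x
        if self.transpose:
            return F.conv_transpose3d(x, self.p["w"], self.p["b"], self.stride)
        return F.conv3d(x, self.p["w"], self.p["b"], self.stride)

    def backward(self, gy):
        x = self._cache["x"]
        if self.transpose:
            gx, gw, gb = F.conv_transpose3d_grad(x, self.p["w"], self.stride, gy)
        else:
            gx, gw, gb = F.conv3d_grad(x, self.p["w"], self.stride, gy)
        self.g["w"] += gw
        self.g["b"] += gb
        return gx


class InstanceNorm3d(Module):
    """Normalize each sample's channels independently over space; affine scale/shift.

    Uses the current activations' statistics in both training and evaluation
    mode, so evaluation is deterministic and batch-composition independent.
    """

    def __init__(self, channels: int, batch_stats: bool = False) -> None:
        super().__init__()
        self.channels = channels
        self.batch_stats = batch_stats  # True = BatchNorm-style pooling over batch

    def init(self, rng, dtype):
        self.p["gamma"] = np.ones(self.channels, dtype=dtype)
        self.p["beta"] = np.zeros(self.channels, dtype=dtype)

    def _axes(self):
        return (0, 2, 3, 4) if self.batch_stats else (2, 3, 4)

    def forward(self, x, train=False, rng=None):
        axes = self._axes()
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        inv = 1.0 / np.sqrt(var + _EPS)
        xhat = (x - mu) * inv
        self._cache.update(xhat=xhat, inv=inv)
        gamma = self.p["gamma"][None, :, None, None, None]
        beta = self.p["beta"][None, :, None, None, None]
        return gamma * xhat + beta

    def backward(self, gy):
        xhat, inv = self._cache["xhat"], self._cache["inv"]
        axes = self._axes()
        n = np.prod([xhat.shape[a] for a in axes])
        gamma = self.p["gamma"][None, :, None, None, None]
        self.g["gamma"] += (gy * xhat).sum(axis=(0, 2, 3, 4))
        self.g["beta"] += gy.sum(axis=(0, 2, 3, 4))
        gxhat = gy * gamma
        gx = inv * (gxhat
                    - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True))
        return gx.astype(gy.dtype, copy=False)


class PReLU(Module):
    """Parametric ReLU with a single learned slope shared across the layer."""

    def __init__(self, init_slope: float = 0.25) -> None:
        super().__init__()
        self.init_slope = init_slope

    def init(self, rng, dtype):
        self.p["slope"] = np.array([self.init_slope], dtype=dtype)

    def forward(self, x, train=False, rng=None):
        self._cache["x"] = x
        s = self.p["slope"][0]
        return np.where(x > 0, x, s * x)

    def backward(self, gy):
        x = self._cache["x"]
        neg = x <= 0
        self.g["slope"][0] += float((gy * x * neg).sum())
        s = self.p["slope"][0]
        return np.where(neg, s * gy, gy)


class Dropout(Module):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._cache["mask"] = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        self._cache["mask"] = mask
        return x * mask

    def backward(self, gy):
        mask = self._cache["mask"]
        return gy if mask is None else gy * mask


class Sequential(Module):
    def __init__(self, named_modules: list[tuple[str, Module]]) -> None:
        super().__init__()
        for name, m in named_modules:
            self.add(name, m)

    def forward(self, x, train=False, rng=None):
        for m in self.children.values():
            x = m.forward(x, train=train, rng=rng)
        return x

    def backward(self, gy):
        for m in reversed(self.children.values()):
            gy = m.backward(gy)
        return gy


class ConvUnit(Sequential):
    """Convolution followed (optionally) by normalization, dropout and PReLU."""

    def __init__(self, cin: int, cout: int, stride: int = 1, kernel: int = 3,
                 transpose: bool = False, dropout: float = 0.0,
                 conv_only: bool = False, batch_stats: bool = False) -> None:
        mods: list[tuple[str, Module]] = [
            ("conv", Conv3d(cin, cout, kernel=kernel, stride=stride, transpose=transpose))
        ]
        if not conv_only:
            mods.append(("norm", InstanceNorm3d(cout, batch_stats=batch_stats)))
            if dropout > 0:
                mods.append(("drop", Dropout(dropout)))
            mods.append(("act", PReLU()))
        super().__init__(mods)


class ResidualUnit(Module):
    """Stack of conv units plus an identity/projection shortcut.

    The first conv unit carries the stride (and the dropout, when enabled);
    the shortcut is a strided 3x3x3 convolution when the unit down-samples, a
    1x1x1 projection when only the channel count changes, and the identity
    otherwise.
    """

    def __init__(self, cin: int, cout: int, stride: int = 1, subunits: int = 2,
                 dropout: float = 0.0, last_conv_only: bool = False,
                 batch_stats: bool = False) -> None:
        super().__init__()
        mods: list[tuple[str, Module]] = []
        c = cin
        for i in range(subunits):
            mods.append((f"unit{i}", ConvUnit(
                c, cout,
                stride=stride if i == 0 else 1,
                dropout=dropout if i == 0 else 0.0,
                conv_only=last_conv_only and i == subunits - 1,
                batch_stats=batch_stats)))
            c = cout
        self.add("path", Sequential(mods))
        if stride != 1 or cin != cout:
            k = 3 if stride != 1 else 1
            self.add("shortcut", Conv3d(cin, cout, kernel=k, stride=stride))

    def forward(self, x, train=False, rng=None):
        y = self.children["path"].forward(x, train=train, rng=rng)
        if "shortcut" in self.children:
            res = self.children["shortcut"].forward(x, train=train, rng=rng)
        else:
            res = x
        return y + res

    def backward(self, gy):
        gx = self.children["path"].backward(gy)
        if "shortcut" in self.children:
            gx = gx + self.children["shortcut"].backward(gy)
        else:
            gx = gx + gy
        return gx


class SkipConnection(Module):
    """Channel-concatenate a submodule's output with its own input."""

    def __init__(self, sub: Module) -> None:
        super().__init__()
        self.add("sub", sub)

    def forward(self, x, train=False, rng=None):
        y = self.children["sub"].forward(x, train=train, rng=rng)
        self._cache["split"] = x.shape[1]
        return np.concatenate([x, y], axis=1)

    def backward(self, gy):
        split = self._cache["split"]
        gx = gy[:, :split]
        gsub = self.children["sub"].backward(gy[:, split:])
        return np.ascontiguousarray(gx) + gsub
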