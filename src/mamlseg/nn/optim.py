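"""Adam optimizer over flat named-parameter dicts."""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np


@dataclass
class AdamState:
    """First/second moment estimates and step counter for Adam."""

    m: "OrderedDict[str, np.ndarray]" = field(default_factory=OrderedDict)
    v: "OrderedDict[str, np.ndarray]" = field(default_factory=OrderedDict)
    t: int = 0


def adam_step(params: "OrderedDict[str, np.ndarray]",
              grads: dict,
              state: AdamState,
              lr: float,
              betas: tuple[float, float] = (0.9, 0.999),
              eps: float = 1e-8,
              weight_decay: float = 0.0) -> "OrderedDict[str, np.ndarray]":
    """One Adam update; returns new params, mutates ``state``.

    ``weight_decay`` is L2-style (added to the gradient before the moment
    updates), matching the common Adam-with-weight-decay convention.
    """
    b1, b2 = betas
    state.t += 1
    t = state.t
    out: "OrderedDict[str, np.ndarray]" = OrderedDict()
    for k, p in params.items():
        g = grads[k]
        if weight_decay:
            g = g + weight_decay * p
        if k not in state.m:
            state.m[k] = np.zeros_like(p)
            state.v[k] = np.zeros_like(p)
        state.m[k] = b1 * state.m[k] + (1 - b1) * g
        state.v[k] = b2 * state.v[k] + (1 - b2) * g * g
        mhat = state.m[k] / (1 - b1 ** t)
        vhat = state.v[k] / (1 - b2 ** t)
        out[k] = p - lr * mhat / (np.sqrt(vhat) + eps)
    return out
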