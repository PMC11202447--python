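"""Configuration presets.

``reference_*`` presets carry the reference experimental settings: the full-width
backbone (16-256 channels, 4,808,917 parameters, trained on 128x128x256 or
128x128x128 volumes) and the published hyperparameters (alpha 1e-4, beta 1e-6,
weight decay 1e-5, batch size 1, dropout 0.1, patience 20/10).  Training at
that scale needs a GPU-class budget.

``desk_*`` presets define the package's CPU-scale study conditions used by the
test-suite and the reproduction script: 32x32x32 phantom volumes, a narrower
backbone (8-32 channels, same topology), a first-order meta-gradient, larger
step sizes so optimization progresses within tens of outer steps, and reduced
patience/epoch caps.  See docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from .backbone import BackboneConfig
from .meta import MetaConfig

__all__ = [
    "reference_backbone",
    "reference_meta_config",
    "desk_backbone",
    "desk_meta_config",
    "DESK_SHAPE",
]

DESK_SHAPE = (32, 32, 32)


def reference_backbone() -> BackboneConfig:
    """The full-scale residual 3D U-Net (4,808,917 parameters)."""
    return BackboneConfig()


def reference_meta_config(seed: int = 0) -> MetaConfig:
    """Published hyperparameters; second-order meta-gradients."""
    return MetaConfig(seed=seed)


def desk_backbone() -> BackboneConfig:
    """Narrow 3-level variant of the same architecture for CPU-scale runs."""
    return BackboneConfig(channels=(8, 16, 32), strides=(2, 2),
                          num_res_units=2, dropout=0.1)


def desk_meta_config(seed: int = 0) -> MetaConfig:
    """CPU-scale meta-learning settings (first-order, larger steps, short caps)."""
    return MetaConfig(
        inner_lr=1e-2,
        outer_lr=1e-3,
        first_order=True,
        steps_per_epoch=2,
        max_epochs_meta=60,
        patience_meta_train=5,
        max_epochs_fine_tune=20,
        patience_fine_tune=5,
        fine_tune_lr=1e-3,
        seed=seed,
    )
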