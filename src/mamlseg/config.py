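"""Declarative run configuration (YAML) shared by the CLI commands.

A run config resolves to: a data source (phantom families or NIfTI
directories), a :class:`~mamlseg.backbone.BackboneConfig`, a
:class:`~mamlseg.meta.MetaConfig`, preprocessing settings and a master seed.
Key names mirror the published hyperparameter table (``alpha``, ``beta``,
``weight_decay``, ``dropout``, ``batch_size``, ``patience``) so those
settings form a literal preset.  The resolved config is written verbatim
into every run's output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backbone import BackboneConfig
from .meta import MetaConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_META_ALIASES = {"alpha": "inner_lr", "beta": "outer_lr"}


@dataclass
class RunConfig:
    """Fully serializable description of one run."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    meta: MetaConfig = field(default_factory=MetaConfig)
    # phantom data source
    phantom_shape: tuple[int, int, int] = (32, 32, 32)
    n_per_family: int = 30
    holdout_index: int = 3
    shots: int = 5
    n_support: int = 10
    n_query: int = 10
    n_eval: int = 10
    n_test: int = 10
    # NIfTI data source: task name -> directory with images/ and masks/
    task_dirs: dict = field(default_factory=dict)
    # preprocessing
    window_lo: float = -200.0
    window_hi: float = 200.0
    target_shape: tuple[int, int, int] | None = None
    # run control
    output_dir: str = "runs/out"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["backbone"] = asdict(self.backbone)
        d["meta"] = asdict(self.meta)
        return d


def _build_meta(d: dict) -> MetaConfig:
    kwargs = {}
    for k, v in d.items():
        kwargs[_META_ALIASES.get(k, k)] = v
    return MetaConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "backbone" in kwargs:
        b = dict(kwargs.pop("backbone"))
        for key in ("channels", "strides"):
            if key in b:
                b[key] = tuple(b[key])
        kwargs["backbone"] = BackboneConfig(**b)
    if "meta" in kwargs:
        kwargs["meta"] = _build_meta(dict(kwargs.pop("meta")))
    for key in ("phantom_shape", "target_shape"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
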