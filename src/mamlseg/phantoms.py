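"""Synthetic 3D phantom tasks for few-shot segmentation.

Each :class:`PhantomFamily` plays the role of one organ-segmentation task: a
shape family (ellipsoid, lobed blob, or capsule) whose size, elongation and
position vary from sample to sample, rendered into a CT-like intensity volume
(background field + foreground offset + Gaussian texture noise, in
Hounsfield-style units) with a perfectly known binary mask.  After the
standard (-200, 200) intensity window the default contrast sits around
0.35 (background) vs 0.65 (foreground) on the unit scale — a soft-tissue-like
regime chosen so tasks are learnable but not trivial.

Everything is driven by seeds and bitwise reproducible per
``(family, shape, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meta import ExperimentPlan, MetaTestTask, MetaTrainTask, SegTask
from .volume_io import BinaryMask, Volume, window_intensity

__all__ = [
    "PhantomFamily",
    "default_families",
    "render_phantom",
    "make_task",
    "add_gaussian_noise",
    "build_plan",
]

_BASE_SHAPES = ("ellipsoid", "lobed-blob", "capsule")


@dataclass(frozen=True)
class PhantomFamily:
    """One phantom task family; intensities are pre-windowing (HU-like) units.

    ``size_range`` is the structure's characteristic radius as a fraction of
    the smallest volume extent; ``position_jitter`` the centre offset as a
    fraction of the extent.  ``intensity_fg``/``intensity_bg`` are
    (mean, between-sample sd) of the class intensity; ``texture_noise_sd`` is
    the voxel-level Gaussian texture.  The foreground/background means must
    differ by at least twice the pooled intensity sd, so every family is
    learnable by construction.
    """

    name: str
    base_shape: str = "ellipsoid"
    size_range: tuple[float, float] = (0.18, 0.30)
    position_jitter: float = 0.08
    intensity_fg: tuple[float, float] = (60.0, 15.0)
    intensity_bg: tuple[float, float] = (-60.0, 15.0)
    texture_noise_sd: float = 40.0

    def __post_init__(self) -> None:
        if self.base_shape not in _BASE_SHAPES:
            raise ValueError(f"base_shape must be one of {_BASE_SHAPES}")
        lo, hi = self.size_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid size_range {self.size_range}")
        if hi + self.position_jitter >= 0.5:
            raise ValueError(
                f"size_range {self.size_range} + jitter {self.position_jitter} "
                "cannot keep the structure inside the volume")
        pooled = np.sqrt((self.intensity_fg[1] ** 2 + self.intensity_bg[1] ** 2) / 2
                         + self.texture_noise_sd ** 2)
        contrast = abs(self.intensity_fg[0] - self.intensity_bg[0])
        if contrast < 2 * pooled:
            raise ValueError(
                f"family {self.name!r}: fg/bg mean contrast {contrast:.1f} is below "
                f"2x pooled sd {2 * pooled:.1f}; the task would not be learnable "
                "by construction")


def default_families() -> list[PhantomFamily]:
    """Four stand-in task families mirroring a four-organ roster."""
    return [
        PhantomFamily("ellipsoid-large", "ellipsoid", size_range=(0.22, 0.32)),
        PhantomFamily("ellipsoid-small", "ellipsoid", size_range=(0.12, 0.20)),
        PhantomFamily("lobed", "lobed-blob", size_range=(0.16, 0.26)),
        PhantomFamily("capsule", "capsule", size_range=(0.14, 0.24)),
    ]


def _mask_for(family: PhantomFamily, shape: tuple[int, int, int],
              rng: np.random.Generator) -> np.ndarray:
    extent = min(shape)
    lo, hi = family.size_range
    r = rng.uniform(lo, hi) * extent
    centre = np.array(shape) / 2.0 + rng.uniform(
        -family.position_jitter, family.position_jitter, size=3) * extent
    # keep the structure strictly inside a 1-voxel boundary ring
    max_r = min(min(c, s - 1 - c) for c, s in zip(centre, shape)) - 2.0
    if max_r < 2.0:
        raise ValueError(
            f"family {family.name!r}: volume {shape} too small for size_range "
            f"{family.size_range}")
    r = min(r, max_r)
    grid = np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"))

    def ellipsoid(c, semi):
        d = sum(((grid[i] - c[i]) / semi[i]) ** 2 for i in range(3))
        return d <= 1.0

    if family.base_shape == "ellipsoid":
        semi = r * rng.uniform(0.7, 1.0, size=3)
        mask = ellipsoid(centre, semi)
    elif family.base_shape == "lobed-blob":
        semi = r * rng.uniform(0.6, 0.9, size=3)
        mask = ellipsoid(centre, semi)
        for _ in range(rng.integers(2, 4)):
            off = rng.uniform(-0.6, 0.6, size=3) * semi
            lobe_r = r * rng.uniform(0.35, 0.55)
            c2 = np.clip(centre + off, 3.0, np.array(shape) - 4.0)
            lobe_r = min(lobe_r, min(min(c, s - 1 - c) for c, s in zip(c2, shape)) - 2.0)
            if lobe_r > 1.0:
                mask |= ellipsoid(c2, np.full(3, lobe_r))
    else:  # capsule: all voxels within radius of a random axis segment
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        half_len = r * rng.uniform(0.8, 1.2)
        radius = r * rng.uniform(0.35, 0.55)
        # clamp so segment ends + radius stay interior
        for i in range(3):
            room = min(centre[i], shape[i] - 1 - centre[i]) - 2.0
            if abs(axis[i]) * half_len + radius > room:
                half_len = max(0.0, (room - radius) / max(abs(axis[i]), 1e-6))
        rel = grid - centre[:, None, None, None]
        t = np.clip(np.tensordot(axis, rel, axes=1), -half_len, half_len)
        closest = centre[:, None, None, None] + axis[:, None, None, None] * t
        mask = ((grid - closest) ** 2).sum(axis=0) <= radius ** 2
    # enforce the interior invariant exactly
    ring = np.ones(shape, dtype=bool)
    ring[1:-1, 1:-1, 1:-1] = False
    mask = mask & ~ring
    if not mask.any():  # pragma: no cover - excluded by construction
        raise ValueError(f"family {family.name!r}: rendered an empty mask")
    return mask


def render_phantom(family: PhantomFamily, shape: tuple[int, int, int],
                   rng: np.random.Generator | int,
                   spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)
                   ) -> tuple[Volume, BinaryMask]:
    """Render one (volume, mask) pair; deterministic per seed.

    The volume is raw (HU-like) intensity: a background level plus the
    foreground offset on the mask, both drawn per sample, plus voxel-level
    Gaussian texture noise.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    shape = tuple(int(s) for s in shape)
    mask = _mask_for(family, shape, rng)
    bg = rng.normal(*family.intensity_bg)
    fg = rng.normal(*family.intensity_fg)
    data = np.full(shape, bg, dtype=np.float32)
    data[mask] = fg
    data += rng.normal(0.0, family.texture_noise_sd, size=shape).astype(np.float32)
    meta = {"family": family.name}
    vol = Volume(data=data, spacing=spacing, meta=meta)
    return vol, BinaryMask(data=mask.astype(np.uint8), spacing=spacing,
                           affine=vol.affine, meta=dict(meta))


def make_task(family: PhantomFamily, n: int, shape: tuple[int, int, int],
              seed: int, window: bool = True,
              spacing: tuple[float, float, float] = (1.5, 1.5, 1.5)) -> SegTask:
    """A :class:`SegTask` of ``n`` independent seeded renders.

    ``window=True`` (default) applies the standard (-200, 200) intensity
    window so pools feed the training loop directly in the unit range.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seeds = np.random.SeedSequence(seed).spawn(n)
    pool = []
    for i, ss in enumerate(seeds):
        vol, mask = render_phantom(family, shape, np.random.default_rng(ss),
                                   spacing=spacing)
        if window:
            vol = window_intensity(vol)
        vol.meta["case_id"] = f"{family.name}-{i:03d}"
        mask.meta["case_id"] = vol.meta["case_id"]
        pool.append((vol, mask))
    return SegTask(name=family.name, pool=pool)


def add_gaussian_noise(v: Volume, mean: float = 0.0, sd: float = 0.2,
                       rng: np.random.Generator | int | None = None) -> Volume:
    """Corrupt a windowed volume with voxelwise Gaussian noise, re-clipped to [0, 1].

    ``sd`` is on the windowed (unit) intensity scale; masks are untouched.
    """
    if sd < 0:
        raise ValueError(f"noise sd must be >= 0, got {sd}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if sd == 0:
        data = v.data.copy()
    else:
        data = v.data + rng.normal(mean, sd, size=v.data.shape).astype(v.data.dtype)
        data = np.clip(data, 0.0, 1.0)
    return Volume(data=data, spacing=v.spacing, affine=v.affine, meta=dict(v.meta))


def build_plan(families: list[PhantomFamily], holdout_index: int, k: int,
               seed: int, shape: tuple[int, int, int] = (32, 32, 32),
               n_support: int = 10, n_query: int = 10, n_eval: int = 10,
               n_test: int = 10) -> ExperimentPlan:
    """Four-family experiment plan: 3 meta-train tasks, 1 held-out task.

    Mirrors the standard roster: each meta-train task renders
    ``n_support + n_query`` episode images plus ``n_eval`` evaluation images;
    the held-out family renders ``k`` training shots (k in {5, 10}) plus
    ``n_test`` test images.  All renders are independently seeded, so the
    meta-test pool never intersects the meta-train pools.
    """
    if len(families) != 4:
        raise ValueError(f"expected exactly 4 families, got {len(families)}")
    names = [f.name for f in families]
    if len(set(names)) != 4:
        raise ValueError(f"duplicate family names: {names}")
    if not 0 <= holdout_index < 4:
        raise ValueError(f"holdout_index must be in 0..3, got {holdout_index}")
    if k < 1:
        raise ValueError("k must be >= 1")
    task_seeds = np.random.SeedSequence(seed).generate_state(8)
    train_tasks = []
    for j, fam in enumerate(families):
        if j == holdout_index:
            continue
        pool_task = make_task(fam, n_support + n_query, shape,
                              int(task_seeds[2 * j]) % (2 ** 31))
        eval_task = make_task(fam, n_eval, shape,
                              int(task_seeds[2 * j + 1]) % (2 ** 31))
        train_tasks.append(MetaTrainTask(task=pool_task, n_support=n_support,
                                         n_query=n_query,
                                         eval_pairs=eval_task.pool))
    ho = families[holdout_index]
    # fixed-size shot pool so the test set is identical for k = 5 and k = 10
    shot_pool = max(k, 10)
    ho_task = make_task(ho, shot_pool + n_test, shape,
                        int(task_seeds[2 * holdout_index]) % (2 ** 31) + 1)
    meta_test = MetaTestTask(name=ho.name, train_pairs=ho_task.pool[:k],
                             test_pairs=ho_task.pool[shot_pool:])
    return ExperimentPlan(meta_train_tasks=train_tasks, meta_test=meta_test)
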