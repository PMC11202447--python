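"""NIfTI volume I/O and CT-style preprocessing.

Reading, writing, intensity windowing, resizing and one-hot encoding of
single-channel 3D volumes and their binary organ masks.  Conventions:

* arrays are 0-based and keep the axis order of the NIfTI header; no
  reorientation to a canonical (e.g. RAS) frame is performed unless asked for;
* voxel spacing is reported in millimetres;
* intensity windowing clips to ``[lo, hi]`` and rescales linearly to ``[0, 1]``
  (the standard CT soft-tissue window treatment), so a windowed volume is
  always in the unit range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "read_nifti",
    "write_nifti",
    "window_intensity",
    "resize_volume",
    "to_onehot",
]


@dataclass
class Volume:
    """A single-channel 3D scalar field with voxel spacing and affine.

    Parameters
    ----------
    data:
        3D array of intensities.  Arbitrary units before windowing, ``[0, 1]``
        after :func:`window_intensity`.
    spacing:
        Per-axis voxel size in mm, all entries positive.
    affine:
        4x4 voxel-to-world map.  Defaults to ``diag(spacing, 1)``.
    meta:
        Free-form provenance (source path, generator seed, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class BinaryMask:
    """A 3D field over {0, 1} aligned to a :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"BinaryMask data must be 3D, got shape {arr.shape}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be exactly 0 or 1, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


def _load_image(path: str | Path) -> nib.spatialimages.SpatialImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"NIfTI file not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"could not read NIfTI file {path}: {exc}") from exc
    return img


def read_nifti(path: str | Path, *, as_mask: bool = False,
               reorient_ras: bool = False) -> Volume | BinaryMask:
    """Read a NIfTI-1/NIfTI-2 file (optionally ``.gz``) into a :class:`Volume`.

    4D files with singleton trailing axes are squeezed to 3D; more than three
    non-singleton axes raise.  ``as_mask=True`` validates and returns a
    :class:`BinaryMask` instead.  ``reorient_ras=True`` reorients to closest
    canonical (RAS) axes first.
    """
    img = _load_image(path)
    if reorient_ras:
        img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim > 3:
        non_singleton = [n for n in data.shape[3:] if n != 1]
        if non_singleton:
            raise ValueError(
                f"{path}: expected a 3D volume, got shape {data.shape} with "
                f"{3 + len(non_singleton)} non-singleton axes"
            )
        data = data.reshape(data.shape[:3])
    if data.ndim < 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    meta = {"source": str(path)}
    cls = BinaryMask if as_mask else Volume
    return cls(data=np.asarray(data, dtype=np.uint8 if as_mask else np.float32),
               spacing=spacing, affine=np.asarray(img.affine), meta=meta)


def write_nifti(v: Volume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1; round-trips through :func:`read_nifti`."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = v.data
    if isinstance(v, BinaryMask):
        data = data.astype(np.uint8)
    else:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, v.affine)
    img.header.set_zooms(v.spacing)
    try:
        nib.save(img, str(path))
    except OSError as exc:
        raise IOError(f"could not write NIfTI file {path}: {exc}") from exc


def window_intensity(v: Volume, lo: float = -200.0, hi: float = 200.0) -> Volume:
    """Clip intensities to ``[lo, hi]`` and rescale linearly onto ``[0, 1]``.

    The default ``(-200, 200)`` window standardizes CT soft-tissue intensities.
    Monotone non-decreasing; idempotent once the data lie in ``[0, 1]`` and the
    window is ``(0, 1)``.
    """
    if lo >= hi:
        raise ValueError(f"window requires lo < hi, got lo={lo}, hi={hi}")
    data = np.clip(v.data, lo, hi)
    data = (data - lo) / (hi - lo)
    return Volume(data=data.astype(v.data.dtype if np.issubdtype(v.data.dtype, np.floating) else np.float32),
                  spacing=v.spacing, affine=v.affine, meta=dict(v.meta))


def resize_volume(v: Volume | BinaryMask, target_shape: tuple[int, int, int],
                  kind: str | None = None) -> Volume | BinaryMask:
    """Resize to ``target_shape`` voxels, preserving physical extent.

    Images use trilinear interpolation, masks nearest-neighbour (so binarity is
    preserved).  ``kind`` overrides the type-based choice ("image" or "mask").
    Spacing is rescaled so ``shape * spacing`` is unchanged per axis.
    """
    target_shape = tuple(int(t) for t in target_shape)
    if len(target_shape) != 3 or any(t < 1 for t in target_shape):
        raise ValueError(f"target_shape must be 3 positive integers, got {target_shape}")
    if kind is None:
        kind = "mask" if isinstance(v, BinaryMask) else "image"
    if kind not in ("image", "mask"):
        raise ValueError(f"kind must be 'image' or 'mask', got {kind!r}")
    old_shape = v.data.shape
    factors = [t / s for t, s in zip(target_shape, old_shape)]
    order = 0 if kind == "mask" else 1
    if target_shape == old_shape:
        data = v.data.copy()
    else:
        data = ndimage.zoom(v.data.astype(np.float32), factors, order=order,
                            mode="nearest", grid_mode=True)
        # zoom can over/undershoot the target by one voxel on awkward ratios
        data = data[tuple(slice(0, t) for t in target_shape)]
        if data.shape != target_shape:  # pragma: no cover - defensive
            pads = [(0, t - s) for t, s in zip(target_shape, data.shape)]
            data = np.pad(data, pads, mode="edge")
    new_spacing = tuple(sp * o / t for sp, o, t in zip(v.spacing, old_shape, target_shape))
    new_affine = v.affine @ np.diag([o / t for o, t in zip(old_shape, target_shape)] + [1.0])
    if kind == "mask":
        return BinaryMask(data=(data > 0.5).astype(np.uint8), spacing=new_spacing,
                          affine=new_affine, meta=dict(v.meta))
    return Volume(data=data, spacing=new_spacing, affine=new_affine, meta=dict(v.meta))


def to_onehot(m: BinaryMask) -> np.ndarray:
    """Encode a binary mask as a 2-channel field: channel 0 background, 1 foreground.

    Channels sum to one at every voxel.
    """
    data = np.asarray(m.data)
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("to_onehot requires a binary mask")
    fg = data.astype(np.float32)
    return np.stack([1.0 - fg, fg], axis=0)
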