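"""Segmentation loss and evaluation metrics.

Training uses the soft Dice loss on foreground probabilities; evaluation
reports the Dice similarity coefficient (DSC), intersection-over-union (IoU)
and the 95th-percentile Hausdorff distance (HD95) in millimetres, per case
and as means.

Conventions (all configurable nowhere — they define the reported numbers):

* DSC = 2|P∩G| / (|P| + |G|) and IoU = |P∩G| / |P∪G|, both defined as 1 when
  prediction and ground truth are both empty, and 0 when exactly one is empty;
* HD95 is the 95th percentile (linear interpolation) of the *pooled symmetric*
  set of boundary-to-boundary distances, where a boundary voxel is a
  foreground voxel with at least one background face-neighbour (voxels at the
  array edge count as having background outside), and distances are Euclidean
  in physical millimetres via the voxel spacing;
* HD95 is undefined when either mask is empty; such cases are excluded from
  the HD95 mean and counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "CaseMetrics",
    "MetricReport",
    "dice_loss",
    "dice_score",
    "iou",
    "hausdorff95",
    "boundary_voxels",
    "evaluate_case",
    "aggregate",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def _as_binary(arr, name: str) -> np.ndarray:
    data = np.asarray(getattr(arr, "data", arr))
    vals = np.unique(data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:10]}")
    return data.astype(bool)


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice_loss(probs: np.ndarray, target, smooth: float = 1e-5) -> float:
    """Soft Dice loss ``1 - (2 Σ p·g + s) / (Σ p + Σ g + s)``.

    ``probs`` are per-voxel foreground probabilities in [0, 1]; ``target`` a
    binary mask of the same shape.  The smoothing constant is added to both
    numerator and denominator, which also defines the loss on empty masks.
    """
    g = _as_binary(target, "target").astype(np.float64)
    p = np.asarray(probs, dtype=np.float64)
    _check_shapes(p, g)
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    return 1.0 - num / den


def dice_loss_grad(probs: np.ndarray, target, smooth: float = 1e-5
                   ) -> tuple[float, np.ndarray]:
    """Soft Dice loss and its gradient with respect to ``probs``."""
    g = _as_binary(target, "target").astype(np.float64)
    p = np.asarray(probs, dtype=np.float64)
    _check_shapes(p, g)
    num = 2.0 * float((p * g).sum()) + smooth
    den = float(p.sum()) + float(g.sum()) + smooth
    loss = 1.0 - num / den
    # d/dp [num/den] = (2g·den - num) / den^2
    grad = -(2.0 * g * den - num) / (den * den)
    return loss, grad


def dice_score(pred, gt) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    _check_shapes(p, g)
    psum, gsum = int(p.sum()), int(g.sum())
    if psum == 0 and gsum == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / (psum + gsum)


def iou(pred, gt) -> float:
    """Jaccard index |P∩G| / |P∪G|; 1.0 when both masks are empty."""
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    _check_shapes(p, g)
    union = int((p | g).sum())
    if union == 0:
        return 1.0
    return int((p & g).sum()) / union


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (n, 3) of foreground voxels with a background face-neighbour."""
    eroded = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff95(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of pooled symmetric boundary distances, in mm.

    Returns ``nan`` (the undefined-metric signal) when either mask is empty.
    """
    p = _as_binary(pred, "pred")
    g = _as_binary(gt, "gt")
    _check_shapes(p, g)
    sp_p = getattr(pred, "spacing", None)
    sp_g = getattr(gt, "spacing", None)
    if sp_p is not None and sp_g is not None and tuple(sp_p) != tuple(sp_g):
        raise ValueError(f"spacing mismatch: {sp_p} vs {sp_g}")
    spacing = np.asarray(sp_p if sp_p is not None else spacing, dtype=float)
    if not p.any() or not g.any():
        return float("nan")
    bp = boundary_voxels(p) * spacing
    bg = boundary_voxels(g) * spacing
    d_pg = cKDTree(bg).query(bp)[0]
    d_gp = cKDTree(bp).query(bg)[0]
    pooled = np.concatenate([d_pg, d_gp])
    return float(np.percentile(pooled, 95))


@dataclass
class CaseMetrics:
    case_id: str
    dsc: float
    iou: float
    hd95: float  # nan when undefined


@dataclass
class MetricReport:
    """Per-case metrics plus arithmetic means (HD95 over defined cases only)."""

    per_case: list[CaseMetrics]
    means: dict = field(default_factory=dict)
    n_hd95_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"case_id": c.case_id, "dsc": c.dsc, "iou": c.iou, "hd95": c.hd95}
             for c in self.per_case])

    def to_csv(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {"means": self.means, "n_cases": len(self.per_case),
                   "n_hd95_excluded": self.n_hd95_excluded}
        Path(path).write_text(json.dumps(payload, indent=2))


def evaluate_case(case_id: str, pred, gt, spacing=(1.0, 1.0, 1.0)) -> CaseMetrics:
    return CaseMetrics(case_id=case_id,
                       dsc=dice_score(pred, gt),
                       iou=iou(pred, gt),
                       hd95=hausdorff95(pred, gt, spacing))


def aggregate(cases: list[CaseMetrics]) -> MetricReport:
    """Combine per-case metrics into a report with means.

    Cases with undefined (nan) HD95 are excluded from the HD95 mean; their
    count is recorded in ``n_hd95_excluded``.
    """
    if not cases:
        raise ValueError("aggregate requires at least one case")
    dscs = [c.dsc for c in cases]
    ious = [c.iou for c in cases]
    hds = [c.hd95 for c in cases if np.isfinite(c.hd95)]
    n_excl = len(cases) - len(hds)
    means = {
        "dsc": float(np.mean(dscs)),
        "iou": float(np.mean(ious)),
        "hd95": float(np.mean(hds)) if hds else float("nan"),
    }
    return MetricReport(per_case=list(cases), means=means, n_hd95_excluded=n_excl)
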