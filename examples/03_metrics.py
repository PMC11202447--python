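"""Segmentation metrics: DSC, IoU and the 95% Hausdorff distance in mm.

Two overlapping spheres stand in for a prediction and its ground truth; the
spacing turns voxel offsets into millimetres.
"""

import numpy as np

from mamlseg import BinaryMask, dice_score, hausdorff95, iou
from mamlseg.metrics import aggregate, evaluate_case


def sphere(center, radius, shape=(32, 32, 32), spacing=(1.5, 1.5, 1.5)):
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"))
    d2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return BinaryMask(data=(d2 <= radius ** 2).astype(np.uint8), spacing=spacing)


gt = sphere((16, 16, 16), 8)
pred = sphere((18, 16, 16), 8)   # prediction shifted by 2 voxels (3 mm)

print(f"DSC  = {dice_score(pred, gt):.4f}   (overlap; 1 = perfect)")
print(f"IoU  = {iou(pred, gt):.4f}   (Jaccard; DSC = 2*IoU/(1+IoU))")
print(f"HD95 = {hausdorff95(pred, gt):.2f} mm (95th pct of boundary distances)")

report = aggregate([
    evaluate_case("shift-2", pred, gt, spacing=gt.spacing),
    evaluate_case("perfect", gt, gt, spacing=gt.spacing),
])
print("aggregate means over 2 cases:", {k: round(v, 4) for k, v in report.means.items()})
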