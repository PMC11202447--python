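"""Generate a synthetic phantom segmentation task and export it as NIfTI.

Each phantom family mimics one organ-segmentation task: a 3D structure whose
shape, size and position vary between samples, embedded in a CT-like
intensity field with texture noise, plus a perfect binary mask.
"""

import numpy as np

from mamlseg import default_families, make_task, render_phantom, write_nifti

family = default_families()[0]
print(f"family: {family.name} ({family.base_shape})")
print(f"  fg intensity {family.intensity_fg} HU, bg {family.intensity_bg} HU, "
      f"texture sd {family.texture_noise_sd} HU")

# one raw (unwindowed) render
vol, mask = render_phantom(family, (32, 32, 32), rng=0)
inside = vol.data[mask.data.astype(bool)]
outside = vol.data[~mask.data.astype(bool)]
print(f"one render: {int(mask.data.sum())} foreground voxels, "
      f"contrast {inside.mean() - outside.mean():.1f} HU "
      f"(inside {inside.mean():.1f}, outside {outside.mean():.1f})")

# a task pool of 5 windowed pairs, exported to disk
task = make_task(family, n=5, shape=(32, 32, 32), seed=7)
for i, (v, m) in enumerate(task.pool):
    write_nifti(v, f"scratch_phantoms/images/{v.meta['case_id']}.nii.gz")
    write_nifti(m, f"scratch_phantoms/masks/{v.meta['case_id']}.nii.gz")
sizes = [int(m.data.sum()) for _, m in task.pool]
print(f"task pool of {len(task.pool)}: windowed intensities in "
      f"[{task.pool[0][0].data.min():.2f}, {task.pool[0][0].data.max():.2f}], "
      f"mask sizes {sizes} voxels (inter-subject variability)")
print("wrote NIfTI tree under scratch_phantoms/")
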