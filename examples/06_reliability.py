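"""Segmentation-reliability metrics on repeated (perturbed) segmentations.

Five noisy repetitions of the same cortical mask are compared pairwise
with the Dice coefficient (>= 70% indicates good overlap) and the modified
Hausdorff distance on boundary-voxel centres.
"""
import numpy as np
from scipy import ndimage

from msbmap import PhantomSpec, generate_phantom, pairwise_reliability

phantom = generate_phantom(PhantomSpec(), seed=1, with_volume=True)
base = phantom.volume.mask("cortical")

rng = np.random.default_rng(0)
repetitions = [base]
for _ in range(4):
    surface = base & ~ndimage.binary_erosion(base)
    nibble = surface & (rng.random(base.shape) < 0.05)
    repetitions.append(base & ~nibble)

table, summary = pairwise_reliability(repetitions,
                                      spacing=phantom.volume.spacing)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"\nDice range: {100 * summary['dice_min']:.1f}-"
      f"{100 * summary['dice_max']:.1f}% "
      f"(all above 70%: {summary['all_dice_good']})")
print(f"modified Hausdorff: median {summary['hd_median_mm']:.3f} mm, "
      f"range {summary['hd_min_mm']:.3f}-{summary['hd_max_mm']:.3f} mm")
# Surface nibbling of a few percent leaves Dice near 1 and HD well below
# the voxel size — the scale on which repeated human segmentations of the
# same scan are expected to differ.
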