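"""Refine a rough trauma contour with the 3D Chan-Vese active contour.

A hypodense sphere inside bright parenchyma stands in for a lesion; the
initial mask is the sphere eroded by two voxels.  The sparse-field evolution
recovers the full sphere, and the printed energy trace decreases
monotonically — each sweep only accepts energy-lowering moves.
"""

import numpy as np
from scipy import ndimage

import ltq

shape = (32, 48, 48)
zz, yy, xx = np.ogrid[tuple(slice(0, n) for n in shape)]
sphere = ((zz - 16) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2) <= 10**2
volume = ltq.CTVolume(np.where(sphere, 60.0, 110.0), (1.5, 1.0, 1.0))
liver = ltq.BinaryMask(np.ones(shape, bool), volume.spacing_mm, role="liver")
init = ltq.BinaryMask(
    ndimage.binary_erosion(sphere, iterations=2), volume.spacing_mm, role="trauma"
)

mask, state = ltq.evolve_chan_vese(
    volume, init, liver, ltq.ChanVeseParams(nu=0.0), return_state=True
)

inter = np.count_nonzero(mask.data & sphere)
dice = 2 * inter / (mask.count() + int(sphere.sum()))
print(f"init voxels: {init.count()}   true sphere: {int(sphere.sum())}"
      f"   recovered: {mask.count()}")
print(f"Dice vs true sphere: {dice:.4f}   (1.0 = exact recovery)")
print(f"region means s1 (inside) / s2 (outside): {state.s1:.3f} / {state.s2:.3f}")
print("energy trace:", "  ".join(f"{e:.1f}" for e in state.energy_trace))
print("the trace never increases: each sweep is an exact discrete descent "
      "of the region-based energy")
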