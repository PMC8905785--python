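"""Morphological refinement of the initial liver mask.

The refinement chain is: 3D Gaussian smoothing of the binary field (isotropic
in physical space), removal of small sparse regions, per-slice axial hole
filling, and selection of the largest 3D connected component — yielding a
spatially coherent, single-component liver segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask

__all__ = [
    "LiverPostprocessParams",
    "smooth_mask",
    "remove_small_regions",
    "fill_axial_holes",
    "keep_largest_component",
    "postprocess_liver",
]


@dataclass(frozen=True)
class LiverPostprocessParams:
    """Knobs of the liver refinement chain.

    ``gaussian_sigma_mm`` is the smoothing scale in millimetres (applied
    per-axis as sigma/spacing voxels so the kernel is isotropic in physical
    space); ``min_region_voxels`` drops components smaller than that count;
    ``connectivity`` is the 3D neighbourhood (6, 18 or 26) used for
    component labelling.
    """

    gaussian_sigma_mm: float = 2.0
    min_region_voxels: int = 64
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.gaussian_sigma_mm < 0:
            raise ValueError("gaussian_sigma_mm must be >= 0")
        if self.min_region_voxels < 0:
            raise ValueError("min_region_voxels must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    return ndimage.generate_binary_structure(3, rank)


def smooth_mask(mask: BinaryMask, sigma_mm: float) -> BinaryMask:
    """Gaussian-smooth the 0/1 indicator field and re-threshold at 0.5.

    ``sigma_mm`` is divided by the per-axis spacing, so smoothing is
    isotropic in physical space; ``sigma_mm == 0`` is the identity.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return mask.with_data(mask.data.copy())
    sigma_vox = [sigma_mm / s for s in mask.spacing_mm]
    blurred = ndimage.gaussian_filter(mask.data.astype(np.float64), sigma=sigma_vox)
    return mask.with_data(blurred >= 0.5)


def remove_small_regions(mask: BinaryMask, min_voxels: int, connectivity: int = 26) -> BinaryMask:
    """Drop connected components with fewer than ``min_voxels`` voxels."""
    if min_voxels <= 1 or not mask.data.any():
        return mask.with_data(mask.data.copy())
    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    if n == 0:
        return mask.with_data(mask.data.copy())
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return mask.with_data(keep[labels])


def fill_axial_holes(mask: BinaryMask) -> BinaryMask:
    """Fill 2D holes slice by slice in the axial plane.

    A hole is background not connected to the border of its own slice.  The
    operation only ever adds voxels and is idempotent.
    """
    out = mask.data.copy()
    for z in range(out.shape[0]):
        if out[z].any():
            out[z] = ndimage.binary_fill_holes(out[z])
    return mask.with_data(out)


def keep_largest_component(mask: BinaryMask, connectivity: int = 26) -> BinaryMask:
    """Keep only the largest 3D connected component (empty input stays empty).

    Size ties are broken toward the component containing the lexicographically
    smallest (z, y, x) voxel.
    """
    if not mask.data.any():
        return mask.with_data(mask.data.copy())
    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    if n == 1:
        return mask.with_data(mask.data.copy())
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = set(np.flatnonzero(sizes == best).tolist())
    if len(candidates) == 1:
        chosen = candidates.pop()
    else:
        flat = labels.ravel()  # C order == lexicographic (z, y, x)
        chosen = next(int(lab) for lab in flat if lab in candidates)
    return mask.with_data(labels == chosen)


def postprocess_liver(mask: BinaryMask, params: LiverPostprocessParams | None = None) -> BinaryMask:
    """Full liver refinement: smooth, drop small regions, fill axial holes,
    keep the largest component.  The result has at most one component."""
    p = params or LiverPostprocessParams()
    out = smooth_mask(mask, p.gaussian_sigma_mm)
    out = remove_small_regions(out, p.min_region_voxels, p.connectivity)
    out = fill_axial_holes(out)
    out = keep_largest_component(out, p.connectivity)
    out.role = mask.role
    return out
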