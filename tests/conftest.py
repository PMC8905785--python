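"""Shared fixtures and oracle helpers for the test suite.

The brute-force helpers here recompute quantities by direct enumeration
(python loops over voxels), independent of the library's vectorised paths,
and serve as oracles in the metric and energy tests.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

import ltq


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_metrics(s: np.ndarray, gt: np.ndarray) -> dict:
    """Dice/recall/precision/RVD/VOE by explicit voxel enumeration."""
    n_s = n_gt = inter = union = 0
    for idx in np.ndindex(s.shape):
        a, b = bool(s[idx]), bool(gt[idx])
        n_s += a
        n_gt += b
        inter += a and b
        union += a or b
    return dict(
        dice=2 * inter / (n_s + n_gt) if (n_s + n_gt) else float("nan"),
        recall=inter / n_gt if n_gt else float("nan"),
        precision=inter / n_s if n_s else 0.0,
        rvd=(n_s - n_gt) / n_gt if n_gt else float("nan"),
        voe=1 - inter / union if union else float("nan"),
    )


def brute_force_energy(vol, inside, s1, s2, mu, nu, lam1, lam2, spacing):
    """Discrete Chan-Vese energy by explicit summation (full-grid outside)."""
    sz, sy, sx = spacing
    vox = sz * sy * sx
    fa = {0: sy * sx, 1: sz * sx, 2: sz * sy}
    area = 0.0
    shape = inside.shape
    for idx in np.ndindex(shape):
        if not inside[idx]:
            continue
        for axis in range(3):
            for d in (-1, 1):
                nb = list(idx)
                nb[axis] += d
                if not (0 <= nb[axis] < shape[axis]) or not inside[tuple(nb)]:
                    area += fa[axis]
    e = mu * area + nu * inside.sum() * vox
    e += lam1 * float(((vol[inside] - s1) ** 2).sum()) * vox
    out = ~inside
    e += lam2 * float(((vol[out] - s2) ** 2).sum()) * vox
    return e


# ---------------------------------------------------------------------------
# phantom and candidate-injection helpers
# ---------------------------------------------------------------------------

SMALL_SPEC = ltq.PhantomSpec(grid_shape=(32, 48, 48), spacing_mm=(3.0, 2.0, 2.0))


def small_phantom(seed: int, ldi: float = 0.0, confounder: str = "none"):
    from dataclasses import replace

    return ltq.generate_phantom(
        replace(SMALL_SPEC, seed=seed, target_ldi_pct=ldi, confounder=confounder)
    )


def inject_texture_candidates(sample, rng, n_blobs: int = 3, radius: int = 3):
    """Spherical false candidates of normal organ texture inside the liver."""
    interior = ndimage.binary_erosion(sample.liver_gt.data, iterations=radius + 1)
    pool = np.argwhere(interior if interior.any() else sample.liver_gt.data)
    init = np.zeros(sample.liver_gt.shape, dtype=bool)
    zz, yy, xx = np.ogrid[tuple(slice(0, n) for n in init.shape)]
    for _ in range(n_blobs):
        c = pool[rng.integers(len(pool))]
        init |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= radius**2
    return ltq.BinaryMask(
        init & sample.liver_gt.data, sample.spec.spacing_mm, role="trauma"
    )


def random_mask(rng, shape=(12, 12, 12), p=0.2, spacing=(1.0, 1.0, 1.0)):
    return ltq.BinaryMask(rng.random(shape) < p, spacing, role="liver")


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture(scope="session")
def trauma_phantom():
    """One mid-severity trauma phantom shared across read-only tests."""
    return small_phantom(seed=42, ldi=15.0)
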