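"""Seeded synthetic CT phantoms with paired liver and trauma ground truth.

Each phantom emulates a portal-venous-phase abdominal CT around the liver: a
large, smooth, single-component organ of roughly uniform enhancement sitting
in a darker background, optionally disrupted by irregular hypodense trauma
blobs that occupy a prescribed fraction of the organ (the target LDI).
Confounders reproduce the pre-existing conditions and artifacts that make
trauma detection hard in practice:

``fatty``
    diffuse low attenuation — the whole organ mean is lowered, no trauma added;
``congestive``
    heterogeneous enhancement — a smooth random field modulates the organ;
``streak``
    a dark planar band crossing the volume, as beam hardening would produce.

The organ is the union of 2-3 overlapping ellipsoids with a smoothed
boundary; trauma blobs are grown by randomised (Eden-type) accretion from a
random-walk spine, which yields connected, irregular regions whose voxel
count hits the LDI target exactly (to rounding).  One master seed fully
determines a sample; cohorts derive per-sample seeds as ``seed + index``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, CTVolume

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PhantomGeometryError",
    "generate_phantom",
    "generate_cohort",
    "CONFOUNDERS",
]

CONFOUNDERS = ("none", "fatty", "congestive", "streak")

#: Organ mean shift applied by the fatty-liver confounder (HU).
FATTY_SHIFT_HU = -30.0
#: Standard deviation of the smooth congestive-heterogeneity field (HU).
CONGESTIVE_SD_HU = 12.0
#: Depth and half-width (voxels) of the streak-artifact band.
STREAK_DEPTH_HU = 30.0
STREAK_HALF_WIDTH = 1.5


class PhantomGeometryError(RuntimeError):
    """Target trauma burden is unreachable inside the generated organ."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic phantom.

    Intensity defaults are HU-like and portal-venous plausible: enhanced
    parenchyma ~110 HU, hypodense laceration/hematoma ~60 HU, non-organ
    background ~40 HU, additive Gaussian noise sd 10 HU.
    """

    grid_shape: tuple[int, int, int] = (48, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 1.5, 1.5)
    liver_hu: float = 110.0
    background_hu: float = 40.0
    trauma_hu: float = 60.0
    noise_sd: float = 10.0
    target_ldi_pct: float = 0.0
    confounder: str = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trauma_hu >= self.liver_hu:
            raise ValueError(
                f"trauma_hu ({self.trauma_hu}) must be < liver_hu ({self.liver_hu}): "
                "trauma is hypodense relative to parenchyma"
            )
        if not (0.0 <= self.target_ldi_pct <= 60.0):
            raise ValueError(f"target_ldi_pct must be in [0, 60], got {self.target_ldi_pct}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"all spacings must be > 0, got {self.spacing_mm}")
        if self.confounder not in CONFOUNDERS:
            raise ValueError(
                f"confounder {self.confounder!r} not one of {CONFOUNDERS}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class PhantomSample:
    """A generated phantom: volume, ground-truth masks, and the exact LDI."""

    volume: CTVolume
    liver_gt: BinaryMask
    trauma_gt: BinaryMask
    true_ldi_pct: float
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# organ geometry
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _make_organ(shape, rng: np.random.Generator) -> np.ndarray:
    nz, ny, nx = shape
    n_ellipsoids = int(rng.integers(2, 4))
    mask = np.zeros(shape, dtype=bool)
    base_center = np.array([nz / 2, ny / 2, nx / 2])
    base_axes = np.array([nz * 0.32, ny * 0.33, nx * 0.33])
    for k in range(n_ellipsoids):
        jitter = rng.uniform(-0.10, 0.10, size=3) * np.array(shape)
        scale = rng.uniform(0.6, 1.0, size=3)
        mask |= _ellipsoid(shape, base_center + jitter, np.maximum(base_axes * scale, 3.0))
    smoothed = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.5)
    organ = smoothed >= 0.5
    # enforce a single 26-connected component
    labels, n = ndimage.label(organ, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        organ = labels == (1 + int(np.argmax(sizes)))
    organ = ndimage.binary_fill_holes(organ)
    return organ


# ---------------------------------------------------------------------------
# trauma growth
# ---------------------------------------------------------------------------

_NEIGHBORS6 = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _eden_growth(organ: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """Grow a connected blob of exactly ``n_target`` voxels inside the organ.

    A short random walk lays down a spine; randomised accretion (each frontier
    voxel carries an i.i.d. priority) then inflates it, which produces
    non-convex, irregular shapes.
    """
    interior = ndimage.binary_erosion(organ, iterations=2)
    seed_pool = np.argwhere(interior if interior.any() else organ)
    start = seed_pool[rng.integers(len(seed_pool))]

    shape = organ.shape
    trauma = np.zeros(shape, dtype=bool)
    frontier: list[tuple[float, tuple[int, int, int]]] = []
    count = 0

    def push(v):
        heapq.heappush(frontier, (float(rng.random()), (int(v[0]), int(v[1]), int(v[2]))))

    # random-walk spine, biased to stay put inside the organ
    pos = start.copy()
    spine = [tuple(int(c) for c in pos)]
    for _ in range(max(8, n_target // 25)):
        step = _NEIGHBORS6[rng.integers(6)]
        cand = pos + step
        if (cand >= 0).all() and (cand < shape).all() and organ[tuple(cand)]:
            pos = cand
            spine.append(tuple(int(c) for c in pos))
    for v in spine:
        if count >= n_target:
            break
        if not trauma[v]:
            trauma[v] = True
            count += 1
            for d in _NEIGHBORS6:
                w = np.array(v) + d
                if (w >= 0).all() and (w < shape).all() and organ[tuple(w)] and not trauma[tuple(w)]:
                    push(w)

    while count < n_target:
        if not frontier:
            raise PhantomGeometryError(
                f"cannot reach {n_target} trauma voxels inside the organ "
                f"(grew {count} before the frontier emptied)"
            )
        _, v = heapq.heappop(frontier)
        if trauma[v]:
            continue
        trauma[v] = True
        count += 1
        for d in _NEIGHBORS6:
            w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
            if (
                0 <= w[0] < shape[0]
                and 0 <= w[1] < shape[1]
                and 0 <= w[2] < shape[2]
                and organ[w]
                and not trauma[w]
            ):
                push(np.array(w))
    return trauma


def _grow_trauma(organ: np.ndarray, n_target: int, rng: np.random.Generator) -> np.ndarray:
    """An irregular but macroscopically smooth trauma region of exactly
    ``n_target`` voxels.

    Raw accretion growth is rough at the voxel scale, which real lacerations
    are not; so an oversized blob is grown first, its indicator smoothed, and
    the ``n_target`` highest-scoring organ voxels kept (deterministic index
    tie-break).  If that superlevel set splits, the largest piece is kept and
    regrown to the exact count by score-ordered accretion.
    """
    organ_count = int(organ.sum())
    n_over = min(organ_count, int(n_target * 1.3) + 24)
    rough = _eden_growth(organ, n_over, rng)
    score = ndimage.gaussian_filter(rough.astype(np.float64), sigma=1.2)
    score[~organ] = -np.inf

    flat_order = np.lexsort((np.arange(score.size), -score.ravel()))
    chosen = flat_order[:n_target]
    trauma = np.zeros(organ.shape, dtype=bool)
    trauma.ravel()[chosen] = True

    labels, n = ndimage.label(trauma, structure=np.ones((3, 3, 3), dtype=bool))
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        trauma = labels == int(np.argmax(sizes))
        count = int(trauma.sum())
        frontier: list[tuple[float, int]] = []
        flat_score = score.ravel()
        flat_trauma = trauma.ravel()
        strides = (organ.shape[1] * organ.shape[2], organ.shape[2], 1)

        def neighbours(f):
            z, rem = divmod(f, strides[0])
            y, x = divmod(rem, strides[1])
            for d in _NEIGHBORS6:
                w = (z + d[0], y + d[1], x + d[2])
                if all(0 <= w[a] < organ.shape[a] for a in range(3)):
                    yield w[0] * strides[0] + w[1] * strides[1] + w[2]

        for f in np.flatnonzero(flat_trauma):
            for g in neighbours(int(f)):
                if organ.ravel()[g] and not flat_trauma[g]:
                    heapq.heappush(frontier, (-flat_score[g], g))
        while count < n_target:
            if not frontier:
                raise PhantomGeometryError(
                    f"cannot reach {n_target} trauma voxels inside the organ"
                )
            _, g = heapq.heappop(frontier)
            if flat_trauma[g]:
                continue
            flat_trauma[g] = True
            count += 1
            for h in neighbours(g):
                if organ.ravel()[h] and not flat_trauma[h]:
                    heapq.heappush(frontier, (-flat_score[h], h))
        trauma = flat_trauma.reshape(organ.shape)
    return trauma


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom; identical spec (incl. seed) gives bit-identical output.

    The emitted ``true_ldi_pct`` is the exact voxel-count ratio and lies
    within 0.5 absolute percentage points of ``spec.target_ldi_pct``.
    """
    # independent deterministic streams so confounder choice never shifts
    # organ geometry or noise
    ss = np.random.SeedSequence(spec.seed)
    rng_organ, rng_trauma, rng_conf, rng_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )

    organ = _make_organ(spec.grid_shape, rng_organ)
    organ_count = int(organ.sum())
    if organ_count < 200:
        raise PhantomGeometryError(f"degenerate organ of only {organ_count} voxels")

    n_target = int(round(spec.target_ldi_pct / 100.0 * organ_count))
    if n_target > 0:
        trauma = _grow_trauma(organ, n_target, rng_trauma)
    else:
        trauma = np.zeros(spec.grid_shape, dtype=bool)
    true_ldi = 100.0 * trauma.sum() / organ_count

    liver_level = spec.liver_hu + (FATTY_SHIFT_HU if spec.confounder == "fatty" else 0.0)
    vol = np.full(spec.grid_shape, spec.background_hu, dtype=np.float64)
    vol[organ] = liver_level
    vol[trauma] = spec.trauma_hu

    if spec.confounder == "congestive":
        rough = rng_conf.standard_normal(spec.grid_shape)
        smooth = ndimage.gaussian_filter(rough, sigma=4.0)
        sd = smooth.std()
        if sd > 0:
            field3d = smooth * (CONGESTIVE_SD_HU / sd)
            vol[organ & ~trauma] += field3d[organ & ~trauma]
    elif spec.confounder == "streak":
        normal = rng_conf.standard_normal(3)
        normal /= np.linalg.norm(normal)
        center = np.array(spec.grid_shape) / 2.0
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in spec.grid_shape), indexing="ij")
        dist = (
            (zz - center[0]) * normal[0]
            + (yy - center[1]) * normal[1]
            + (xx - center[2]) * normal[2]
        )
        vol[np.abs(dist) < STREAK_HALF_WIDTH] -= STREAK_DEPTH_HU

    # soften organ/lesion boundaries a touch, as partial-volume blur would
    vol = ndimage.gaussian_filter(vol, sigma=0.8)
    if spec.noise_sd > 0:
        vol += rng_noise.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    source = f"phantom(seed={spec.seed},ldi={spec.target_ldi_pct},conf={spec.confounder})"
    return PhantomSample(
        volume=CTVolume(data=vol, spacing_mm=spec.spacing_mm, source_id=source),
        liver_gt=BinaryMask(organ, spec.spacing_mm, role="ground_truth_liver"),
        trauma_gt=BinaryMask(trauma, spec.spacing_mm, role="ground_truth_trauma"),
        true_ldi_pct=float(true_ldi),
        spec=spec,
    )


def generate_cohort(
    n: int,
    ldi_levels: list[float],
    confounder_mix: dict[str, float] | None = None,
    seed: int = 0,
    base_spec: PhantomSpec | None = None,
) -> list[PhantomSample]:
    """Generate ``n`` phantoms cycling deterministically through conditions.

    Sample ``i`` receives LDI level ``ldi_levels[i % len(ldi_levels)]`` and a
    seed of ``seed + i``.  Confounder counts follow ``confounder_mix``
    proportions by largest remainder (insertion order breaks ties), and the
    resulting multiset is dealt to samples in sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not ldi_levels:
        raise ValueError("ldi_levels must be non-empty")
    if confounder_mix is None:
        confounder_mix = {"none": 1.0}
    for name in confounder_mix:
        if name not in CONFOUNDERS:
            raise ValueError(f"unknown confounder {name!r}")
    total = sum(confounder_mix.values())
    if total <= 0:
        raise ValueError("confounder_mix proportions must sum to a positive value")

    quotas = {k: n * v / total for k, v in confounder_mix.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    leftover = n - sum(counts.values())
    by_remainder = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_remainder[:leftover]:
        counts[k] += 1
    conf_seq = [name for name in confounder_mix for _ in range(counts[name])]

    base = base_spec if base_spec is not None else PhantomSpec()
    samples = []
    for i in range(n):
        spec = replace(
            base,
            target_ldi_pct=float(ldi_levels[i % len(ldi_levels)]),
            confounder=conf_seq[i],
            seed=seed + i,
        )
        samples.append(generate_phantom(spec))
    return samples
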