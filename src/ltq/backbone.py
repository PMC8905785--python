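"""Slice-wise U-net segmentation backbone.

Axial CT slices are segmented independently by a compact encoder-decoder
convolutional network with skip connections (the U-net topology: per level a
3x3 conv + ReLU, 2x average-pool downsampling; nearest-neighbour upsampling
with skip concatenation on the way back up; a 1x1 sigmoid head).  Per-slice
probability maps are restacked into a 3D :class:`ProbabilityMap` on the
input lattice.

The network is implemented in pure numpy (see :mod:`ltq._nn`) with
hand-derived gradients, BCE + soft-Dice loss, and Adam — small enough to
train on a CPU in seconds and bit-reproducible under a fixed seed.  Every
downstream stage accepts any probability map or mask, so tests and
experiments can bypass training entirely and inject oracle or perturbed
masks instead.

Intensities are normalised by windowing to [-100, 300] HU and scaling to
[0, 1] before entering the network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize

from . import _nn
from .core import BinaryMask, CTVolume

__all__ = [
    "BackboneConfig",
    "ProbabilityMap",
    "BackboneHandle",
    "train_backbone",
    "predict",
    "binarize",
    "save_backbone",
    "load_backbone",
]

_HU_WINDOW = (-100.0, 300.0)


@dataclass(frozen=True)
class BackboneConfig:
    """Architecture, optimisation and augmentation settings for one task.

    ``depth`` counts downsampling levels (>= 2); channel width doubles per
    level starting from ``base_channels``.  ``input_size`` is the in-plane
    size slices are resampled to (must be divisible by ``2**depth``).
    Augmentation ranges follow the usual rotate/re-scale/translate recipe.
    """

    depth: int = 4
    base_channels: int = 16
    input_size: int = 64
    epochs: int = 10
    batch_size: int = 8
    learning_rate: float = 3e-3
    augmentation: dict = field(
        default_factory=lambda: {
            "rotation_deg": 10.0,
            "scale_range": 0.1,
            "translation_px": 4.0,
        }
    )
    seed: int = 0
    task: str = "liver"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth={2**self.depth}"
            )
        if self.task not in ("liver", "trauma"):
            raise ValueError("task must be 'liver' or 'trauma'")
        if any(v < 0 for v in self.augmentation.values()):
            raise ValueError("augmentation ranges must be non-negative")


@dataclass
class ProbabilityMap:
    """Per-voxel foreground probabilities on the lattice of the input volume."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    task: str = "liver"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < 0.0 or self.data.max() > 1.0:
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def shape(self):
        return self.data.shape


def normalize_hu(data: np.ndarray) -> np.ndarray:
    lo, hi = _HU_WINDOW
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _channels(cfg: BackboneConfig) -> list[int]:
    return [cfg.base_channels * 2**i for i in range(cfg.depth + 1)]


def _init_params(cfg: BackboneConfig) -> dict:
    rng = np.random.default_rng(cfg.seed)
    ch = _channels(cfg)
    params: dict[str, np.ndarray] = {}
    c_in = 1
    for i in range(cfg.depth):
        params[f"enc{i}_W"] = _nn.he_init(rng, (ch[i], c_in, 3, 3), c_in * 9)
        params[f"enc{i}_b"] = np.zeros(ch[i])
        c_in = ch[i]
    params["bott_W"] = _nn.he_init(rng, (ch[cfg.depth], c_in, 3, 3), c_in * 9)
    params["bott_b"] = np.zeros(ch[cfg.depth])
    for i in reversed(range(cfg.depth)):
        c_cat = ch[i + 1] + ch[i]
        params[f"dec{i}_W"] = _nn.he_init(rng, (ch[i], c_cat, 3, 3), c_cat * 9)
        params[f"dec{i}_b"] = np.zeros(ch[i])
    params["head_W"] = _nn.he_init(rng, (1, ch[0]), ch[0])
    params["head_b"] = np.zeros(1)
    return params


def _forward(params: dict, cfg: BackboneConfig, X: np.ndarray):
    """X (N,1,S,S) -> logits (N,1,S,S) with a cache for backprop."""
    cache: dict = {}
    cur = X
    for i in range(cfg.depth):
        z, cache[f"enc{i}_conv"] = _nn.conv3_forward(
            cur, params[f"enc{i}_W"], params[f"enc{i}_b"]
        )
        a, cache[f"enc{i}_relu"] = _nn.relu_forward(z)
        cache[f"skip{i}"] = a
        cur, cache[f"pool{i}"] = _nn.avgpool2_forward(a)
    z, cache["bott_conv"] = _nn.conv3_forward(cur, params["bott_W"], params["bott_b"])
    cur, cache["bott_relu"] = _nn.relu_forward(z)
    for i in reversed(range(cfg.depth)):
        up, cache[f"up{i}"] = _nn.upsample2_forward(cur)
        cat = np.concatenate([up, cache[f"skip{i}"]], axis=1)
        cache[f"cat{i}_split"] = up.shape[1]
        z, cache[f"dec{i}_conv"] = _nn.conv3_forward(
            cat, params[f"dec{i}_W"], params[f"dec{i}_b"]
        )
        cur, cache[f"dec{i}_relu"] = _nn.relu_forward(z)
    logits, cache["head"] = _nn.conv1_forward(cur, params["head_W"], params["head_b"])
    return logits, cache


def _backward(params: dict, cfg: BackboneConfig, cache: dict, dLogits: np.ndarray) -> dict:
    grads: dict[str, np.ndarray] = {}
    grads["head_W"], grads["head_b"], d = _nn.conv1_backward(
        dLogits, params["head_W"], cache["head"]
    )
    dskip = {}
    for i in range(cfg.depth):
        d = _nn.relu_backward(d, cache[f"dec{i}_relu"])
        grads[f"dec{i}_W"], grads[f"dec{i}_b"], dcat = _nn.conv3_backward(
            d, params[f"dec{i}_W"], cache[f"dec{i}_conv"]
        )
        split = cache[f"cat{i}_split"]
        dup, dskip[i] = dcat[:, :split], dcat[:, split:]
        d = _nn.upsample2_backward(dup, cache[f"up{i}"])
    d = _nn.relu_backward(d, cache["bott_relu"])
    grads["bott_W"], grads["bott_b"], d = _nn.conv3_backward(
        d, params["bott_W"], cache["bott_conv"]
    )
    for i in reversed(range(cfg.depth)):
        d = _nn.avgpool2_backward(d, cache[f"pool{i}"])
        d = d + dskip[i]
        d = _nn.relu_backward(d, cache[f"enc{i}_relu"])
        grads[f"enc{i}_W"], grads[f"enc{i}_b"], d = _nn.conv3_backward(
            d, params[f"enc{i}_W"], cache[f"enc{i}_conv"]
        )
    return grads


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class BackboneHandle:
    """A trained segmenter: parameters, its config, and the training history."""

    params: dict
    cfg: BackboneConfig
    history: pd.DataFrame

    @property
    def trained(self) -> bool:
        return len(self.history) > 0


def _augment_pair(img, msk, aug: dict, rng: np.random.Generator):
    angle = np.deg2rad(rng.uniform(-aug["rotation_deg"], aug["rotation_deg"]))
    scale = 1.0 + rng.uniform(-aug["scale_range"], aug["scale_range"])
    shift = rng.uniform(-aug["translation_px"], aug["translation_px"], size=2)
    c, s = np.cos(angle), np.sin(angle)
    A = np.array([[c, -s], [s, c]]) / scale
    center = (np.array(img.shape) - 1) / 2.0
    offset = center - A @ center + shift
    img_t = ndimage.affine_transform(img, A, offset=offset, order=1, mode="nearest")
    msk_t = ndimage.affine_transform(
        msk.astype(np.float64), A, offset=offset, order=0, mode="constant"
    )
    return img_t, msk_t > 0.5


def _slice_dataset(samples, cfg: BackboneConfig):
    S = cfg.input_size
    imgs, msks = [], []
    for vol, mask in samples:
        if vol.shape != mask.shape:
            raise ValueError(
                f"volume/mask shape mismatch: {vol.shape} vs {mask.shape}"
            )
        norm = normalize_hu(vol.data)
        for z in range(vol.shape[0]):
            img = resize(norm[z], (S, S), order=1, preserve_range=True,
                         anti_aliasing=False)
            msk = resize(mask.data[z].astype(np.float64), (S, S), order=0,
                         preserve_range=True) > 0.5
            imgs.append(img)
            msks.append(msk)
    return np.asarray(imgs), np.asarray(msks)


def train_backbone(samples, cfg: BackboneConfig) -> BackboneHandle:
    """Train a slice-wise segmenter on ``(CTVolume, BinaryMask)`` pairs.

    Deterministic under a fixed config seed: identical data and config give
    identical loss traces.  The per-epoch history records mean training loss
    and a training Dice measured on a fixed evaluation subset.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one training pair")
    imgs, msks = _slice_dataset(samples, cfg)
    n = len(imgs)
    rng = np.random.default_rng(cfg.seed + 1)
    params = _init_params(cfg)
    opt = _nn.Adam(params, lr=cfg.learning_rate)
    eval_idx = np.linspace(0, n - 1, min(n, 32)).astype(int)
    # weight the foreground class by its rarity (capped) so small lesions
    # are not drowned out by the background term
    pos_frac = float(msks.mean())
    pos_weight = float(np.clip((1.0 - pos_frac) / max(pos_frac, 1e-6), 1.0, 50.0))

    records = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = np.empty((len(idx), 1, cfg.input_size, cfg.input_size))
            gb = np.empty_like(xb)
            for j, i in enumerate(idx):
                img, msk = imgs[i], msks[i]
                if rng.random() < 0.5:
                    img, msk = _augment_pair(img, msk, cfg.augmentation, rng)
                xb[j, 0] = img
                gb[j, 0] = msk
            logits, cache = _forward(params, cfg, xb)
            loss, dz = _nn.bce_dice_loss(logits, gb, pos_weight=pos_weight)
            grads = _backward(params, cfg, cache, dz)
            opt.step(params, grads)
            losses.append(loss)
        # training Dice on the fixed evaluation subset
        xe = imgs[eval_idx][:, None]
        logits, _ = _forward(params, cfg, xe)
        pred = _nn.sigmoid(logits)[:, 0] >= 0.5
        gt = msks[eval_idx]
        inter = (pred & gt).sum()
        denom = pred.sum() + gt.sum()
        dice = 2.0 * inter / denom if denom else 1.0
        records.append(dict(epoch=epoch, loss=float(np.mean(losses)), dice=float(dice)))

    history = pd.DataFrame(records)
    return BackboneHandle(params=params, cfg=cfg, history=history)


def predict(handle: BackboneHandle, volume: CTVolume) -> ProbabilityMap:
    """Per-slice inference restacked into a 3D probability map.

    Slices are processed axially in order; the output grid matches the input
    volume's shape, with probabilities in [0, 1].
    """
    if not isinstance(handle, BackboneHandle) or not handle.trained:
        raise ValueError("predict requires a trained BackboneHandle")
    cfg = handle.cfg
    S = cfg.input_size
    norm = normalize_hu(volume.data)
    out = np.empty_like(volume.data)
    batch = 16
    slices = [
        resize(norm[z], (S, S), order=1, preserve_range=True, anti_aliasing=False)
        for z in range(volume.shape[0])
    ]
    for start in range(0, len(slices), batch):
        xb = np.asarray(slices[start:start + batch])[:, None]
        logits, _ = _forward(handle.params, cfg, xb)
        probs = _nn.sigmoid(logits)[:, 0]
        for j in range(probs.shape[0]):
            out[start + j] = resize(
                probs[j], volume.shape[1:], order=1, preserve_range=True,
                anti_aliasing=False,
            )
    return ProbabilityMap(
        data=np.clip(out, 0.0, 1.0), spacing_mm=volume.spacing_mm, task=cfg.task
    )


def binarize(p: ProbabilityMap, threshold: float = 0.5) -> BinaryMask:
    """Threshold a probability map: voxel set iff probability >= threshold."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return BinaryMask(
        data=p.data >= threshold, spacing_mm=p.spacing_mm,
        role="liver" if p.task == "liver" else "trauma",
    )


# ---------------------------------------------------------------------------
# checkpoints: <dir>/model.npz, <dir>/config.json, <dir>/history.csv
# ---------------------------------------------------------------------------

def save_backbone(handle: BackboneHandle, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savez(d / "model.npz", **handle.params)
    (d / "config.json").write_text(json.dumps(asdict(handle.cfg), indent=2))
    handle.history.to_csv(d / "history.csv", index=False)
    return d


def load_backbone(directory) -> BackboneHandle:
    d = Path(directory)
    if not (d / "model.npz").exists():
        raise FileNotFoundError(f"no checkpoint at {d}")
    with np.load(d / "model.npz") as npz:
        params = {k: npz[k].copy() for k in npz.files}
    cfg = BackboneConfig(**json.loads((d / "config.json").read_text()))
    history = pd.read_csv(d / "history.csv")
    return BackboneHandle(params=params, cfg=cfg, history=history)
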