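"""Minimal numpy building blocks for the slice-wise segmentation network.

Forward/backward passes are written explicitly (im2col convolutions, average
pooling, nearest-neighbour upsampling, channel concatenation) so training is
pure numpy and bit-reproducible under a fixed seed.  A finite-difference
check in the test suite guards the analytic gradients.

Array layout is ``(N, C, H, W)`` throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv3_forward", "conv3_backward",
    "conv1_forward", "conv1_backward",
    "he_init",
    "relu_forward", "relu_backward",
    "avgpool2_forward", "avgpool2_backward",
    "upsample2_forward", "upsample2_backward",
    "sigmoid", "bce_dice_loss",
    "Adam",
]


# ---------------------------------------------------------------------------
# 3x3 convolution, 'same' padding, via im2col
# ---------------------------------------------------------------------------

def _im2col3(Xp: np.ndarray, H: int, W: int) -> np.ndarray:
    """(N, C, H+2, W+2) -> (N, C, 9, H, W) view-stack of the 9 shifts."""
    cols = np.empty(Xp.shape[:2] + (9, H, W), dtype=Xp.dtype)
    k = 0
    for dy in range(3):
        for dx in range(3):
            cols[:, :, k] = Xp[:, :, dy:dy + H, dx:dx + W]
            k += 1
    return cols


def conv3_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """X (N,C,H,W), W (F,C,3,3), b (F,) -> out (N,F,H,W) plus cache."""
    N, C, H, Wd = X.shape
    F = W.shape[0]
    Xp = np.pad(X, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = _im2col3(Xp, H, Wd).reshape(N, C * 9, H * Wd)
    Wm = W.reshape(F, C * 9)
    out = np.matmul(Wm[None], cols).reshape(N, F, H, Wd)
    out += b[None, :, None, None]
    return out, (cols, X.shape, W.shape)


def conv3_backward(dOut: np.ndarray, W: np.ndarray, cache):
    """Gradients w.r.t. weights, bias and input."""
    cols, x_shape, w_shape = cache
    N, C, H, Wd = x_shape
    F = w_shape[0]
    dm = dOut.reshape(N, F, H * Wd)
    dW = np.matmul(dm, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w_shape)
    db = dOut.sum(axis=(0, 2, 3))
    Wm = W.reshape(F, C * 9)
    dcols = np.matmul(Wm.T[None], dm).reshape(N, C, 9, H, Wd)
    dXp = np.zeros((N, C, H + 2, Wd + 2))
    k = 0
    for dy in range(3):
        for dx in range(3):
            dXp[:, :, dy:dy + H, dx:dx + Wd] += dcols[:, :, k]
            k += 1
    return dW, db, dXp[:, :, 1:-1, 1:-1]


# ---------------------------------------------------------------------------
# 1x1 convolution (final classifier head)
# ---------------------------------------------------------------------------

def conv1_forward(X: np.ndarray, W: np.ndarray, b: np.ndarray):
    """X (N,C,H,W), W (F,C) -> (N,F,H,W)."""
    out = np.einsum("fc,nchw->nfhw", W, X) + b[None, :, None, None]
    return out, X


def conv1_backward(dOut: np.ndarray, W: np.ndarray, X: np.ndarray):
    dW = np.einsum("nfhw,nchw->fc", dOut, X)
    db = dOut.sum(axis=(0, 2, 3))
    dX = np.einsum("fc,nfhw->nchw", W, dOut)
    return dW, db, dX


# ---------------------------------------------------------------------------
# activations / resampling
# ---------------------------------------------------------------------------

def relu_forward(X):
    mask = X > 0
    return X * mask, mask


def relu_backward(dOut, mask):
    return dOut * mask


def avgpool2_forward(X):
    N, C, H, W = X.shape
    out = X.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))
    return out, X.shape


def avgpool2_backward(dOut, x_shape):
    N, C, H, W = x_shape
    up = np.repeat(np.repeat(dOut, 2, axis=2), 2, axis=3) / 4.0
    return up


def upsample2_forward(X):
    return np.repeat(np.repeat(X, 2, axis=2), 2, axis=3), X.shape


def upsample2_backward(dOut, x_shape):
    N, C, H, W = x_shape
    return dOut.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5))


def sigmoid(z):
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_dice_loss(
    z: np.ndarray, g: np.ndarray, dice_weight: float = 1.0, pos_weight: float = 1.0
):
    """Binary cross-entropy (with logits) plus soft-Dice loss.

    Returns ``(loss, dL/dz)``.  ``pos_weight`` multiplies the foreground
    term of the cross-entropy, countering the extreme class imbalance of
    small lesions; the Dice term uses a smoothing constant so empty targets
    are well-defined.
    """
    p = sigmoid(z)
    softplus = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30))))
    # BCE = pos_weight * g * softplus(-z) + (1 - g) * softplus(z)
    softplus_neg = softplus - z
    bce = float((pos_weight * g * softplus_neg + (1.0 - g) * softplus).mean())
    dz = ((1.0 - g) * p - pos_weight * g * (1.0 - p)) / z.size

    eps = 1.0
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum() + g.sum()) + eps
    dice_loss = 1.0 - num / den
    # d(1 - num/den)/dp = -(2 g den - num) / den^2 ; chain through sigmoid
    ddice_dp = -(2.0 * g * den - num) / den**2
    dz = dz + dice_weight * ddice_dp * p * (1.0 - p)
    return bce + dice_weight * dice_loss, dz


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-normal weight initialisation."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    """Plain Adam over a name->array parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
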