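"""Segmentation losses: BCE, Dice, focal, categorical CE, and compounds.

All losses consume a one-hot target and a same-shaped probability map
(output of a per-pixel softmax).  Binary cross-entropy and focal loss are
applied per scalar entry across every channel and averaged; Dice is
computed per channel over the whole batch with an additive smoothing
constant and averaged over channels; categorical cross-entropy averages
the per-pixel sum of ``-y log p`` over pixels.  Every ``*_loss`` function
has a ``*_loss_grad`` companion returning ``(value, dL/dy_pred)`` for the
numpy training engine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LossConfig:
    """Constants of the loss family.

    alpha and gamma parameterize the focal loss (class balance and
    focusing strength); lambda1/lambda2 weight the cross-entropy and Dice
    terms of the compound losses; smooth is added to the Dice numerator
    and denominator; clip_eps bounds probabilities away from {0, 1}
    before logarithms.
    """

    alpha: float = 0.5
    gamma: float = 2.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    smooth: float = 1.0
    clip_eps: float = 1e-7

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda weights must be >= 0")
        if self.smooth < 0:
            raise ValueError("smooth must be >= 0")
        if not 0.0 < self.clip_eps < 0.5:
            raise ValueError("clip_eps must be in (0, 0.5)")


def _check_pair(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"shape mismatch: y_true {y_true.shape} vs y_pred {y_pred.shape}")
    return y_true, y_pred


# ---------------------------------------------------------------------------
# binary cross-entropy
# ---------------------------------------------------------------------------

def bce_loss_grad(y_true, y_pred, cfg: LossConfig = LossConfig()):
    y, p = _check_pair(y_true, y_pred)
    p = np.clip(p, cfg.clip_eps, 1.0 - cfg.clip_eps)
    n = p.size
    value = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum() / n
    grad = -(y / p - (1.0 - y) / (1.0 - p)) / n
    return float(value), grad


def bce_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Mean binary cross-entropy over all entries (pixels x channels)."""
    return bce_loss_grad(y_true, y_pred, cfg)[0]


# ---------------------------------------------------------------------------
# Dice
# ---------------------------------------------------------------------------

def dice_loss_grad(y_true, y_pred, cfg: LossConfig = LossConfig()):
    y, p = _check_pair(y_true, y_pred)
    c = y.shape[-1] if y.ndim > 1 else 1
    yf = y.reshape(-1, c)
    pf = p.reshape(-1, c)
    inter = (yf * pf).sum(axis=0)
    sums = yf.sum(axis=0) + pf.sum(axis=0)
    s = cfg.smooth
    dice = (2.0 * inter + s) / (sums + s)
    value = float(np.mean(1.0 - dice))
    # d/dp of (1 - (2I+s)/(U+s)) = -(2 y (U+s) - (2I+s)) / (U+s)^2, / C
    gflat = -(2.0 * yf * (sums + s) - (2.0 * inter + s)) / (sums + s) ** 2 / c
    return value, gflat.reshape(p.shape)


def dice_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Per-channel smoothed Dice loss averaged over channels (batch Dice)."""
    return dice_loss_grad(y_true, y_pred, cfg)[0]


# ---------------------------------------------------------------------------
# focal
# ---------------------------------------------------------------------------

def focal_loss_grad(y_true, y_pred, cfg: LossConfig = LossConfig()):
    y, p = _check_pair(y_true, y_pred)
    p = np.clip(p, cfg.clip_eps, 1.0 - cfg.clip_eps)
    n = p.size
    pt = np.where(y == 1.0, p, 1.0 - p)
    a, g = cfg.alpha, cfg.gamma
    one_minus = 1.0 - pt
    value = float((a * one_minus ** g * (-np.log(pt))).sum() / n)
    # dL/dpt, then chain through pt = +/- y_pred
    if g == 0:
        dpt = -a / pt
    else:
        dpt = a * (g * one_minus ** (g - 1.0) * np.log(pt) - one_minus ** g / pt)
    grad = np.where(y == 1.0, dpt, -dpt) / n
    return value, grad


def focal_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Focal loss: cross-entropy modulated by alpha * (1 - p_t)^gamma."""
    return focal_loss_grad(y_true, y_pred, cfg)[0]


# ---------------------------------------------------------------------------
# compounds and categorical CE
# ---------------------------------------------------------------------------

def bce_dice_loss_grad(y_true, y_pred, cfg: LossConfig = LossConfig()):
    vb, gb = bce_loss_grad(y_true, y_pred, cfg)
    vd, gd = dice_loss_grad(y_true, y_pred, cfg)
    return cfg.lambda1 * vb + cfg.lambda2 * vd, cfg.lambda1 * gb + cfg.lambda2 * gd


def bce_dice_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Weighted sum lambda1 * BCE + lambda2 * Dice."""
    return bce_dice_loss_grad(y_true, y_pred, cfg)[0]


def cce_loss_grad(y_true, y_pred, cfg: LossConfig = LossConfig()):
    y, p = _check_pair(y_true, y_pred)
    if y.ndim < 2 or y.shape[-1] < 2:
        raise ValueError("categorical cross-entropy needs >= 2 channels")
    csum = y.sum(axis=-1)
    if not np.allclose(csum, 1.0) or not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("y_true must be one-hot across the channel axis")
    p = np.clip(p, cfg.clip_eps, 1.0 - cfg.clip_eps)
    n_pix = y.size // y.shape[-1]
    value = float(-(y * np.log(p)).sum() / n_pix)
    grad = -(y / p) / n_pix
    return value, grad


def cce_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Categorical cross-entropy: mean over pixels of -sum_c y_c log p_c."""
    return cce_loss_grad(y_true, y_pred, cfg)[0]


def cce_dice_loss_grad(y_true, y_pred, cfg: LossConfig = LossConfig()):
    vc, gc = cce_loss_grad(y_true, y_pred, cfg)
    vd, gd = dice_loss_grad(y_true, y_pred, cfg)
    return cfg.lambda1 * vc + cfg.lambda2 * vd, cfg.lambda1 * gc + cfg.lambda2 * gd


def cce_dice_loss(y_true, y_pred, cfg: LossConfig = LossConfig()) -> float:
    """Weighted sum lambda1 * CCE + lambda2 * Dice."""
    return cce_dice_loss_grad(y_true, y_pred, cfg)[0]


LOSSES = {
    "bce": bce_loss,
    "dice": dice_loss,
    "focal": focal_loss,
    "bce_dice": bce_dice_loss,
    "cce": cce_loss,
    "cce_dice": cce_dice_loss,
}

LOSS_GRADS = {
    "bce": bce_loss_grad,
    "dice": dice_loss_grad,
    "focal": focal_loss_grad,
    "bce_dice": bce_dice_loss_grad,
    "cce": cce_loss_grad,
    "cce_dice": cce_dice_loss_grad,
}


def get_loss(name: str):
    """Look up a loss function by its configuration name."""
    try:
        return LOSSES[name]
    except KeyError:
        raise KeyError(f"unknown loss {name!r}; choose from {sorted(LOSSES)}")
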