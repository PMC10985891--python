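"""Compound segmentation training loss: weighted cross-entropy + Dice.

The total loss is ``L = 0.5 * L_dice + 0.5 * L_ce`` where

* ``L_ce = -(1/(M*N)) * sum_k sum_i W_k * g(k,i) * log p(k,i)`` with
  per-class weights ``W_k = N_total / N_k`` computed from pixel counts of
  the training split — rare classes (the SVC) get a proportionally larger
  weight.  Only positive pixels contribute; the Dice term penalizes false
  positives.
* ``L_dice`` is the mean over the M channels of one minus the soft Dice
  overlap ``2*sum(g*p) / (sum(g) + sum(p))`` (with a small smoothing
  epsilon).  The per-channel summand is already normalized by pixel sums,
  so the channel mean (1/M) is the natural prefactor: an extra 1/N would
  shrink the term towards zero as images grow.

``p`` are per-channel probabilities in [0, 1] (M = 3 vessel channels),
``g`` the binary ground-truth channels.  Arrays may carry a leading batch
axis; pixels are then pooled over the batch.  All functions optionally
return the analytic gradient with respect to ``p`` so the loss can drive
any differentiable backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLAMP_EPS = 1e-7     # lower clamp on p inside log
DICE_EPS = 1e-6      # smoothing added to numerator and denominator


class MissingClassError(ValueError):
    """A class has zero positive pixels; its CE weight is undefined."""


@dataclass(frozen=True)
class ClassWeights:
    """W_k = N_total / N_k for each vessel class k."""

    weights: np.ndarray        # shape (M,), index k-1
    n_total: int
    n_k: np.ndarray            # shape (M,)

    @classmethod
    def uniform(cls, m: int = 3) -> "ClassWeights":
        return cls(weights=np.ones(m), n_total=m, n_k=np.ones(m, dtype=int))


@dataclass(frozen=True)
class LossValue:
    """Total loss and its two components (L = 0.5*L_dice + 0.5*L_ce)."""

    total: float
    ce: float
    dice: float
    m: int
    n: int


def compute_class_weights(masks, classes=(1, 2, 3)) -> ClassWeights:
    """Pixel-frequency weights over a collection of label masks.

    ``N_k`` counts pixels labeled ``k`` over the whole split, ``N_total``
    all pixels; a class absent from every mask raises
    :class:`MissingClassError` (its weight would be undefined).
    """
    masks = [np.asarray(m) for m in masks]
    if not masks:
        raise ValueError("need at least one mask")
    n_total = int(sum(m.size for m in masks))
    n_k = np.zeros(len(classes), dtype=np.int64)
    for m in masks:
        for j, k in enumerate(classes):
            n_k[j] += int((m == k).sum())
    for j, k in enumerate(classes):
        if n_k[j] == 0:
            raise MissingClassError(f"class {k} has no positive pixels in the split")
    return ClassWeights(weights=n_total / n_k, n_total=n_total, n_k=n_k)


def _align(pred, gt):
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if p.ndim == 3:                      # (M, H, W) -> (1, M, H, W)
        p, g = p[None], g[None]
    if p.ndim != 4:
        raise ValueError(f"expected (M,H,W) or (B,M,H,W), got {p.shape}")
    return p, g


def ce_loss(pred, gt, weights: ClassWeights, grad: bool = False):
    """Class-weighted cross-entropy on positive pixels.

    Returns the scalar, or ``(scalar, dL/dp)`` when ``grad`` is true.
    """
    p, g = _align(pred, gt)
    b, m, h, w = p.shape
    wk = np.asarray(weights.weights, dtype=float).reshape(1, m, 1, 1)
    n = b * h * w                         # pixels per channel, batch pooled
    pc = np.clip(p, CLAMP_EPS, 1.0)
    loss = float(-(wk * g * np.log(pc)).sum() / (m * n))
    if not grad:
        return loss
    dp = -(wk * g) / (m * n * pc)
    dp[p < CLAMP_EPS] = 0.0               # clamped region: flat
    return loss, dp.reshape(np.asarray(pred).shape)


def dice_loss(pred, gt, grad: bool = False):
    """Mean over channels of (1 - soft Dice), smoothed by ``DICE_EPS``."""
    p, g = _align(pred, gt)
    b, m, h, w = p.shape
    inter = (g * p).sum(axis=(0, 2, 3)) + DICE_EPS       # per channel
    denom = g.sum(axis=(0, 2, 3)) + p.sum(axis=(0, 2, 3)) + DICE_EPS
    loss = float((1.0 - 2.0 * inter / denom).mean())
    if not grad:
        return loss
    # d/dp_i [ -2*I/S ] = -2*(g_i*S - I)/S^2
    dp = -2.0 * (g * denom.reshape(1, m, 1, 1) - inter.reshape(1, m, 1, 1)) \
        / (denom.reshape(1, m, 1, 1) ** 2) / m
    return loss, dp.reshape(np.asarray(pred).shape)


def total_loss(pred, gt, weights: ClassWeights, grad: bool = False):
    """``0.5 * dice + 0.5 * ce``; optionally with ``dL/dp``."""
    p, g = _align(pred, gt)
    _, m, h, w = p.shape
    n = p.shape[0] * h * w
    if grad:
        lce, dce = ce_loss(pred, gt, weights, grad=True)
        ldc, ddc = dice_loss(pred, gt, grad=True)
        value = LossValue(total=0.5 * ldc + 0.5 * lce, ce=lce, dice=ldc, m=m, n=n)
        return value, 0.5 * dce + 0.5 * ddc
    lce = ce_loss(pred, gt, weights)
    ldc = dice_loss(pred, gt)
    return LossValue(total=0.5 * ldc + 0.5 * lce, ce=lce, dice=ldc, m=m, n=n)


def mask_to_channels(mask: np.ndarray, classes=(1, 2, 3)) -> np.ndarray:
    """One binary channel per vessel class (no background channel)."""
    mask = np.asarray(mask)
    return np.stack([(mask == k).astype(float) for k in classes])
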