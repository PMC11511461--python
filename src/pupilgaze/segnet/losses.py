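"""Joint segmentation loss: Dice for the pupil map, binary cross-entropy
for eye closure, combined as total = lambda1 * dice + lambda2 * bce.

The public functions operate on plain arrays / scalars (evaluation and
testing); `dice_loss_t` / `closure_loss_t` are the differentiable
training counterparts on autodiff tensors.
"""

from __future__ import annotations

import numpy as np

from pupilgaze.segnet import autodiff as ad
from pupilgaze.segnet.autodiff import Tensor

__all__ = ["dice_loss", "closure_loss", "total_loss", "dice_loss_t", "closure_loss_t"]

_CLIP = 1e-7  # probability clipping for the BCE term


def dice_loss(truth_mask: np.ndarray, pred_map: np.ndarray) -> float:
    """1 - 2*sum(y*yhat) / sum(y + yhat).

    The degenerate all-background case (both sums zero) returns 0 via
    additive smoothing s=1; no smoothing is applied otherwise so the
    closed forms (e.g. half-overlap -> 1/3) hold exactly.
    """
    y = np.asarray(truth_mask, dtype=np.float64)
    yhat = np.asarray(pred_map, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    if not np.isin(np.unique(y), (0.0, 1.0)).all():
        raise ValueError("truth mask must be binary")
    if yhat.min() < 0.0 or yhat.max() > 1.0:
        raise ValueError("predictions must lie in [0, 1]")
    inter = float((y * yhat).sum())
    denom = float((y + yhat).sum())
    if denom == 0.0:
        return 1.0 - (2.0 * inter + 1.0) / (denom + 1.0)  # = 0
    return 1.0 - 2.0 * inter / denom


def closure_loss(truth_closed: float, p_close: float) -> float:
    """Scalar binary cross-entropy of the eye-closure label; the
    prediction is clipped to [delta, 1-delta] with delta = 1e-7."""
    y = float(truth_closed)
    if y not in (0.0, 1.0):
        raise ValueError("truth_closed must be 0 or 1")
    p = float(np.clip(p_close, _CLIP, 1.0 - _CLIP))
    return -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))


def total_loss(dice: float, bce: float, lambda1: float, lambda2: float,
               gate: int = 1) -> float:
    """lambda1 * dice + lambda2 * bce; with gate = 0 no decoder output
    exists, so the pupil term is masked to zero."""
    pupil_term = dice if gate else 0.0
    return lambda1 * pupil_term + lambda2 * bce


# -- differentiable training versions ------------------------------------

def dice_loss_t(truth: np.ndarray, pred: Tensor, smooth: float = 1e-6) -> Tensor:
    """Per-sample Dice loss, (N, 1, H, W) -> (N,) tensor. A tiny smooth
    term keeps the gradient finite on empty masks."""
    y = Tensor(truth)
    inter = ad.tsum(ad.mul(y, pred), axis=(1, 2, 3))
    denom = ad.tsum(ad.add(y, pred), axis=(1, 2, 3))
    ratio = ad.mul(inter + smooth, ad.power(denom + smooth, -1.0))
    return 1.0 - 2.0 * ratio


def closure_loss_t(truth: np.ndarray, p: Tensor) -> Tensor:
    """Per-sample BCE, (N,) labels vs (N,) probabilities -> (N,) tensor."""
    y = Tensor(truth)
    return -(
        ad.mul(y, ad.log(p + _CLIP)) + ad.mul(1.0 - y, ad.log((1.0 - p) + _CLIP))
    )
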