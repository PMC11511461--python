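"""Training loop for the segmentation network.

Joint objective per batch::

    total = lambda1 * mean_over_open_frames(dice) + lambda2 * mean(bce)

Gating during training is teacher-forced: the ground-truth closed label
masks the Dice term (a closed frame has no meaningful pupil target), so
open-eye frames always train the decoder. Inference gating uses the
predicted Pclose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from pupilgaze.config import NetConfig, TrainConfig
from pupilgaze.segnet import autodiff as ad
from pupilgaze.segnet.autodiff import Tensor
from pupilgaze.segnet.losses import closure_loss_t, dice_loss_t
from pupilgaze.segnet.model import PupilSegNet
from pupilgaze.segnet.optim import Adam
from pupilgaze.synthdata import EyeFrame

__all__ = ["TrainHistory", "frames_to_arrays", "train_model", "evaluate_dice"]


@dataclass
class TrainHistory:
    epoch_loss: List[float] = field(default_factory=list)
    epoch_dice: List[float] = field(default_factory=list)
    epoch_bce: List[float] = field(default_factory=list)

    def to_rows(self):
        return [
            {"epoch": i, "total_loss": l, "dice_loss": d, "bce_loss": b}
            for i, (l, d, b) in enumerate(
                zip(self.epoch_loss, self.epoch_dice, self.epoch_bce)
            )
        ]


def frames_to_arrays(frames: Sequence[EyeFrame]):
    """Stack frames into (N,1,H,W) pixels, (N,1,H,W) masks, (N,) closed."""
    x = np.stack([f.pixels for f in frames]).astype(np.float32)[:, None]
    masks = np.stack([f.annotation.mask for f in frames]).astype(np.float32)[:, None]
    closed = np.array([f.annotation.closed for f in frames], dtype=np.float32)
    return x, masks, closed


def train_model(
    model: PupilSegNet,
    frames: Sequence[EyeFrame],
    train_cfg: Optional[TrainConfig] = None,
    optimizer: Optional[Adam] = None,
) -> TrainHistory:
    cfg = train_cfg or TrainConfig()
    if not frames:
        raise ValueError("no training frames supplied")
    lam1, lam2 = model.config.loss_weights
    x, masks, closed = frames_to_arrays(frames)
    n = len(frames)
    opt = optimizer or Adam(
        model.parameters(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2
    )
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        tot_sum = dice_sum = bce_sum = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            open_mask = 1.0 - closed[idx]
            prob, p_close = model.forward_batch(x[idx], training=True)
            dice_vec = dice_loss_t(masks[idx], prob)
            n_open = float(open_mask.sum())
            if n_open > 0:
                dice = ad.tsum(ad.mul(dice_vec, Tensor(open_mask))) * (1.0 / n_open)
            else:  # all-closed batch: pupil term masked out entirely
                dice = Tensor(0.0)
            bce = ad.tmean(closure_loss_t(closed[idx], p_close))
            loss = lam1 * dice + lam2 * bce
            opt.zero_grad()
            loss.backward()
            opt.step()
            tot_sum += loss.item()
            dice_sum += dice.item()
            bce_sum += bce.item()
            n_batches += 1
        history.epoch_loss.append(tot_sum / n_batches)
        history.epoch_dice.append(dice_sum / n_batches)
        history.epoch_bce.append(bce_sum / n_batches)
    return history


def evaluate_dice(model: PupilSegNet, frames: Sequence[EyeFrame],
                  batch_size: int = 8) -> float:
    """Mean Dice *score* (1 - loss) over open-eye frames, eval mode."""
    x, masks, closed = frames_to_arrays(frames)
    scores = []
    with ad.no_grad():
        for start in range(0, len(frames), batch_size):
            sl = slice(start, start + batch_size)
            prob, _ = model.forward_batch(x[sl], training=False)
            pm = prob.data
            for i in range(pm.shape[0]):
                if closed[sl][i]:
                    continue
                y = masks[sl][i]
                inter = float((y * pm[i]).sum())
                denom = float((y + pm[i]).sum())
                scores.append(2.0 * inter / denom if denom > 0 else 1.0)
    if not scores:
        raise ValueError("no open-eye frames to evaluate")
    return float(np.mean(scores))
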