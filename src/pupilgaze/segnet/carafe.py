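"""Content-aware reassembly (CARAFE) upsampling.

Two stages: (1) predict one m x m reassembly kernel per output location
from the content of its source neighborhood; (2) form each output value
as the kernel-weighted sum of that neighborhood, shared across channels.
Each output location q = (u, v) reads from source location
(s, t) = (u // r, v // r); border neighborhoods are zero-padded; kernels
are softmax-normalized so each sums to 1.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from pupilgaze.segnet import autodiff as ad
from pupilgaze.segnet.autodiff import Tensor
from pupilgaze.segnet.layers import Conv2d, Module

__all__ = ["carafe_source", "carafe_reassemble", "CarafeUpsample"]


def carafe_source(q: Tuple[int, int], r: int) -> Tuple[int, int]:
    """Source location (s, t) = (u // r, v // r) for target location q."""
    u, v = q
    if u < 0 or v < 0:
        raise ValueError("target location must be nonnegative")
    if r < 1:
        raise ValueError("upsampling ratio must be >= 1")
    return (u // r, v // r)


def carafe_reassemble(features: Tensor, kernels: Tensor, m: int, r: int) -> Tensor:
    """Weighted reassembly of source neighborhoods.

    features: (N, C, H, W); kernels: (N, m*m, rH, rW) with each kernel
    summing to 1 over its m*m entries. Returns (N, C, rH, rW).
    """
    if m % 2 == 0:
        raise ValueError("kernel size m must be odd")
    n, c, h, w = features.shape
    kn, km2, oh, ow = kernels.shape
    if kn != n or km2 != m * m or oh != r * h or ow != r * w:
        raise ValueError(
            f"kernel shape {kernels.shape} does not match features "
            f"{features.shape} with m={m}, r={r}"
        )
    pad = m // 2
    xp = np.pad(features.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((n, c, oh, ow), dtype=np.float32)
    for idx in range(m * m):
        i, j = divmod(idx, m)
        src = xp[:, :, i : i + h, j : j + w]
        srcu = np.repeat(np.repeat(src, r, axis=2), r, axis=3)
        out += srcu * kernels.data[:, idx : idx + 1]

    def bw(g):
        if kernels.requires_grad:
            dk = np.empty_like(kernels.data)
        dxp = np.zeros_like(xp) if features.requires_grad else None
        for idx in range(m * m):
            i, j = divmod(idx, m)
            if kernels.requires_grad:
                src = xp[:, :, i : i + h, j : j + w]
                srcu = np.repeat(np.repeat(src, r, axis=2), r, axis=3)
                dk[:, idx] = (g * srcu).sum(axis=1)
            if dxp is not None:
                t = (g * kernels.data[:, idx : idx + 1]).reshape(n, c, h, r, w, r)
                dxp[:, :, i : i + h, j : j + w] += t.sum(axis=(3, 5))
        if kernels.requires_grad:
            kernels._accumulate(dk)
        if features.requires_grad:
            features._accumulate(dxp[:, :, pad : pad + h, pad : pad + w])

    return Tensor(out, parents=(features, kernels), backward=bw)


class CarafeUpsample(Module):
    """x2 (or xr) CARAFE layer: 1x1 content-encoder conv predicting
    r^2 * m^2 kernel logits, pixel-shuffled to one m x m kernel per
    output location and softmax-normalized."""

    def __init__(self, channels: int, m: int, r: int, rng: np.random.Generator):
        if m % 2 == 0:
            raise ValueError("kernel size m must be odd")
        self.m = m
        self.r = r
        self.encoder = Conv2d(channels, r * r * m * m, 1, rng)

    def predict_kernels(self, features: Tensor, training: bool = False) -> Tensor:
        """(N, C, H, W) -> (N, m*m, rH, rW) simplex-normalized kernels."""
        logits = self.encoder(features)
        shuffled = ad.pixel_shuffle(logits, self.r)
        return ad.softmax_channels(shuffled)

    def __call__(self, features: Tensor, training: bool = False) -> Tensor:
        kernels = self.predict_kernels(features, training)
        return carafe_reassemble(features, kernels, self.m, self.r)
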