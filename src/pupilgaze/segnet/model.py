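"""Gated encoder-decoder pupil segmentation network.

Encoder: five down blocks (four conv+BN+LeakyReLU layers each) with a
2x2 average pool after each of the first four, so the fifth block — the
bottleneck — sits at 1/16 of the input resolution. An eye-closure head
(global average pool -> linear -> sigmoid) reads the bottleneck and
produces Pclose. The gating variable

    G = Heaviside(1 - Pclose - epsilon),  Heaviside(0) = 1

switches the decoder: when G = 0 the upsampling path is skipped entirely
and the probability map is the all-zero sentinel. The decoder is four up
blocks, each preceded by a x2 CARAFE upsampling and a skip connection
from the matching encoder stage; a final 1x1 conv + sigmoid yields the
per-pixel pupil probability map at input resolution.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np

from pupilgaze.config import NetConfig
from pupilgaze.segnet import autodiff as ad
from pupilgaze.segnet.autodiff import Tensor, no_grad
from pupilgaze.segnet.carafe import CarafeUpsample
from pupilgaze.segnet.layers import Conv2d, ConvBlock, Linear, Module

__all__ = ["gate", "SegOutput", "PupilSegNet", "forward", "save_checkpoint", "load_checkpoint"]

DOWNSAMPLE_FACTOR = 16  # four 2x2 poolings


def gate(p_close: float, epsilon: float) -> int:
    """G = Heaviside(1 - Pclose - epsilon) with Heaviside(0) = 1.

    1 means run the decoder; 0 means skip upsampling entirely.
    """
    if not 0.0 <= p_close <= 1.0:
        raise ValueError("p_close must lie in [0, 1]")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    return 1 if (1.0 - p_close - epsilon) >= 0.0 else 0


@dataclass
class SegOutput:
    prob_map: np.ndarray  # (H, W) in [0, 1]; all-zero sentinel when gated off
    p_close: float
    gate: int
    decoder_ran: bool


class PupilSegNet(Module):
    def __init__(self, config: Optional[NetConfig] = None, seed: int = 0):
        config = config or NetConfig()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.encoder_channels
        slope = config.leaky_slope
        m, r = config.carafe_kernel, config.carafe_ratio

        self.down = [
            ConvBlock(1 if i == 0 else ch[i - 1], ch[i], rng, slope) for i in range(5)
        ]
        self.closure = Linear(ch[4], 1, rng)

        # decoder works down from the bottleneck width to the first stage
        dec_in = ch[4]
        ups, blocks = [], []
        for lvl in (3, 2, 1, 0):
            ups.append(CarafeUpsample(dec_in, m, r, rng))
            blocks.append(ConvBlock(dec_in + ch[lvl], ch[lvl], rng, slope))
            dec_in = ch[lvl]
        self.ups = ups
        self.up_blocks = blocks
        self.head = Conv2d(ch[0], 1, 1, rng)

    # -- batched paths (training / bulk inference) -----------------------
    def encode(self, x: Tensor, training: bool):
        skips = []
        for i in range(4):
            x = self.down[i](x, training)
            skips.append(x)
            x = ad.avg_pool2(x)
        bottleneck = self.down[4](x, training)
        return bottleneck, skips

    def closure_prob(self, bottleneck: Tensor) -> Tensor:
        pooled = ad.global_avg_pool(bottleneck)
        return ad.sigmoid(self.closure(pooled))  # (N, 1)

    def decode(self, bottleneck: Tensor, skips, training: bool) -> Tensor:
        x = bottleneck
        for up, block, skip in zip(self.ups, self.up_blocks, reversed(skips)):
            x = up(x, training)
            x = ad.concat([x, skip], axis=1)
            x = block(x, training)
        return ad.sigmoid(self.head(x))

    def forward_batch(self, pixels: np.ndarray, training: bool = False,
                      run_decoder: bool = True):
        """pixels: (N, 1, H, W) in [0, 1]. Returns (prob_map Tensor or
        None, p_close Tensor of shape (N,))."""
        _check_divisible(pixels.shape[-2:])
        x = Tensor(pixels)
        bottleneck, skips = self.encode(x, training)
        p_close = ad.reshape(self.closure_prob(bottleneck), (-1,))
        prob = self.decode(bottleneck, skips, training) if run_decoder else None
        return prob, p_close

    def footprint_bytes(self, bytes_per_param: int = 4) -> int:
        return self.num_parameters() * bytes_per_param


def _check_divisible(shape: Tuple[int, int]) -> None:
    h, w = shape
    if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
        raise ValueError(
            f"input size {h}x{w} must be divisible by {DOWNSAMPLE_FACTOR} "
            "(four 2x2 poolings)"
        )


def forward(frame, model: PupilSegNet) -> SegOutput:
    """Single-frame inference with eye-closure gating.

    `frame` is an EyeFrame or a 2-D intensity array in [0, 1]. Uses the
    network's running batch-norm statistics (eval mode). When the gate
    is closed the decoder is skipped and prob_map is all zeros.
    """
    pixels = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    if pixels.ndim != 2:
        raise ValueError("frame must be a single 2-D intensity grid")
    _check_divisible(pixels.shape)
    x = pixels[None, None].astype(np.float32)
    eps = model.config.epsilon
    with no_grad():
        xt = Tensor(x)
        bottleneck, skips = model.encode(xt, training=False)
        p_close = float(model.closure_prob(bottleneck).data[0, 0])
        g = gate(p_close, eps)
        if g == 0:
            prob = np.zeros(pixels.shape, dtype=np.float32)
            return SegOutput(prob_map=prob, p_close=p_close, gate=0, decoder_ran=False)
        prob = model.decode(bottleneck, skips, training=False).data[0, 0]
    return SegOutput(prob_map=prob, p_close=p_close, gate=1, decoder_ran=True)


def save_checkpoint(model: PupilSegNet, path: Union[str, Path]) -> None:
    """Weights as .npz plus a JSON sidecar carrying the NetConfig."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(dataclasses.asdict(model.config), fh, sort_keys=True)


def load_checkpoint(path: Union[str, Path]) -> PupilSegNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with open(path.with_suffix(".json")) as fh:
        raw = json.load(fh)
    raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    model = PupilSegNet(NetConfig(**raw))
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
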