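"""Run configuration: dataclasses for every pipeline stage plus YAML loading."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import yaml


@dataclass
class SynthEyeConfig:
    """Parameters of the synthetic near-infrared eye-frame generator."""

    height: int = 64
    width: int = 64
    pupil_radius_range: Tuple[float, float] = (6.0, 12.0)
    # semi-minor axis = semi-major * ratio drawn from this range
    aspect_ratio_range: Tuple[float, float] = (0.6, 1.0)
    closed_prob: float = 0.0
    partial_occlusion_prob: float = 0.0
    glint_count_range: Tuple[int, int] = (0, 2)
    glint_radius_range: Tuple[float, float] = (1.0, 2.5)
    illumination_gradient_range: Tuple[float, float] = (0.0, 0.2)
    noise_sigma: float = 0.02
    pupil_intensity_range: Tuple[float, float] = (0.05, 0.2)
    iris_intensity_range: Tuple[float, float] = (0.3, 0.6)
    sclera_intensity_range: Tuple[float, float] = (0.5, 0.9)

    def validate(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("image size must be at least 32x32")
        if self.height % 16 or self.width % 16:
            raise ValueError("image size must be divisible by 16")
        if self.pupil_radius_range[1] > min(self.height, self.width) / 2:
            raise ValueError(
                "pupil radius may not exceed half the image size "
                f"(got max radius {self.pupil_radius_range[1]})"
            )
        if not 0.0 <= self.closed_prob <= 1.0:
            raise ValueError("closed_prob must be in [0, 1]")


@dataclass
class NetConfig:
    """Architecture hyperparameters of the segmentation network."""

    base_channels: int = 8
    channel_multipliers: Tuple[int, ...] = (1, 2, 4, 4, 4)
    carafe_kernel: int = 5  # m, odd
    carafe_ratio: int = 2  # r, fixed at 2 per up block
    epsilon: float = 0.01  # gate threshold
    loss_weights: Tuple[float, float] = (1.0, 0.5)  # (lambda1, lambda2)
    leaky_slope: float = 0.01

    def validate(self) -> None:
        if len(self.channel_multipliers) != 5:
            raise ValueError("channel_multipliers must have 5 entries")
        if self.carafe_kernel % 2 == 0 or self.carafe_kernel < 3:
            raise ValueError("carafe_kernel m must be odd and >= 3")
        if self.carafe_ratio != 2:
            raise ValueError("carafe_ratio must be 2 (four x2 up blocks = x16)")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if sum(self.loss_weights) <= 0:
            raise ValueError("loss weights must not both be zero")
        if not 0.0 < self.leaky_slope < 1.0:
            raise ValueError("leaky_slope must be in (0, 1)")

    @property
    def encoder_channels(self) -> Tuple[int, ...]:
        return tuple(self.base_channels * m for m in self.channel_multipliers)


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    epochs: int = 30
    seed: int = 0


@dataclass
class CalibConfig:
    order: int = 2
    # normalized six-point layout: corners + center + top-edge midpoint
    layout: Tuple[Tuple[float, float], ...] = (
        (0.1, 0.1),
        (0.9, 0.1),
        (0.1, 0.9),
        (0.9, 0.9),
        (0.5, 0.5),
        (0.5, 0.1),
    )
    screen_width: float = 1920.0
    screen_height: float = 1080.0


@dataclass
class EvalConfig:
    threshold_px: float = 5.0
    px_per_mm: float = 3.0
    viewing_distance_mm: float = 1000.0


@dataclass
class RunConfig:
    synth: SynthEyeConfig = field(default_factory=SynthEyeConfig)
    net: NetConfig = field(default_factory=NetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    calib: CalibConfig = field(default_factory=CalibConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _fill(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; missing blocks take defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        synth=_fill(SynthEyeConfig, raw.get("synth", {})),
        net=_fill(NetConfig, raw.get("net", {})),
        train=_fill(TrainConfig, raw.get("train", {})),
        calib=_fill(CalibConfig, raw.get("calib", {})),
        eval=_fill(EvalConfig, raw.get("eval", {})),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
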