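"""Seeded synthetic near-infrared eye frames and gaze sessions.

Frames emulate dark-pupil head-mounted recordings: a dark elliptical
pupil on a brighter iris/sclera, with corneal glints, eyelid occlusion,
illumination gradients, additive noise, off-axis (elliptical) pupils and
closed-eye frames. The ground-truth mask is captured *before* any
nuisance rendering, so annotations are exact by construction.

Coordinate convention: 0-based pixel indices, (x = column, y = row),
pixel centers at integer coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from pupilgaze import gazemap
from pupilgaze.config import SynthEyeConfig
from pupilgaze.gazemap import MappingModel

__all__ = [
    "PupilAnnotation",
    "EyeFrame",
    "GazeSession",
    "SplitIndex",
    "rasterize_ellipse",
    "generate_eye_frame",
    "generate_dataset",
    "generate_gaze_session",
    "default_true_model",
    "DEFAULT_PUPIL_BOX",
]

# pupil-motion box in eye-camera coordinates (x0, y0, x1, y1)
DEFAULT_PUPIL_BOX = (100.0, 100.0, 540.0, 380.0)
DEFAULT_DISPLAY_BOUNDS = (0.0, 0.0, 1920.0, 1080.0)


@dataclass
class PupilAnnotation:
    center: Tuple[float, float]  # (cx, cy) px
    semi_axes: Tuple[float, float]  # (a, b) px, a >= b
    orientation: float  # radians in [0, pi)
    closed: bool
    mask: np.ndarray  # binary uint8 grid, same shape as pixels

    def __post_init__(self):
        a, b = self.semi_axes
        if a < b:
            raise ValueError("semi-axes must satisfy a >= b")
        if not 0.0 <= self.orientation < math.pi:
            raise ValueError("orientation must lie in [0, pi)")
        if self.closed and self.mask.any():
            raise ValueError("closed frames must carry an all-zero mask")


@dataclass
class EyeFrame:
    pixels: np.ndarray  # float64 in [0, 1], shape (H, W)
    annotation: Optional[PupilAnnotation]
    frame_id: str
    eye_side: str = "left"

    def __post_init__(self):
        h, w = self.pixels.shape
        if h < 32 or w < 32 or h % 16 or w % 16:
            raise ValueError("frame size must be >= 32 and divisible by 16")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.eye_side not in ("left", "right"):
            raise ValueError("eye_side must be 'left' or 'right'")


@dataclass
class GazeSession:
    """Paired (noisy pupil vector, screen point) samples plus generation record."""

    pupil_xy: np.ndarray  # (N, 2) noisy pupil vectors
    screen_uv: np.ndarray  # (N, 2) exact screen points
    pupil_clean: np.ndarray  # (N, 2) noise-free pupil vectors
    true_model: MappingModel
    noise_sigma: float

    @property
    def samples(self) -> List[Tuple[Tuple[float, float], Tuple[float, float]]]:
        return [
            (tuple(p), tuple(s)) for p, s in zip(self.pupil_xy, self.screen_uv)
        ]

    def __len__(self) -> int:
        return len(self.pupil_xy)


@dataclass
class SplitIndex:
    train: List[int] = field(default_factory=list)
    val: List[int] = field(default_factory=list)
    test: List[int] = field(default_factory=list)


def rasterize_ellipse(
    shape: Tuple[int, int],
    center: Tuple[float, float],
    semi_axes: Tuple[float, float],
    orientation: float,
) -> np.ndarray:
    """Binary mask of pixel centers inside the ellipse inequality."""
    h, w = shape
    cx, cy = center
    a, b = semi_axes
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - cx
    dy = yy - cy
    ct, st = math.cos(orientation), math.sin(orientation)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return inside.astype(np.uint8)


def _draw_disc(img: np.ndarray, center, radius, value) -> None:
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    img[(xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2] = value


def generate_eye_frame(
    config: SynthEyeConfig,
    seed: int,
    *,
    center: Optional[Tuple[float, float]] = None,
    closed: Optional[bool] = None,
    frame_id: Optional[str] = None,
    eye_side: str = "left",
) -> EyeFrame:
    """Render one frame with an exact annotation.

    Nuisance features (eyelid, glints, illumination gradient, noise) are
    applied after the mask is captured, so the annotation always refers
    to the clean geometry. Identical (config, seed) gives bit-identical
    output. ``center``/``closed`` override the sampled values (used by
    the calibration pipeline).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    h, w = config.height, config.width

    # geometry -- sampled even when overridden so the seed stream is stable
    a = rng.uniform(*config.pupil_radius_range)
    ratio = rng.uniform(*config.aspect_ratio_range)
    b = a * ratio
    theta = rng.uniform(0.0, math.pi)
    margin = a + 1.0
    cx = rng.uniform(margin, w - 1 - margin)
    cy = rng.uniform(margin, h - 1 - margin)
    is_closed = bool(rng.random() < config.closed_prob)
    if center is not None:
        cx, cy = float(center[0]), float(center[1])
    if closed is not None:
        is_closed = bool(closed)

    pupil_val = rng.uniform(*config.pupil_intensity_range)
    iris_val = rng.uniform(*config.iris_intensity_range)
    sclera_val = rng.uniform(*config.sclera_intensity_range)
    skin_val = min(1.0, sclera_val * rng.uniform(0.9, 1.1))

    img = np.full((h, w), sclera_val, dtype=np.float64)
    _draw_disc(img, (cx, cy), a * rng.uniform(2.0, 2.8), iris_val)
    ellipse = rasterize_ellipse((h, w), (cx, cy), (a, b), theta)
    img[ellipse == 1] = pupil_val

    # ground truth captured now; everything below is nuisance
    mask = np.zeros((h, w), dtype=np.uint8) if is_closed else ellipse.copy()
    annotation = PupilAnnotation(
        center=(cx, cy), semi_axes=(a, b), orientation=theta, closed=is_closed, mask=mask
    )

    if is_closed:
        # eyelid band covering the whole pupil (>= 90% coverage rule)
        lid_edge = int(math.ceil(cy + b + 2))
        img[: min(h, lid_edge), :] = skin_val
    elif rng.random() < config.partial_occlusion_prob:
        # partial lid covers at most ~40% of the pupil, still labeled open
        frac = rng.uniform(0.05, 0.4)
        lid_edge = int(round(cy - b + frac * 2 * b))
        if lid_edge > 0:
            img[: min(h, lid_edge), :] = skin_val

    n_glints = int(rng.integers(config.glint_count_range[0], config.glint_count_range[1] + 1))
    for _ in range(n_glints):
        gx = cx + rng.uniform(-2.5 * a, 2.5 * a)
        gy = cy + rng.uniform(-2.5 * a, 2.5 * a)
        gr = rng.uniform(*config.glint_radius_range)
        _draw_disc(img, (gx, gy), gr, 1.0)

    grad_mag = rng.uniform(*config.illumination_gradient_range)
    angle = rng.uniform(0.0, 2 * math.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = (xx / max(w - 1, 1)) * math.cos(angle) + (yy / max(h - 1, 1)) * math.sin(angle)
    img = img + grad_mag * (ramp - ramp.mean())

    if config.noise_sigma > 0:
        img = img + rng.normal(0.0, config.noise_sigma, size=(h, w))

    img = np.clip(img, 0.0, 1.0)
    fid = frame_id if frame_id is not None else f"synth_{seed:08d}"
    return EyeFrame(pixels=img, annotation=annotation, frame_id=fid, eye_side=eye_side)


def split_indices(n: int, seed: int) -> SplitIndex:
    """70/15/15 split: floor-rounded val/test, remainder to train."""
    n_val = int(math.floor(0.15 * n))
    n_test = int(math.floor(0.15 * n))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(
        train=sorted(int(i) for i in perm[n_val + n_test :]),
        val=sorted(int(i) for i in perm[:n_val]),
        test=sorted(int(i) for i in perm[n_val : n_val + n_test]),
    )


def generate_dataset(
    config: SynthEyeConfig, n: int, seed: int
) -> Tuple[List[EyeFrame], SplitIndex]:
    """Generate n frames plus a stable pseudorandom 70/15/15 split."""
    if n < 10:
        raise ValueError("dataset size must be at least 10")
    root = np.random.default_rng(seed)
    frame_seeds = root.integers(0, 2**63 - 1, size=n)
    frames = [
        generate_eye_frame(config, int(s), frame_id=f"frame_{i:05d}")
        for i, s in enumerate(frame_seeds)
    ]
    return frames, split_indices(n, seed)


def default_true_model(
    seed: int = 0,
    pupil_box: Tuple[float, float, float, float] = DEFAULT_PUPIL_BOX,
    screen: Tuple[float, float] = (1920.0, 1080.0),
) -> MappingModel:
    """A gently nonlinear second-order model mapping ``pupil_box`` into a
    ``screen``-sized display with margin (exact by construction)."""
    x0, y0, x1, y1 = pupil_box
    mx, sx = (x0 + x1) / 2, (x1 - x0) / 2
    my, sy = (y0 + y1) / 2, (y1 - y0) / 2
    sw, sh = screen
    rng = np.random.default_rng(seed)
    # quadratic gains in normalized coords, small relative to the linear span
    qu = rng.uniform(0.005, 0.02, size=3) * sw
    qv = rng.uniform(0.005, 0.02, size=3) * sh

    def ref(x, y):
        t, s = (x - mx) / sx, (y - my) / sy
        u = 0.5 * sw + 0.4 * sw * t + qu[0] * t * t + qu[1] * t * s + qu[2] * s * s
        v = 0.5 * sh + 0.35 * sh * s + qv[0] * t * t + qv[1] * t * s + qv[2] * s * s
        return u, v

    # recover raw-coordinate coefficients by exact interpolation
    pts = np.array(
        [(x0, y0), (x1, y0), (x0, y1), (x1, y1), (mx, my), (mx, y0)], dtype=float
    )
    uv = np.array([ref(x, y) for x, y in pts])
    return gazemap.fit(gazemap.CalibrationSet(pts, uv), n=2)


def generate_gaze_session(
    true_model: MappingModel,
    n_points: int,
    noise_sigma: float,
    seed: int,
    *,
    pupil_box: Tuple[float, float, float, float] = DEFAULT_PUPIL_BOX,
    display_bounds: Optional[Tuple[float, float, float, float]] = DEFAULT_DISPLAY_BOUNDS,
    pupil_xy: Optional[Sequence[Tuple[float, float]]] = None,
) -> GazeSession:
    """Sample a calibration/gaze session from a known generating model.

    Pupil vectors are drawn uniformly over ``pupil_box`` (or taken from
    ``pupil_xy`` when given, e.g. a calibration layout); screen points
    are the exact polynomial images of the clean vectors; Gaussian noise
    of sd ``noise_sigma`` is then added to the pupil vectors.
    """
    if true_model.order not in (1, 2):
        raise ValueError("true_model order must be 1 or 2")
    if n_points < true_model.m:
        raise ValueError(
            f"n_points={n_points} is under-determined for an order-"
            f"{true_model.order} model (needs >= {true_model.m})"
        )
    rng = np.random.default_rng(seed)
    if pupil_xy is not None:
        clean = np.asarray(pupil_xy, dtype=float)
        if len(clean) != n_points:
            raise ValueError("pupil_xy length must equal n_points")
    else:
        x0, y0, x1, y1 = pupil_box
        clean = np.column_stack(
            [rng.uniform(x0, x1, size=n_points), rng.uniform(y0, y1, size=n_points)]
        )
    screen = gazemap.predict(true_model, clean)
    if display_bounds is not None:
        u0, v0, u1, v1 = display_bounds
        if (
            screen[:, 0].min() < u0
            or screen[:, 0].max() > u1
            or screen[:, 1].min() < v0
            or screen[:, 1].max() > v1
        ):
            raise ValueError("generated screen points fall outside the display bounds")
    noisy = clean + rng.normal(0.0, noise_sigma, size=clean.shape) if noise_sigma > 0 else clean.copy()
    return GazeSession(
        pupil_xy=noisy,
        screen_uv=screen,
        pupil_clean=clean,
        true_model=true_model,
        noise_sigma=noise_sigma,
    )
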