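"""Pupil measurements from a segmentation probability map.

Threshold, keep the largest 8-connected component, take the
intensity-weighted centroid as the pupil center, and fit the ellipse
(semi-axes, orientation) from second-order central moments. The reported
diameter is the major-axis length 2a; orientation/axes stand in for the
two-axis rotational attitude of the eye.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

__all__ = ["PupilState", "extract_pupil", "pixel_error", "MIN_COMPONENT_PIXELS"]

MIN_COMPONENT_PIXELS = 10
_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class PupilState:
    center: Tuple[float, float]  # (cx, cy) px
    semi_axes: Tuple[float, float]  # (a, b) px, a >= b
    orientation: float  # radians in [0, pi)
    diameter: float  # = 2a
    closed: bool
    valid: bool

    @classmethod
    def invalid(cls, closed: bool = False) -> "PupilState":
        return cls(
            center=(math.nan, math.nan),
            semi_axes=(math.nan, math.nan),
            orientation=math.nan,
            diameter=math.nan,
            closed=closed,
            valid=False,
        )


def extract_pupil(prob_map: np.ndarray, threshold: float = 0.5) -> PupilState:
    """Measure the pupil from a per-pixel probability map.

    Degenerate inputs (empty or < MIN_COMPONENT_PIXELS largest
    component) give valid=False, never an exception.
    """
    p = np.asarray(prob_map, dtype=np.float64)
    if p.ndim != 2:
        raise ValueError("prob_map must be 2-D")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("prob_map values must lie in [0, 1]")
    binary = p >= threshold
    if not binary.any():
        return PupilState.invalid()
    labels, n_comp = ndimage.label(binary, structure=_EIGHT_CONN)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n_comp + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < MIN_COMPONENT_PIXELS:
        return PupilState.invalid()
    comp = labels == best
    weights = np.where(comp, p, 0.0)
    total = weights.sum()
    yy, xx = np.nonzero(comp)
    wv = weights[yy, xx]
    cx = float((wv * xx).sum() / total)
    cy = float((wv * yy).sum() / total)

    dx = xx - cx
    dy = yy - cy
    mu20 = float((wv * dx * dx).sum() / total)
    mu02 = float((wv * dy * dy).sum() / total)
    mu11 = float((wv * dx * dy).sum() / total)
    cov = np.array([[mu20, mu11], [mu11, mu02]])
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lmin, lmax = max(evals[0], 0.0), max(evals[1], 0.0)
    # uniform ellipse: second moment along an axis = (semi-axis)^2 / 4
    a = 2.0 * math.sqrt(lmax)
    b = 2.0 * math.sqrt(lmin)
    vx, vy = evecs[:, 1]  # major-axis direction
    theta = math.atan2(vy, vx) % math.pi
    return PupilState(
        center=(cx, cy),
        semi_axes=(a, b),
        orientation=theta,
        diameter=2.0 * a,
        closed=False,
        valid=True,
    )


def pixel_error(state: PupilState, truth) -> float:
    """Euclidean distance between detected and ground-truth centers.

    Comparing against a closed-eye truth (or an invalid detection) is
    undefined and returns NaN so callers can exclude it from rate
    denominators.
    """
    truth_closed = getattr(truth, "closed", False)
    if truth_closed or not state.valid:
        return math.nan
    tx, ty = truth.center
    return math.hypot(state.center[0] - tx, state.center[1] - ty)
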