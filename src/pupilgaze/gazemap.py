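"""Polynomial pupil-vector -> screen-coordinate calibration.

The mapping is a pair of bivariate polynomials of total degree ``n``
(default 2, the six-coefficient form)::

    u = A0 + A1*x + A2*y + A3*x^2 + A4*x*y + A5*y^2
    v = B0 + B1*x + B2*y + B3*x^2 + B4*x*y + B5*y^2

With exactly m calibration points the coefficients solve the square
system directly; with more points they minimize the mean squared
deviation (least squares).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np

__all__ = [
    "MappingModel",
    "CalibrationSet",
    "coefficient_count",
    "design_matrix",
    "fit",
    "predict",
    "predict_binocular",
    "save_model",
    "load_model",
]


def coefficient_count(n: int) -> int:
    """Number of coefficients m = 1 + sum_{i=1..n}(1 + i) per output axis.

    Equals the number of 2-variable monomials of total degree <= n:
    n=1 -> 3, n=2 -> 6, n=3 -> 10.
    """
    if n < 1:
        raise ValueError("polynomial order must be >= 1")
    return 1 + sum(1 + i for i in range(1, n + 1))


def _monomials(x: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Columns ordered [1, x, y, x^2, xy, y^2, x^3, x^2 y, ...]."""
    cols = [np.ones_like(x)]
    for deg in range(1, n + 1):
        for j in range(deg + 1):
            cols.append(x ** (deg - j) * y**j)
    return np.column_stack(cols)


def design_matrix(pupil_xy: np.ndarray, n: int) -> np.ndarray:
    pts = np.asarray(pupil_xy, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("pupil vectors must be an (N, 2) array")
    return _monomials(pts[:, 0], pts[:, 1], n)


@dataclass
class MappingModel:
    order: int
    A: np.ndarray  # length m, maps to u
    B: np.ndarray  # length m, maps to v

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        m = coefficient_count(self.order)
        if self.A.shape != (m,) or self.B.shape != (m,):
            raise ValueError(f"order {self.order} requires coefficient vectors of length {m}")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise ValueError("coefficients must be finite")

    @property
    def m(self) -> int:
        return coefficient_count(self.order)


@dataclass
class CalibrationSet:
    """Paired (pupil vector, screen target) observations."""

    pupil_xy: np.ndarray  # (N, 2)
    screen_uv: np.ndarray  # (N, 2)

    def __post_init__(self):
        self.pupil_xy = np.asarray(self.pupil_xy, dtype=float)
        self.screen_uv = np.asarray(self.screen_uv, dtype=float)
        if self.pupil_xy.shape != self.screen_uv.shape or self.pupil_xy.ndim != 2:
            raise ValueError("pupil and screen arrays must both be (N, 2)")

    def __len__(self) -> int:
        return len(self.pupil_xy)


def fit(calib: CalibrationSet, n: int = 2) -> MappingModel:
    """Solve for the mapping coefficients.

    Exactly m points: direct solve of the square system. More than m:
    least squares (pseudoinverse), which minimizes the mean squared
    deviation between targets and mapped pupil vectors.

    Raises
    ------
    ValueError
        If fewer than m points are supplied or the design matrix is
        rank-deficient (e.g. collinear calibration points for n=2).
    """
    m = coefficient_count(n)
    if len(calib) < m:
        raise ValueError(f"order {n} needs at least {m} calibration points, got {len(calib)}")
    M = design_matrix(calib.pupil_xy, n)
    rank = np.linalg.matrix_rank(M)
    if rank < m:
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {m}); "
            "calibration points are degenerate (e.g. collinear)"
        )
    u = calib.screen_uv[:, 0]
    v = calib.screen_uv[:, 1]
    if len(calib) == m:
        A = np.linalg.solve(M, u)
        B = np.linalg.solve(M, v)
    else:
        A, *_ = np.linalg.lstsq(M, u, rcond=None)
        B, *_ = np.linalg.lstsq(M, v, rcond=None)
    return MappingModel(order=n, A=A, B=B)


def predict(model: MappingModel, pupil_xy) -> np.ndarray:
    """Map pupil vector(s) to screen coordinates. Pure function.

    Accepts a single (x, y) pair or an (N, 2) array; returns the same
    arrangement.
    """
    pts = np.asarray(pupil_xy, dtype=float)
    single = pts.ndim == 1
    if single:
        pts = pts[None, :]
    M = design_matrix(pts, model.order)
    uv = np.column_stack([M @ model.A, M @ model.B])
    return uv[0] if single else uv


def predict_binocular(left: MappingModel, right: MappingModel, left_xy, right_xy) -> np.ndarray:
    """Average the per-eye predictions (documented default fusion)."""
    return 0.5 * (predict(left, left_xy) + predict(right, right_xy))


def save_model(model: MappingModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"order": model.order, "A": model.A.tolist(), "B": model.B.tolist()},
            fh,
            sort_keys=True,
        )


def load_model(path: str | Path) -> MappingModel:
    with open(path) as fh:
        d = json.load(fh)
    return MappingModel(order=d["order"], A=np.array(d["A"]), B=np.array(d["B"]))


def six_point_targets(layout: Sequence[Tuple[float, float]], width: float, height: float) -> np.ndarray:
    """Scale a normalized layout onto a width x height screen."""
    pts = np.asarray(layout, dtype=float)
    return pts * np.array([width, height])
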