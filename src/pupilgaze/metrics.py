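"""Evaluation metrics: 5-pixel detection rate, confusion-matrix
precision, RMSE, angular error between gaze vectors, per-target
localization error, and k-fold cross-validation of the gaze mapping."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from pupilgaze import gazemap
from pupilgaze.gazemap import CalibrationSet
from pupilgaze.synthdata import GazeSession

__all__ = [
    "MetricsReport",
    "five_pixel_rate",
    "precision",
    "rmse",
    "angular_error",
    "gaze_angles_from_screen",
    "localization_error",
    "cross_validate",
    "CrossValResult",
]


@dataclass
class MetricsReport:
    five_px_rate: Optional[float] = None
    precision: Optional[float] = None
    rmse: Optional[float] = None
    mean_angular_error_deg: Optional[float] = None
    localization_errors: List[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "five_px_rate": self.five_px_rate,
            "precision": self.precision,
            "rmse": self.rmse,
            "mean_angular_error_deg": self.mean_angular_error_deg,
            "localization_errors": list(self.localization_errors),
        }


def five_pixel_rate(errors: Sequence[float], threshold: float = 5.0) -> float:
    """Fraction of center errors strictly below the threshold.

    NaN entries (undefined comparisons, e.g. closed-eye truths) are
    excluded from the denominator.
    """
    arr = np.asarray(list(errors), dtype=float)
    if arr.size == 0:
        raise ValueError("error list must be nonempty")
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no defined errors to rate")
    return float((arr < threshold).mean())


def precision(tp_counts: Sequence[int], fp_counts: Sequence[int]) -> float:
    """sum(TP) / (sum(TP) + sum(FP)) over consecutive samples."""
    tp = np.asarray(list(tp_counts), dtype=int)
    fp = np.asarray(list(fp_counts), dtype=int)
    if (tp < 0).any() or (fp < 0).any():
        raise ValueError("counts must be nonnegative")
    denom = int(tp.sum() + fp.sum())
    if denom == 0:
        raise ValueError("precision undefined: no positive predictions at all")
    return float(tp.sum() / denom)


def rmse(actual, estimated) -> float:
    """Root mean square error; 2-D entries use the Euclidean residual."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(estimated, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length/shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("need at least one sample")
    d = b - a
    if d.ndim == 1:
        sq = d**2
    else:
        sq = (d**2).sum(axis=-1)
    return float(np.sqrt(sq.mean()))


def angular_error(a, b) -> float:
    """Angle in degrees between two 3-vectors: arccos(a.b / |a||b|),
    cosine clipped to [-1, 1] against rounding."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("gaze vectors must be nonzero")
    cos = float(np.clip(a @ b / (na * nb), -1.0, 1.0))
    return math.degrees(math.acos(cos))


def gaze_angles_from_screen(
    points,
    px_per_mm: float,
    viewing_distance_mm: float,
    screen_center_px: Tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Unit gaze vectors for screen points, eye on the screen-center
    normal at the given viewing distance.

    points: (N, 2) or (2,) pixel coordinates. Returns unit 3-vectors
    (x right, y down, z toward the screen).
    """
    if viewing_distance_mm <= 0:
        raise ValueError("viewing distance must be positive")
    if px_per_mm <= 0:
        raise ValueError("px_per_mm must be positive")
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    if single:
        pts = pts[None]
    off_mm = (pts - np.asarray(screen_center_px)) / px_per_mm
    vecs = np.column_stack(
        [off_mm[:, 0], off_mm[:, 1], np.full(len(off_mm), viewing_distance_mm)]
    )
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return vecs[0] if single else vecs


def localization_error(truth: Tuple[float, float], estimate: Tuple[float, float]) -> float:
    """Euclidean distance between a target point and its estimate."""
    return math.hypot(truth[0] - estimate[0], truth[1] - estimate[1])


@dataclass
class CrossValResult:
    fold_rmse: List[float]
    mean_rmse: float
    sd_rmse: float
    fold_reports: List[MetricsReport]


def cross_validate(
    session: GazeSession,
    k_folds: int,
    order: int = 2,
    seed: int = 0,
) -> CrossValResult:
    """Seeded k-fold cross-validation of the polynomial gaze mapping.

    Each fold is held out once; the model is fitted on the remaining
    points and screen-space RMSE measured on the held-out pairs.
    Aggregate is mean +/- sd across folds.
    """
    n = len(session)
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if k_folds > n:
        raise ValueError("more folds than points")
    m = gazemap.coefficient_count(order)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k_folds)
    fold_rmse, reports = [], []
    for i, hold in enumerate(folds):
        train = np.concatenate([f for j, f in enumerate(folds) if j != i])
        if len(train) < m:
            raise ValueError(
                f"fold {i}: only {len(train)} training points for an "
                f"order-{order} model (needs >= {m})"
            )
        model = gazemap.fit(
            CalibrationSet(session.pupil_xy[train], session.screen_uv[train]), n=order
        )
        pred = gazemap.predict(model, session.pupil_xy[hold])
        truth = session.screen_uv[hold]
        fold_err = rmse(truth, pred)
        loc = [localization_error(t, p) for t, p in zip(truth, pred)]
        fold_rmse.append(fold_err)
        reports.append(MetricsReport(rmse=fold_err, localization_errors=loc))
    return CrossValResult(
        fold_rmse=fold_rmse,
        mean_rmse=float(np.mean(fold_rmse)),
        sd_rmse=float(np.std(fold_rmse)),
        fold_reports=reports,
    )
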