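"""Readers and writers for the pipeline's file formats.

Frames are 8-bit grayscale PNG; annotations and per-frame results are
CSV; mapping models are JSON; masks are 0/255 PNG.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from pupilgaze.pupilgeom import PupilState
from pupilgaze.synthdata import EyeFrame, PupilAnnotation

__all__ = [
    "save_frame_png",
    "load_frame_png",
    "save_mask_png",
    "load_mask_png",
    "write_annotations_csv",
    "read_annotations_csv",
    "write_frames",
    "load_frames",
    "write_track_csv",
    "read_track_csv",
    "write_calibration_csv",
    "read_calibration_csv",
]

ANNOTATION_COLUMNS = ["frame_id", "cx", "cy", "a", "b", "theta", "closed"]


def save_frame_png(pixels: np.ndarray, path: str | Path) -> None:
    img = np.clip(np.round(np.asarray(pixels) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


def load_frame_png(path: str | Path) -> np.ndarray:
    img = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return img / 255.0


def save_mask_png(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(mask) > 0).astype(np.uint8) * 255, mode="L").save(path)


def load_mask_png(path: str | Path) -> np.ndarray:
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.uint8)


def write_annotations_csv(frames: Sequence[EyeFrame], path: str | Path) -> None:
    rows = []
    for f in frames:
        ann = f.annotation
        rows.append(
            {
                "frame_id": f.frame_id,
                "cx": ann.center[0],
                "cy": ann.center[1],
                "a": ann.semi_axes[0],
                "b": ann.semi_axes[1],
                "theta": ann.orientation,
                "closed": int(ann.closed),
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    return df


def write_frames(frames: Sequence[EyeFrame], out_dir: str | Path,
                 with_masks: bool = True) -> None:
    """PNG frames + annotations.csv (+ masks/) under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mask_dir = out / "masks"
    if with_masks:
        mask_dir.mkdir(exist_ok=True)
    for f in frames:
        save_frame_png(f.pixels, out / f"{f.frame_id}.png")
        if with_masks:
            save_mask_png(f.annotation.mask, mask_dir / f"{f.frame_id}.png")
    write_annotations_csv(frames, out / "annotations.csv")


def load_frames(frames_dir: str | Path) -> List[EyeFrame]:
    """Load PNG frames; annotations.csv and masks/ are attached when present."""
    root = Path(frames_dir)
    ann_path = root / "annotations.csv"
    ann_by_id: Dict[str, dict] = {}
    if ann_path.exists():
        for row in read_annotations_csv(ann_path).to_dict("records"):
            ann_by_id[str(row["frame_id"])] = row
    frames = []
    for png in sorted(root.glob("*.png")):
        fid = png.stem
        try:
            pixels = load_frame_png(png)
        except Exception as e:  # unreadable frame: skip with a warning
            warnings.warn(f"skipping unreadable frame {png.name}: {e}")
            continue
        annotation: Optional[PupilAnnotation] = None
        if fid in ann_by_id:
            row = ann_by_id[fid]
            mask_path = root / "masks" / png.name
            mask = (
                load_mask_png(mask_path)
                if mask_path.exists()
                else np.zeros(pixels.shape, dtype=np.uint8)
            )
            closed = bool(int(row["closed"]))
            if closed:
                mask = np.zeros(pixels.shape, dtype=np.uint8)
            annotation = PupilAnnotation(
                center=(float(row["cx"]), float(row["cy"])),
                semi_axes=(float(row["a"]), float(row["b"])),
                orientation=float(row["theta"]),
                closed=closed,
                mask=mask,
            )
        try:
            frames.append(EyeFrame(pixels=pixels, annotation=annotation, frame_id=fid))
        except ValueError as e:  # e.g. size not divisible by 16
            warnings.warn(f"skipping frame {png.name}: {e}")
    return frames


TRACK_COLUMNS = ["frame_id", "valid", "closed", "p_close", "gate",
                 "cx", "cy", "a", "b", "theta", "diameter"]


def write_track_csv(rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(list(rows), columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_track_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def track_row(frame_id: str, state: PupilState, p_close: float, gate: int) -> dict:
    return {
        "frame_id": frame_id,
        "valid": int(state.valid),
        "closed": int(state.closed),
        "p_close": p_close,
        "gate": gate,
        "cx": state.center[0],
        "cy": state.center[1],
        "a": state.semi_axes[0],
        "b": state.semi_axes[1],
        "theta": state.orientation,
        "diameter": state.diameter,
    }


def write_calibration_csv(pupil_xy: np.ndarray, screen_uv: np.ndarray,
                          path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "point_id": range(len(pupil_xy)),
            "x": pupil_xy[:, 0],
            "y": pupil_xy[:, 1],
            "u": screen_uv[:, 0],
            "v": screen_uv[:, 1],
        }
    )
    df.to_csv(path, index=False)


def read_calibration_csv(path: str | Path):
    df = pd.read_csv(path)
    for col in ("x", "y", "u", "v"):
        if col not in df.columns:
            raise ValueError(f"calibration CSV missing column '{col}'")
    return df[["x", "y"]].to_numpy(float), df[["u", "v"]].to_numpy(float)
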