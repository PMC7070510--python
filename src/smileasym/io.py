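"""Reading and writing the OpenFace 2.0 CSV dialect.

One CSV per recording: one row per frame with columns ``frame``,
``confidence``, ``success``, the 3D landmarks as ``X_0..X_67``,
``Y_0..Y_67``, ``Z_0..Z_67`` (mm, camera coordinates), and the AU
intensity columns ``AU06_r``, ``AU12_r`` (0-5 scale).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .face import LandmarkSet, N_LANDMARKS

__all__ = ["read_openface_csv", "write_openface_csv", "frames_from_dataframe"]

_X_COLS = [f"X_{i}" for i in range(N_LANDMARKS)]
_Y_COLS = [f"Y_{i}" for i in range(N_LANDMARKS)]
_Z_COLS = [f"Z_{i}" for i in range(N_LANDMARKS)]


def frames_from_dataframe(df: pd.DataFrame) -> list[LandmarkSet]:
    """Landmark frames from an OpenFace-dialect table (one row per frame)."""
    for col in ("frame", *_X_COLS, *_Y_COLS, *_Z_COLS):
        if col not in df.columns:
            raise ValueError(f"missing OpenFace column {col!r}")
    X = df[_X_COLS].to_numpy(float)
    Y = df[_Y_COLS].to_numpy(float)
    Z = df[_Z_COLS].to_numpy(float)
    pts = np.stack([X, Y, Z], axis=2)  # (F, 68, 3)
    conf = (
        df["confidence"].to_numpy(float)
        if "confidence" in df.columns
        else np.ones(len(df))
    )
    succ = (
        df["success"].to_numpy().astype(bool)
        if "success" in df.columns
        else np.ones(len(df), bool)
    )
    frame_ids = df["frame"].to_numpy(int)
    return [
        LandmarkSet(int(frame_ids[i]), pts[i], float(conf[i]), bool(succ[i]))
        for i in range(len(df))
    ]


def read_openface_csv(path) -> pd.DataFrame:
    """Read an OpenFace-dialect CSV (column names stripped of whitespace)."""
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    return df


def write_openface_csv(
    path,
    frames: Sequence[LandmarkSet],
    au: np.ndarray | None = None,
) -> None:
    """Write frames (and optional (F, 2) AU06_r/AU12_r array) as CSV."""
    frames = list(frames)
    data = {
        "frame": [f.frame_id for f in frames],
        "confidence": [f.confidence for f in frames],
        "success": [int(f.success) for f in frames],
    }
    pts = np.stack([f.points for f in frames]) if frames else np.zeros((0, 68, 3))
    for i in range(N_LANDMARKS):
        data[f"X_{i}"] = pts[:, i, 0]
    for i in range(N_LANDMARKS):
        data[f"Y_{i}"] = pts[:, i, 1]
    for i in range(N_LANDMARKS):
        data[f"Z_{i}"] = pts[:, i, 2]
    if au is not None:
        au = np.asarray(au, float)
        data["AU06_r"] = au[:, 0]
        data["AU12_r"] = au[:, 1]
    pd.DataFrame(data).to_csv(Path(path), index=False, float_format="%.6f")
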