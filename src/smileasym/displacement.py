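"""Per-landmark displacement intensities and regional aggregation.

After a smile frame is registered onto the subject's neutral reference,
the per-landmark Euclidean distance between the two sets is the landmark's
displacement "intensity" for that frame.  Regional intensities sum the
per-landmark distances within a (region, hemiface) index set per frame and
average across frames, yielding one value per subject × condition ×
region × side — the unit of the downstream repeated-measures analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .face import LandmarkSet, N_LANDMARKS, RegionMap, validate_landmark_set

__all__ = [
    "DisplacementProfile",
    "displacement_profile",
    "neutral_reference",
    "aligned_neutral_reference",
    "region_intensity",
    "normalized_landmark_error",
    "build_intensity_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DisplacementProfile:
    """68 per-landmark displacement magnitudes (mm) for one aligned frame."""

    frame_id: int
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (N_LANDMARKS,):
            raise ValueError(f"expected {N_LANDMARKS} distances, got {d.shape}")
        if not np.all(np.isfinite(d)) or np.any(d < 0):
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "distances", d)


def displacement_profile(
    aligned_smile: LandmarkSet, neutral_ref: LandmarkSet
) -> DisplacementProfile:
    """Per-landmark Euclidean distances between two co-registered sets."""
    validate_landmark_set(aligned_smile)
    validate_landmark_set(neutral_ref)
    d = np.linalg.norm(aligned_smile.points - neutral_ref.points, axis=1)
    return DisplacementProfile(aligned_smile.frame_id, d)


def neutral_reference(neutral_frames: Sequence[LandmarkSet]) -> LandmarkSet:
    """Coordinate-wise median over neutral frames.

    The median is robust to transient neutral-condition events (blinks,
    micro-expressions) that would bias a mean template.
    """
    frames = [validate_landmark_set(f) for f in neutral_frames]
    if not frames:
        raise ValueError("no usable neutral frames")
    stack = np.stack([f.points for f in frames])
    med = np.median(stack, axis=0)
    conf = float(np.mean([f.confidence for f in frames]))
    return LandmarkSet(frames[0].frame_id, med, conf, True)


def aligned_neutral_reference(
    neutral_frames: Sequence[LandmarkSet],
    fid=None,
    with_scale: bool = True,
) -> LandmarkSet:
    """Neutral reference from frames that still carry per-frame head pose.

    Each neutral frame is first registered onto the first neutral frame
    (fiducial-anchored), then the coordinate-wise median is taken — a raw
    median across differently posed frames would smear the template.
    """
    from .align import batch_align

    frames = [validate_landmark_set(f) for f in neutral_frames]
    if not frames:
        raise ValueError("no usable neutral frames")
    if len(frames) == 1:
        return frames[0]
    pairs = batch_align(frames, frames[0], fid, with_scale=with_scale,
                        confidence_threshold=0.0)
    return neutral_reference([a for a, _ in pairs])


def region_intensity(
    profiles: Sequence[DisplacementProfile],
    rm: RegionMap,
    region: str,
    side: str = "both",
    per_landmark: str = "sum",
) -> float:
    """Aggregate displacement intensity of a (region, side) across frames.

    Per frame, the per-landmark distances over the region ∩ side index set
    are combined by ``per_landmark`` ("sum", the default, or "mean"); the
    per-frame values are then averaged across frames so recordings of
    different lengths stay comparable.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one displacement profile is required")
    idx = rm.indexes(region, side)
    if idx.size == 0:
        raise KeyError(f"region {region!r} has no landmarks on side {side!r}")
    stack = np.stack([p.distances for p in profiles])[:, idx]
    if per_landmark == "sum":
        per_frame = stack.sum(axis=1)
    elif per_landmark == "mean":
        per_frame = stack.mean(axis=1)
    else:
        raise ValueError(f"unknown per_landmark mode {per_landmark!r}")
    return float(per_frame.mean())


def _eye_centers(pts: np.ndarray, rm: RegionMap) -> tuple[np.ndarray, np.ndarray]:
    left = pts[rm.indexes("eye_left")].mean(0)
    right = pts[rm.indexes("eye_right")].mean(0)
    return left, right


def normalized_landmark_error(
    predicted: LandmarkSet,
    truth: LandmarkSet,
    scale_mode: str = "interocular",
    d_scale: float | None = None,
    statistic: str = "mean",
    region_map: RegionMap | None = None,
) -> float:
    """Size-normalized landmark error ε = (1/L) Σᵢ d(x̃ᵢ, xᵢ) / d_scale.

    ``scale_mode="interocular"`` takes d_scale as the distance between the
    two eye centres (mean of each eye's landmark ring) of the ground-truth
    set; ``"custom"`` requires ``d_scale``.  ``statistic="median"`` replaces
    the mean over landmarks with a median.
    """
    validate_landmark_set(predicted)
    validate_landmark_set(truth)
    if scale_mode == "interocular":
        from .face import default_region_map

        rm = region_map or default_region_map()
        cl, cr = _eye_centers(truth.points, rm)
        d_scale = float(np.linalg.norm(cl - cr))
    elif scale_mode != "custom":
        raise ValueError(f"unknown scale_mode {scale_mode!r}")
    if d_scale is None or d_scale <= 0:
        raise ValueError("d_scale must be a positive number")
    d = np.linalg.norm(predicted.points - truth.points, axis=1)
    if statistic == "mean":
        return float(d.mean() / d_scale)
    if statistic == "median":
        return float(np.median(d) / d_scale)
    raise ValueError(f"unknown statistic {statistic!r}")


def build_intensity_table(
    cohort: Mapping[str, Mapping[str, Sequence[DisplacementProfile]]],
    rm: RegionMap,
    per_landmark: str = "sum",
    conditions: tuple = ("posed", "spontaneous"),
    regions: tuple | None = None,
) -> pd.DataFrame:
    """Tidy per-subject intensity table for the repeated-measures analysis.

    ``cohort`` maps subject_id → condition → aligned displacement profiles.
    Returns one row per subject × condition × region × side (left/right)
    with columns subject_id, condition, region, side, intensity.  Subjects
    missing any required condition are excluded with a warning
    (complete-case analysis).  With the default "sum" aggregation,
    composite-region rows equal the sum of their primitive parts.
    """
    regions = tuple(regions or RegionMap.ANALYSIS_REGIONS)
    rows = []
    for subject_id in sorted(cohort):
        per_cond = cohort[subject_id]
        if any(c not in per_cond or not len(per_cond[c]) for c in conditions):
            logger.warning(
                "subject %s missing a condition; excluded from intensity table",
                subject_id,
            )
            continue
        for condition in conditions:
            profiles = per_cond[condition]
            for region in regions:
                for side in ("left", "right"):
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "condition": condition,
                            "region": region,
                            "side": side,
                            "intensity": region_intensity(
                                profiles, rm, region, side, per_landmark
                            ),
                        }
                    )
    return pd.DataFrame(
        rows, columns=["subject_id", "condition", "region", "side", "intensity"]
    )
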