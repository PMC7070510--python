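"""Action-unit intensity summaries from OpenFace-dialect AU columns.

AU06 (cheek raiser, orbicularis oculi) and AU12 (lip corner puller,
zygomatic major) intensities on the OpenFace 0-5 scale are consumed as
features; per subject × condition they are summarised to a mean over
quality-passing frames, optionally baselined against the subject's own
neutral condition (person-specific normalization), clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["AuRecord", "summarize_au", "build_au_table"]

AU_COLUMNS = ("AU06_r", "AU12_r")


@dataclass(frozen=True)
class AuRecord:
    subject_id: str
    condition: str
    au06: float
    au12: float

    def __post_init__(self) -> None:
        if self.au06 < 0 or self.au12 < 0:
            raise ValueError("AU intensities must be non-negative")

    @property
    def au_sum(self) -> float:
        """Combined AU06 + AU12 intensity."""
        return self.au06 + self.au12


def _frame_filter(frames: pd.DataFrame, confidence_threshold: float) -> pd.DataFrame:
    keep = frames
    if "success" in frames.columns:
        keep = keep[keep["success"].astype(bool)]
    if "confidence" in frames.columns:
        keep = keep[keep["confidence"] >= confidence_threshold]
    return keep


def summarize_au(
    frames: pd.DataFrame,
    subject_id: str = "",
    condition: str = "",
    baseline: tuple[float, float] | None = None,
    statistic: str = "mean",
    confidence_threshold: float = 0.75,
) -> AuRecord:
    """Per-condition AU06/AU12 summary over quality-passing frames.

    ``frames`` needs AU06_r and AU12_r columns (success/confidence used
    for filtering when present).  ``baseline`` is the subject's neutral
    (AU06, AU12) means; when given it is subtracted and the result clipped
    at 0, since negative AU intensity is meaningless.  ``statistic`` is
    "mean" (default), "max", or "p90".
    """
    keep = _frame_filter(frames, confidence_threshold)
    if keep.empty:
        raise ValueError("no usable frames after quality filtering")
    if statistic == "mean":
        vals = [float(keep[c].mean()) for c in AU_COLUMNS]
    elif statistic == "max":
        vals = [float(keep[c].max()) for c in AU_COLUMNS]
    elif statistic == "p90":
        vals = [float(np.percentile(keep[c], 90)) for c in AU_COLUMNS]
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if baseline is not None:
        vals = [max(0.0, v - b) for v, b in zip(vals, baseline)]
    return AuRecord(subject_id, condition, vals[0], vals[1])


def build_au_table(records: Sequence[AuRecord]) -> pd.DataFrame:
    """Tidy TSV-ready table: subject_id, condition, au06, au12, au_sum."""
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "condition": r.condition,
                "au06": r.au06,
                "au12": r.au12,
                "au_sum": r.au_sum,
            }
            for r in records
        ],
        columns=["subject_id", "condition", "au06", "au12", "au_sum"],
    )
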