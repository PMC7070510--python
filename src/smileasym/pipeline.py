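"""End-to-end orchestration: read → filter → align → aggregate → contrast.

The pipeline consumes a manifest mapping subjects to per-condition
OpenFace-dialect CSVs, builds each subject's neutral reference, registers
every smile frame onto it, aggregates per-landmark displacements into the
region × hemiface intensity table, summarises AU06/AU12, fits the
repeated-measures contrasts, and writes tidy TSV reports plus a run log.
Subjects failing quality in any required condition are dropped whole.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import align as _align
from .au import build_au_table, summarize_au
from .displacement import (
    aligned_neutral_reference,
    build_intensity_table,
    displacement_profile,
)
from .face import FiducialSet, RegionMap, default_region_map
from .io import frames_from_dataframe, read_openface_csv
from .model import AuContrastModel, RegionAsymmetryModel

__all__ = ["PipelineConfig", "run_pipeline", "intensity_table_from_cohort"]

logger = logging.getLogger(__name__)

SMILE_CONDITIONS = ("posed", "spontaneous")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full analysis run.

    ``manifest`` maps subject_id → condition → CSV path (relative paths
    resolved against ``input_dir``).  All thresholds and modes default to
    the package's documented conventions.
    """

    manifest: Mapping[str, Mapping[str, str]]
    input_dir: str = "."
    output_dir: str = "results"
    region_map: str = "default"
    fiducial_indexes: tuple = ()
    confidence_threshold: float = 0.75
    aggregation: str = "sum"
    with_scale: bool = True
    au_baseline: bool = True
    au_statistic: str = "mean"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold must lie in [0, 1]")
        if self.aggregation not in ("sum", "mean"):
            raise ValueError("aggregation must be 'sum' or 'mean'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "manifest" in raw and isinstance(raw["manifest"], str):
            mpath = Path(raw["manifest"])
            if not mpath.is_absolute():
                mpath = Path(path).parent / mpath
            with open(mpath) as fh:
                manifest = json.load(fh)["subjects"]
            raw["manifest"] = manifest
            raw.setdefault("input_dir", str(mpath.parent))
        return cls(**raw)

    def load_region_map(self) -> RegionMap:
        if self.region_map == "default":
            return default_region_map()
        return RegionMap.from_yaml(self.region_map)

    def load_fiducials(self) -> FiducialSet:
        if self.fiducial_indexes:
            return FiducialSet(tuple(self.fiducial_indexes))
        return FiducialSet()


def _subject_profiles(
    frames_by_cond: Mapping[str, Sequence],
    fid: FiducialSet,
    confidence_threshold: float,
    with_scale: bool,
) -> tuple[dict, list[float]]:
    """Align each smile condition onto the neutral reference; return
    condition → displacement profiles plus per-frame mean residuals."""
    neutral_kept = [
        f
        for f in frames_by_cond["neutral"]
        if f.success and f.confidence >= confidence_threshold
    ]
    if not neutral_kept:
        raise ValueError("no usable neutral frames")
    ref = aligned_neutral_reference(neutral_kept, fid, with_scale=with_scale)
    profiles: dict = {}
    residuals: list[float] = []
    for cond in SMILE_CONDITIONS:
        if cond not in frames_by_cond:
            continue
        pairs = _align.batch_align(
            frames_by_cond[cond],
            ref,
            fid,
            with_scale=with_scale,
            confidence_threshold=confidence_threshold,
        )
        profiles[cond] = [displacement_profile(a, ref) for a, _ in pairs]
        residuals.extend(ar.mean_residual for _, ar in pairs)
    return profiles, residuals


def intensity_table_from_cohort(
    cohort_frames: Mapping[str, Mapping[str, Sequence]],
    rm: RegionMap | None = None,
    fid: FiducialSet | None = None,
    aggregation: str = "sum",
    confidence_threshold: float = 0.75,
    with_scale: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Intensity table and overall mean fiducial residual for an in-memory
    cohort (subject → condition → frames, including "neutral")."""
    rm = rm or default_region_map()
    fid = fid or FiducialSet()
    profiles_by_subject: dict = {}
    residuals: list[float] = []
    for sid in sorted(cohort_frames):
        try:
            profiles, res = _subject_profiles(
                cohort_frames[sid], fid, confidence_threshold, with_scale
            )
        except ValueError as exc:
            logger.warning("subject %s dropped: %s", sid, exc)
            continue
        profiles_by_subject[sid] = profiles
        residuals.extend(res)
    table = build_intensity_table(profiles_by_subject, rm, aggregation)
    mean_res = float(np.mean(residuals)) if residuals else float("nan")
    return table, mean_res


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes intensity.tsv, au.tsv, anova_landmarks.tsv, posthoc.tsv,
    anova_au.tsv, cell_means.tsv, run.json and run.log under
    ``cfg.output_dir``; returns the bundle as in-memory objects.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("smileasym")
    root.addHandler(handler)
    root.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path) -> dict:
    rm = cfg.load_region_map()
    fid = cfg.load_fiducials()
    logger.info("pipeline config: %s", {**asdict(cfg), "manifest": "..."})
    base = Path(cfg.input_dir)
    cohort_frames: dict = {}
    au_records = []
    for sid, paths in sorted(cfg.manifest.items()):
        if any(c not in paths for c in ("neutral", *SMILE_CONDITIONS)):
            logger.warning("subject %s missing a condition file; dropped", sid)
            continue
        tables = {}
        for cond, rel in paths.items():
            p = Path(rel)
            tables[cond] = read_openface_csv(p if p.is_absolute() else base / p)
        cohort_frames[sid] = {
            cond: frames_from_dataframe(tab) for cond, tab in tables.items()
        }
        baseline = None
        if cfg.au_baseline and "neutral" in tables:
            try:
                neutral_rec = summarize_au(
                    tables["neutral"], sid, "neutral",
                    statistic=cfg.au_statistic,
                    confidence_threshold=cfg.confidence_threshold,
                )
                baseline = (neutral_rec.au06, neutral_rec.au12)
            except (ValueError, KeyError):
                logger.warning("subject %s: no neutral AU baseline", sid)
        for cond in SMILE_CONDITIONS:
            if "AU06_r" not in tables[cond].columns:
                continue
            try:
                au_records.append(
                    summarize_au(
                        tables[cond], sid, cond,
                        baseline=baseline,
                        statistic=cfg.au_statistic,
                        confidence_threshold=cfg.confidence_threshold,
                    )
                )
            except ValueError as exc:
                logger.warning("subject %s %s AU summary failed: %s", sid, cond, exc)
    if not cohort_frames:
        raise ValueError("empty cohort after filtering")

    intensity, mean_residual = intensity_table_from_cohort(
        cohort_frames, rm, fid, cfg.aggregation,
        cfg.confidence_threshold, cfg.with_scale,
    )
    logger.info("mean fiducial residual over all aligned pairs: %.4f mm",
                mean_residual)
    intensity.to_csv(out / "intensity.tsv", sep="\t", index=False)

    landmark_results = RegionAsymmetryModel(
        intensity, regions=RegionMap.ANALYSIS_REGIONS
    ).fit()
    landmark_results.to_frame().to_csv(
        out / "anova_landmarks.tsv", sep="\t", index=False
    )
    landmark_results.cell_table().to_csv(
        out / "cell_means.tsv", sep="\t", index=False
    )
    posthoc_rows = [
        {
            "region": region,
            "contrast": r.contrast,
            "t": r.t_value,
            "p_raw": r.p_raw,
            "p_adjusted": r.p_adjusted,
            "direction": r.direction,
        }
        for region, results in landmark_results.posthoc.items()
        for r in results
    ]
    pd.DataFrame(posthoc_rows).to_csv(out / "posthoc.tsv", sep="\t", index=False)

    au_table = build_au_table(au_records)
    au_results = None
    au_table.to_csv(out / "au.tsv", sep="\t", index=False)
    if not au_table.empty:
        au_results = AuContrastModel(au_table).fit()
        au_results.to_frame().to_csv(out / "anova_au.tsv", sep="\t", index=False)

    meta = {
        "n_subjects": int(intensity["subject_id"].nunique()),
        "mean_fiducial_residual_mm": mean_residual,
        "config": {**asdict(cfg), "manifest": sorted(cfg.manifest)},
    }
    with open(out / "run.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return {
        "intensity": intensity,
        "au": au_table,
        "landmark_results": landmark_results,
        "au_results": au_results,
        "mean_fiducial_residual_mm": mean_residual,
        "meta": meta,
    }
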