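"""Replicated validation studies of the analysis pipeline.

Simulation studies used to validate the pipeline's statistical behaviour:
type-I error calibration of the within-subject contrasts under an
exchangeable Gaussian null, and detection power plus direction agreement
on default-parameter synthetic cohorts whose injected effects follow the
smile-asymmetry pattern the analysis is designed to detect (spontaneous
upper face > posed, posed mouth > spontaneous, left eyebrow > right,
no nose effect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RegionAsymmetryModel
from .face import RegionMap
from .pipeline import intensity_table_from_cohort
from .simulate import CohortSpec, simulate_subject
from .stats import ALPHA, rm_anova_twoway

__all__ = [
    "null_calibration_study",
    "effect_direction_study",
    "EffectStudyResult",
]

#: Main-effect directions injected by the default generator, in the form
#: (region, effect, expected direction string).
EXPECTED_DIRECTIONS = (
    ("eyebrow", "expression", "Spontaneous > Posed"),
    ("eye", "expression", "Spontaneous > Posed"),
    ("outline", "expression", "Spontaneous > Posed"),
    ("upper_face", "expression", "Spontaneous > Posed"),
    ("mouth", "expression", "Posed > Spontaneous"),
    ("eyebrow", "side", "Left > Right"),
)


def null_calibration_study(
    n_subjects: int = 57,
    n_replicates: int = 2000,
    seed: int = 0,
    alpha: float = ALPHA,
) -> dict:
    """Rejection rate of each 2×2 RM-ANOVA effect under a true null.

    Per replicate, per-subject cell values are an exchangeable Gaussian
    (a common subject level plus independent cell noise), so no effect is
    real and each rejection rate should sit at the nominal alpha.
    """
    rng = np.random.default_rng(seed)
    effects = ("expression", "side", "interaction")
    rejections = {eff: 0 for eff in effects}
    cell_names = (
        "posed_left", "posed_right", "spontaneous_left", "spontaneous_right"
    )
    for _ in range(n_replicates):
        subject_level = rng.normal(0.0, 3.0, n_subjects)
        cells = {
            name: subject_level + rng.normal(0.0, 1.0, n_subjects)
            for name in cell_names
        }
        res = rm_anova_twoway(cells)
        for eff in effects:
            rejections[eff] += res.p_values[eff] < alpha
    return {eff: rejections[eff] / n_replicates for eff in effects}


@dataclass(frozen=True)
class EffectStudyResult:
    power_expression_upper_face: float
    power_side_eyebrow: float
    nose_false_positive_rate: float
    direction_agreement: float
    n_replicates: int
    n_subjects: int


def _simulate_cohort_frames(spec: CohortSpec) -> dict:
    out = {}
    for i in range(spec.n_subjects):
        sub = simulate_subject(spec, i)
        out[sub.subject_id] = sub.frames
    return out


def effect_direction_study(
    n_subjects: int = 50,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = ALPHA,
) -> EffectStudyResult:
    """Power, direction agreement, and null-region false-positive rate.

    Each replicate simulates a fresh default-parameter cohort, runs the
    full pipeline (align → displace → aggregate → 2×2 RM-ANOVA) and
    scores: detection (p < alpha with the injected direction) of the
    expression effect in the upper face and the side effect in the
    eyebrow; whether all injected main-effect directions are reproduced;
    and rejection of the expression effect in the nose, which carries no
    injected effect and estimates the empirical type-I error end to end.
    """
    rng = np.random.default_rng(seed)
    hits_upper = hits_side = nose_fp = dirs_ok = 0
    for _ in range(n_replicates):
        spec = CohortSpec(
            n_subjects=n_subjects, seed=int(rng.integers(2**31))
        )
        table, _ = intensity_table_from_cohort(_simulate_cohort_frames(spec))
        res = RegionAsymmetryModel(
            table, regions=RegionMap.ANALYSIS_REGIONS
        ).fit()
        anova = res.anova
        if (
            anova["upper_face"].p_values["expression"] < alpha
            and res.direction("upper_face", "expression") == "Spontaneous > Posed"
        ):
            hits_upper += 1
        if (
            anova["eyebrow"].p_values["side"] < alpha
            and res.direction("eyebrow", "side") == "Left > Right"
        ):
            hits_side += 1
        if anova["nose"].p_values["expression"] < alpha:
            nose_fp += 1
        signs_ok = all(
            np.sign(
                _effect_sign(anova[region].effect_table, effect)
            ) == (1 if expected.split(" > ")[0] in ("Spontaneous", "Left") else -1)
            for region, effect, expected in EXPECTED_DIRECTIONS
        )
        dirs_ok += signs_ok
    return EffectStudyResult(
        power_expression_upper_face=hits_upper / n_replicates,
        power_side_eyebrow=hits_side / n_replicates,
        nose_false_positive_rate=nose_fp / n_replicates,
        direction_agreement=dirs_ok / n_replicates,
        n_replicates=n_replicates,
        n_subjects=n_subjects,
    )


def _effect_sign(effect_table: dict, effect: str) -> float:
    pl = effect_table["posed_left"][0]
    pr = effect_table["posed_right"][0]
    sl = effect_table["spontaneous_left"][0]
    sr = effect_table["spontaneous_right"][0]
    if effect == "expression":
        return (sl + sr) - (pl + pr)  # positive: Spontaneous > Posed
    if effect == "side":
        return (pl + sl) - (pr + sr)  # positive: Left > Right
    raise ValueError(f"unknown effect {effect!r}")
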