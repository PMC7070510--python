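"""Within-subject ANOVA contrasts for the smile-asymmetry design.

All factors here have exactly two levels (expression: posed vs.
spontaneous; side: left vs. right), so every repeated-measures ANOVA
effect reduces to a paired t test on the corresponding within-subject
contrast, with F = t² on (1, n−1) degrees of freedom.  Sphericity is
trivially satisfied with two levels, so no Greenhouse–Geisser correction
is applied.  Post-hoc pairwise comparisons are paired t tests with
Bonferroni adjustment p_adj = min(1, m·p_raw).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RmAnovaResult",
    "PostHocResult",
    "paired_t",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "bonferroni_posthoc",
    "DEFAULT_POSTHOC_FAMILY",
]

ALPHA = 0.05


@dataclass(frozen=True)
class RmAnovaResult:
    """F statistics and p-values for a within-subject design.

    ``effect_table`` carries per-cell (mean, sd) keyed by cell label.
    """

    factor_names: tuple
    f_values: dict
    df_pairs: dict
    p_values: dict
    effect_table: dict = field(default_factory=dict)
    n_subjects: int = 0

    def __post_init__(self) -> None:
        for eff, f in self.f_values.items():
            if f < 0:
                raise ValueError(f"negative F for effect {eff!r}")
            p = self.p_values[eff]
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value outside [0,1] for effect {eff!r}")


@dataclass(frozen=True)
class PostHocResult:
    contrast: str
    t_value: float
    p_raw: float
    p_adjusted: float
    direction: str

    def __post_init__(self) -> None:
        if self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p below raw p")


def paired_t(diff: np.ndarray) -> tuple[float, float, int]:
    """t statistic, two-sided p, and df for a one-sample t on differences.

    Degenerate zero-variance differences give t = 0 (p = 1) for an all-zero
    contrast and t = ±inf (p = 0) for a constant non-zero one.
    """
    diff = np.asarray(diff, dtype=float)
    n = diff.size
    if n < 3:
        raise ValueError("need at least 3 complete subjects")
    df = n - 1
    m = diff.mean()
    sd = diff.std(ddof=1)
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0, df
        return float(np.sign(m)) * np.inf, 0.0, df
    t = m / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(p), df


def _effect_from_contrast(diff: np.ndarray) -> tuple[float, int, int, float]:
    t, p, df = paired_t(diff)
    f = t * t if np.isfinite(t) else np.inf
    return float(f), 1, df, p


def _cell_stats(values: Mapping[str, np.ndarray]) -> dict:
    return {
        k: (float(np.mean(v)), float(np.std(v, ddof=1)))
        for k, v in values.items()
    }


def rm_anova_oneway(
    posed: Sequence[float], spontaneous: Sequence[float]
) -> RmAnovaResult:
    """One-factor (two-level) repeated-measures ANOVA on paired values.

    F on (1, n−1) df, identical to the squared paired t statistic of
    spontaneous − posed.
    """
    posed = np.asarray(posed, dtype=float)
    spont = np.asarray(spontaneous, dtype=float)
    if posed.shape != spont.shape or posed.ndim != 1:
        raise ValueError("posed and spontaneous must be equal-length 1D arrays")
    if np.any(~np.isfinite(posed)) or np.any(~np.isfinite(spont)):
        raise ValueError("incomplete pairs: non-finite values present")
    f, df1, df2, p = _effect_from_contrast(spont - posed)
    return RmAnovaResult(
        factor_names=("expression",),
        f_values={"expression": f},
        df_pairs={"expression": (df1, df2)},
        p_values={"expression": p},
        effect_table=_cell_stats({"posed": posed, "spontaneous": spont}),
        n_subjects=posed.size,
    )


def rm_anova_twoway(cells: Mapping[str, Sequence[float]]) -> RmAnovaResult:
    """2×2 within-subject ANOVA: expression × side.

    ``cells`` maps "posed_left", "posed_right", "spontaneous_left",
    "spontaneous_right" to equal-length per-subject value arrays.  Each
    effect's F on (1, n−1) df equals the squared paired t of its
    within-subject contrast:

    * expression: mean over sides of spontaneous − posed
    * side:       mean over expressions of left − right
    * interaction: (spont_L − spont_R) − (posed_L − posed_R)
    """
    required = ("posed_left", "posed_right", "spontaneous_left", "spontaneous_right")
    missing = [k for k in required if k not in cells]
    if missing:
        raise ValueError(f"missing cells: {missing}")
    arrs = {k: np.asarray(cells[k], dtype=float) for k in required}
    n = arrs["posed_left"].size
    if any(a.shape != (n,) for a in arrs.values()):
        raise ValueError("all four cells must be equal-length 1D arrays")
    if any(np.any(~np.isfinite(a)) for a in arrs.values()):
        raise ValueError("incomplete cells: non-finite values present")
    pl, pr = arrs["posed_left"], arrs["posed_right"]
    sl, sr = arrs["spontaneous_left"], arrs["spontaneous_right"]
    contrasts = {
        "expression": 0.5 * ((sl + sr) - (pl + pr)),
        "side": 0.5 * ((pl + sl) - (pr + sr)),
        "interaction": (sl - sr) - (pl - pr),
    }
    f_values, df_pairs, p_values = {}, {}, {}
    for eff, diff in contrasts.items():
        f, df1, df2, p = _effect_from_contrast(diff)
        f_values[eff] = f
        df_pairs[eff] = (df1, df2)
        p_values[eff] = p
    return RmAnovaResult(
        factor_names=("expression", "side"),
        f_values=f_values,
        df_pairs=df_pairs,
        p_values=p_values,
        effect_table=_cell_stats(arrs),
        n_subjects=n,
    )


#: Default post-hoc family for a 2×2 table: expression simple effects
#: within each side plus side simple effects within each expression (m=4).
DEFAULT_POSTHOC_FAMILY = (
    ("spontaneous_left", "posed_left"),
    ("spontaneous_right", "posed_right"),
    ("posed_left", "posed_right"),
    ("spontaneous_left", "spontaneous_right"),
)


def _direction(label_a: str, label_b: str, mean_diff: float) -> str:
    def pretty(label: str) -> str:
        return label.replace("_", " ").title()

    if mean_diff > 0:
        return f"{pretty(label_a)} > {pretty(label_b)}"
    if mean_diff < 0:
        return f"{pretty(label_b)} > {pretty(label_a)}"
    return "No difference"


def bonferroni_posthoc(
    cells: Mapping[str, Sequence[float]],
    family: Sequence[tuple[str, str]] = DEFAULT_POSTHOC_FAMILY,
) -> list[PostHocResult]:
    """Paired t per contrast with Bonferroni adjustment over the family."""
    family = list(family)
    if not family:
        raise ValueError("post-hoc family must not be empty")
    m = len(family)
    out = []
    for a, b in family:
        if a not in cells or b not in cells:
            raise KeyError(f"contrast ({a}, {b}) references unknown cells")
        diff = np.asarray(cells[a], dtype=float) - np.asarray(cells[b], dtype=float)
        t, p_raw, _ = paired_t(diff)
        out.append(
            PostHocResult(
                contrast=f"{a} vs {b}",
                t_value=t,
                p_raw=p_raw,
                p_adjusted=min(1.0, m * p_raw),
                direction=_direction(a, b, float(diff.mean())),
            )
        )
    return out
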