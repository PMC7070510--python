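"""Model/Results interface for the smile-asymmetry contrasts.

:class:`RegionAsymmetryModel` fits, per facial region, the 2×2
within-subject ANOVA (expression: posed vs. spontaneous × side: left vs.
right) to a tidy intensity table, with Bonferroni-adjusted pairwise
post-hoc tests; :class:`AuContrastModel` fits the one-factor
repeated-measures ANOVA (posed vs. spontaneous) per AU feature.  Both
follow the fit() → Results-with-summary() convention of statistical
modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import (
    DEFAULT_POSTHOC_FAMILY,
    PostHocResult,
    RmAnovaResult,
    bonferroni_posthoc,
    rm_anova_oneway,
    rm_anova_twoway,
)

__all__ = [
    "RegionAsymmetryModel",
    "RegionAsymmetryResults",
    "AuContrastModel",
    "AuContrastResults",
]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class RegionAsymmetryResults:
    """Per-region 2×2 RM-ANOVA results with post-hoc contrasts."""

    anova: Mapping[str, RmAnovaResult]
    posthoc: Mapping[str, Sequence[PostHocResult]]
    n_subjects: int
    regions: tuple

    def direction(self, region: str, effect: str) -> str:
        """Readable direction of a main effect, e.g. "Spontaneous > Posed".

        Returns "Not significant" when the effect's p ≥ 0.05.
        """
        res = self.anova[region]
        if res.p_values[effect] >= 0.05:
            return "Not significant"
        cells = res.effect_table
        if effect == "expression":
            spont = cells["spontaneous_left"][0] + cells["spontaneous_right"][0]
            posed = cells["posed_left"][0] + cells["posed_right"][0]
            return "Spontaneous > Posed" if spont > posed else "Posed > Spontaneous"
        if effect == "side":
            left = cells["posed_left"][0] + cells["spontaneous_left"][0]
            right = cells["posed_right"][0] + cells["spontaneous_right"][0]
            return "Left > Right" if left > right else "Right > Left"
        return "Interaction"

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per region × effect."""
        rows = []
        for region in self.regions:
            res = self.anova[region]
            for effect in ("expression", "side", "interaction"):
                rows.append(
                    {
                        "region": region,
                        "effect": effect,
                        "F": res.f_values[effect],
                        "df1": res.df_pairs[effect][0],
                        "df2": res.df_pairs[effect][1],
                        "p": res.p_values[effect],
                        "stars": _stars(res.p_values[effect]),
                        "direction": self.direction(region, effect),
                    }
                )
        return pd.DataFrame(rows)

    def cell_table(self) -> pd.DataFrame:
        """Per-region cell means ± SD, mirroring the published layout."""
        rows = []
        for region in self.regions:
            res = self.anova[region]
            for cond in ("posed", "spontaneous"):
                row = {"region": region, "condition": cond}
                for side in ("left", "right"):
                    m, sd = res.effect_table[f"{cond}_{side}"]
                    row[f"{side}_mean"] = m
                    row[f"{side}_sd"] = sd
                rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Two-way repeated-measures ANOVA (expression x side), "
            f"n = {self.n_subjects} subjects",
            "",
        ]
        hdr = (
            f"{'region':<12}{'effect':<13}{'F':>10}{'df':>9}{'p':>11}  direction"
        )
        lines += [hdr, "-" * len(hdr)]
        for _, r in self.to_frame().iterrows():
            lines.append(
                f"{r.region:<12}{r.effect:<13}{r.F:>10.2f}"
                f"{f'({r.df1},{r.df2})':>9}{r.p:>11.2g}"
                f"{r.stars:<4} {r.direction}"
            )
        return "\n".join(lines)

    def plot_intensities(self, ax=None):
        """Grouped bar chart of cell means per region (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        tab = self.cell_table()
        x = np.arange(len(self.regions))
        width = 0.2
        for j, (cond, side) in enumerate(
            (c, s) for c in ("posed", "spontaneous") for s in ("left", "right")
        ):
            vals = [
                tab[(tab.region == reg) & (tab.condition == cond)][
                    f"{side}_mean"
                ].iloc[0]
                for reg in self.regions
            ]
            ax.bar(x + (j - 1.5) * width, vals, width, label=f"{cond}/{side}")
        ax.set_xticks(x)
        ax.set_xticklabels(self.regions, rotation=30, ha="right")
        ax.set_ylabel("intensity (mm)")
        ax.legend()
        return ax


class RegionAsymmetryModel:
    """2×2 within-subject asymmetry model over a tidy intensity table.

    Parameters
    ----------
    data : DataFrame
        Columns subject_id, condition (posed/spontaneous), region,
        side (left/right), intensity — one row per cell.
    regions : sequence of str, optional
        Regions to analyse (default: all present in the data).
    posthoc_family : sequence of (cell, cell) pairs
        Pairwise contrasts for the Bonferroni family (default m = 4:
        expression within each side, side within each condition).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        regions: Sequence[str] | None = None,
        posthoc_family: Sequence[tuple] = DEFAULT_POSTHOC_FAMILY,
    ) -> None:
        required = {"subject_id", "condition", "region", "side", "intensity"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"intensity table missing columns {sorted(missing)}")
        self.data = data
        self.regions = tuple(
            regions if regions is not None else pd.unique(data["region"])
        )
        self.posthoc_family = tuple(posthoc_family)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "RegionAsymmetryModel":
        return cls(data, **kw)

    def _cells(self, region: str) -> tuple[dict, int]:
        sub = self.data[self.data["region"] == region]
        wide = sub.pivot_table(
            index="subject_id",
            columns=["condition", "side"],
            values="intensity",
        )
        needed = [
            ("posed", "left"), ("posed", "right"),
            ("spontaneous", "left"), ("spontaneous", "right"),
        ]
        for key in needed:
            if key not in wide.columns:
                raise ValueError(f"region {region!r}: missing cell {key}")
        wide = wide.dropna(subset=needed)  # complete-case analysis
        cells = {f"{c}_{s}": wide[(c, s)].to_numpy(float) for c, s in needed}
        return cells, len(wide)

    def fit(self) -> RegionAsymmetryResults:
        anova, posthoc = {}, {}
        n = 0
        for region in self.regions:
            cells, n = self._cells(region)
            anova[region] = rm_anova_twoway(cells)
            posthoc[region] = bonferroni_posthoc(cells, self.posthoc_family)
        return RegionAsymmetryResults(anova, posthoc, n, self.regions)


@dataclass(frozen=True)
class AuContrastResults:
    """One-way RM-ANOVA (posed vs. spontaneous) per AU feature."""

    anova: Mapping[str, RmAnovaResult]
    n_subjects: int
    features: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat in self.features:
            res = self.anova[feat]
            pm, psd = res.effect_table["posed"]
            sm, ssd = res.effect_table["spontaneous"]
            p = res.p_values["expression"]
            rows.append(
                {
                    "feature": feat,
                    "posed_mean": pm,
                    "posed_sd": psd,
                    "spontaneous_mean": sm,
                    "spontaneous_sd": ssd,
                    "F": res.f_values["expression"],
                    "df1": res.df_pairs["expression"][0],
                    "df2": res.df_pairs["expression"][1],
                    "p": p,
                    "stars": _stars(p),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA on AU intensity, n = {self.n_subjects}",
            "",
        ]
        hdr = (
            f"{'feature':<9}{'posed':>14}{'spontaneous':>16}{'F':>10}{'p':>11}"
        )
        lines += [hdr, "-" * len(hdr)]
        for _, r in self.to_frame().iterrows():
            lines.append(
                f"{r.feature:<9}"
                f"{f'{r.posed_mean:.2f}±{r.posed_sd:.2f}':>14}"
                f"{f'{r.spontaneous_mean:.2f}±{r.spontaneous_sd:.2f}':>16}"
                f"{r.F:>10.2f}{r.p:>11.2g}{r.stars}"
            )
        return "\n".join(lines)


class AuContrastModel:
    """Posed-vs-spontaneous contrast on per-subject AU summaries.

    ``data`` is the tidy AU table (subject_id, condition, au06, au12,
    au_sum) with one posed and one spontaneous row per subject.
    """

    FEATURES = ("au06", "au12", "au_sum")

    def __init__(self, data: pd.DataFrame) -> None:
        self.data = data

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame) -> "AuContrastModel":
        return cls(data)

    def fit(self) -> AuContrastResults:
        wide = self.data.pivot_table(
            index="subject_id", columns="condition", values=list(self.FEATURES)
        )
        anova = {}
        n = 0
        for feat in self.FEATURES:
            sub = wide[feat].dropna(subset=["posed", "spontaneous"])
            anova[feat] = rm_anova_oneway(
                sub["posed"].to_numpy(float), sub["spontaneous"].to_numpy(float)
            )
            n = len(sub)
        return AuContrastResults(anova, n, self.FEATURES)
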