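"""ADA-based glycemic classification from fasting and 2-h OGTT glucose.

Categories (all glucose in mmol/l, compared without rounding):

* diabetes: fasting >= 7.0 or 2-h >= 11.1 (excluded from analyses)
* IFG flag: fasting >= 5.6; IGT flag: 2-h >= 7.8
* NGT / isolated IFG / isolated IGT / IFG+IGT from the two flags

Composite groups: "combined IGT" is any elevated 2-h glucose regardless of
fasting glycemia (isolated IGT + IFG+IGT); "prediabetes" is IFG and/or IGT.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "GlycemicCategory",
    "GlycemicClass",
    "classify_subject",
    "classify_table",
    "derive_groups",
    "FASTING_IFG_MMOL_L",
    "TWOHOUR_IGT_MMOL_L",
    "FASTING_DIABETES_MMOL_L",
    "TWOHOUR_DIABETES_MMOL_L",
]

FASTING_IFG_MMOL_L = 5.6
TWOHOUR_IGT_MMOL_L = 7.8
FASTING_DIABETES_MMOL_L = 7.0
TWOHOUR_DIABETES_MMOL_L = 11.1


class GlycemicCategory(str, enum.Enum):
    NGT = "NGT"
    ISOLATED_IFG = "ISOLATED_IFG"
    ISOLATED_IGT = "ISOLATED_IGT"
    IFG_IGT = "IFG_IGT"
    DIABETES = "DIABETES"


@dataclass(frozen=True)
class GlycemicClass:
    category: GlycemicCategory

    @property
    def igt_combined(self) -> bool:
        """Elevated post-load glucose independently of fasting glycemia."""
        return self.category in (GlycemicCategory.ISOLATED_IGT, GlycemicCategory.IFG_IGT)

    @property
    def prediabetes(self) -> bool:
        """IFG and/or IGT."""
        return self.category in (
            GlycemicCategory.ISOLATED_IFG,
            GlycemicCategory.ISOLATED_IGT,
            GlycemicCategory.IFG_IGT,
        )


def classify_subject(fasting_glucose: float, twohour_glucose: float) -> GlycemicClass:
    """Classify one subject from fasting and 2-h glucose (mmol/l)."""
    for name, v in (("fasting", fasting_glucose), ("2-h", twohour_glucose)):
        if v is None or not math.isfinite(v) or v <= 0:
            raise ValueError(f"{name} glucose must be positive and finite, got {v!r}")
    if fasting_glucose >= FASTING_DIABETES_MMOL_L or twohour_glucose >= TWOHOUR_DIABETES_MMOL_L:
        return GlycemicClass(GlycemicCategory.DIABETES)
    ifg = fasting_glucose >= FASTING_IFG_MMOL_L
    igt = twohour_glucose >= TWOHOUR_IGT_MMOL_L
    if ifg and igt:
        return GlycemicClass(GlycemicCategory.IFG_IGT)
    if ifg:
        return GlycemicClass(GlycemicCategory.ISOLATED_IFG)
    if igt:
        return GlycemicClass(GlycemicCategory.ISOLATED_IGT)
    return GlycemicClass(GlycemicCategory.NGT)


def classify_table(
    df: pd.DataFrame,
    fasting_col: str = "glucose_0_mmol_l",
    twohour_col: str = "glucose_120_mmol_l",
) -> pd.DataFrame:
    """Vectorised classification; appends category and indicator columns."""
    fg = df[fasting_col].to_numpy(dtype=float)
    g2 = df[twohour_col].to_numpy(dtype=float)
    if np.any(~np.isfinite(fg) | (fg <= 0)) or np.any(~np.isfinite(g2) | (g2 <= 0)):
        raise ValueError("glucose columns must be positive and finite for every subject")
    diab = (fg >= FASTING_DIABETES_MMOL_L) | (g2 >= TWOHOUR_DIABETES_MMOL_L)
    ifg = fg >= FASTING_IFG_MMOL_L
    igt = g2 >= TWOHOUR_IGT_MMOL_L
    cat = np.select(
        [diab, ifg & igt, ifg, igt],
        [
            GlycemicCategory.DIABETES.value,
            GlycemicCategory.IFG_IGT.value,
            GlycemicCategory.ISOLATED_IFG.value,
            GlycemicCategory.ISOLATED_IGT.value,
        ],
        default=GlycemicCategory.NGT.value,
    )
    out = df.copy()
    out["category"] = cat
    out["igt_combined"] = ~diab & igt
    out["prediabetes"] = ~diab & (ifg | igt)
    return out


def derive_groups(classes: Iterable[GlycemicClass | GlycemicCategory | str]) -> dict[str, int]:
    """Group counts and the composite combined-IGT / prediabetes totals.

    Expects diabetes rows to have been excluded already; any remaining
    DIABETES entry raises.
    """
    counts = {c.value: 0 for c in GlycemicCategory}
    for item in classes:
        if isinstance(item, GlycemicClass):
            cat = item.category
        elif isinstance(item, GlycemicCategory):
            cat = item
        else:
            cat = GlycemicCategory(str(item))
        counts[cat.value] += 1
    if counts[GlycemicCategory.DIABETES.value]:
        raise ValueError("diabetes rows must be excluded before deriving group counts")
    igt_combined = counts["ISOLATED_IGT"] + counts["IFG_IGT"]
    prediabetes = counts["ISOLATED_IFG"] + igt_combined
    return {
        "NGT": counts["NGT"],
        "isolated_IFG": counts["ISOLATED_IFG"],
        "isolated_IGT": counts["ISOLATED_IGT"],
        "IFG_IGT": counts["IFG_IGT"],
        "IGT_combined": igt_combined,
        "prediabetes": prediabetes,
        "total": counts["NGT"] + prediabetes,
    }
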