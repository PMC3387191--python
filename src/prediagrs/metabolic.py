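"""Insulin-sensitivity and beta-cell surrogate indices from OGTT data.

The whole-body insulin sensitivity index of Matsuda & DeFronzo is

    ISI = 10000 / sqrt(G0 * I0 * Gmean * Imean)

with glucose in mg/dl and insulin in uU/ml, and the means taken as the
unweighted average over the five OGTT samples (0, 30, 60, 90, 120 min).
Inputs here are mmol/l and pmol/l (the units laboratories in Europe
report); conversions are applied internally: mg/dl = mmol/l * 18.016 and
uU/ml = pmol/l / 6.0 (the divisor is configurable, 6.945 being the other
common convention).

HOMA1 fasting indices: HOMA-IR = G*I/22.5 and HOMA-B = 20*I/(G - 3.5),
with G in mmol/l and I in uU/ml; HOMA-B is undefined for G <= 3.5 mmol/l
and is returned as NaN with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "OGTT_MINUTES",
    "GLUCOSE_MGDL_PER_MMOL",
    "INSULIN_PMOL_PER_UU",
    "matsuda_isi",
    "homa_indices",
    "median_isi_split",
    "add_metabolic_indices",
]

OGTT_MINUTES = (0, 30, 60, 90, 120)
GLUCOSE_MGDL_PER_MMOL = 18.016
INSULIN_PMOL_PER_UU = 6.0


def _as_curve(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[-1] != len(OGTT_MINUTES):
        raise ValueError(
            f"{name} must have exactly {len(OGTT_MINUTES)} samples at minutes {OGTT_MINUTES}"
        )
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(f"{name} values must all be positive and finite")
    return arr


def matsuda_isi(
    glucose_mmol_l,
    insulin_pmol_l,
    *,
    insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU,
) -> np.ndarray | float:
    """Matsuda-DeFronzo ISI from 5-point OGTT curves.

    Accepts a single curve (length-5 sequences) or arrays of shape
    (n, 5); returns a scalar or a length-n array accordingly.
    """
    scalar = np.asarray(glucose_mmol_l).ndim == 1
    g = _as_curve(glucose_mmol_l, "glucose") * GLUCOSE_MGDL_PER_MMOL
    i = _as_curve(insulin_pmol_l, "insulin") / insulin_pmol_per_uu
    isi = 10000.0 / np.sqrt(g[:, 0] * i[:, 0] * g.mean(axis=1) * i.mean(axis=1))
    return float(isi[0]) if scalar else isi


def homa_indices(
    fasting_glucose_mmol_l,
    fasting_insulin_pmol_l,
    *,
    insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """(HOMA-IR, HOMA-B) from fasting glucose (mmol/l) and insulin (pmol/l).

    HOMA-B is NaN (with a warning) where glucose <= 3.5 mmol/l.
    """
    g = np.asarray(fasting_glucose_mmol_l, dtype=float)
    i = np.asarray(fasting_insulin_pmol_l, dtype=float)
    if np.any(g <= 0) or np.any(i <= 0):
        raise ValueError("fasting glucose and insulin must be positive")
    i_uu = i / insulin_pmol_per_uu
    homa_ir = g * i_uu / 22.5
    denom = g - 3.5
    with np.errstate(divide="ignore", invalid="ignore"):
        homa_b = np.where(denom > 0, 20.0 * i_uu / np.where(denom > 0, denom, np.nan), np.nan)
    if np.any(denom <= 0):
        warnings.warn(
            "HOMA-B undefined for fasting glucose <= 3.5 mmol/l; returned as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    if g.ndim == 0:
        return float(homa_ir), float(homa_b)
    return homa_ir, homa_b


def median_isi_split(isi) -> tuple[float, np.ndarray]:
    """Median split into insulin-resistant vs -sensitive.

    Returns ``(threshold, resistant_mask)`` where the threshold is the
    sample median, resistant means ISI strictly below it, and subjects
    exactly at the median count as sensitive (the >= side).
    """
    arr = np.asarray(isi, dtype=float)
    if arr.size == 0:
        raise ValueError("ISI list must be non-empty")
    threshold = float(np.median(arr))
    return threshold, arr < threshold


def add_metabolic_indices(
    df: pd.DataFrame, *, insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU
) -> pd.DataFrame:
    """Append isi_matsuda, homa_ir, homa_b columns computed from OGTT columns."""
    g = df[[f"glucose_{t}_mmol_l" for t in OGTT_MINUTES]].to_numpy(dtype=float)
    i = df[[f"insulin_{t}_pmol_l" for t in OGTT_MINUTES]].to_numpy(dtype=float)
    out = df.copy()
    out["isi_matsuda"] = matsuda_isi(g, i, insulin_pmol_per_uu=insulin_pmol_per_uu)
    homa_ir, homa_b = homa_indices(
        g[:, 0], i[:, 0], insulin_pmol_per_uu=insulin_pmol_per_uu
    )
    out["homa_ir"] = homa_ir
    out["homa_b"] = homa_b
    return out
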