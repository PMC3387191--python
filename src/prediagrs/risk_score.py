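"""Simple, weighted and secretion-restricted genetic risk scores.

For subject j with risk-allele counts a_ij over N panel SNPs:

* simple score: sum_i a_ij (an integer in [0, 2N])
* weighted score: (N / sum_i w_i) * sum_i w_i * a_ij with w_i = ln(OR_i)

The normalisation constant N / sum(w) restores the allele-count scale, so
the weighted score is directly comparable with the simple score: it is
bounded by [0, 2N] and equals the simple score exactly when all panel ORs
coincide. The secretion-restricted variants apply the same formulas to
the sub-panel of secretion-related loci (renormalised by its own size).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .genotype_qc import GenotypeMatrix
from .snp_panel import SNPPanel, secretion_subset

__all__ = ["simple_score", "weighted_score", "score_cohort"]

WeightFunction = Callable[[float], float]


def _validate_counts(counts_row, n_expected: int) -> np.ndarray:
    arr = np.asarray(counts_row, dtype=float)
    if arr.ndim != 1 or arr.size != n_expected:
        raise ValueError(f"expected a complete row of {n_expected} counts, got shape {arr.shape}")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing genotype in counts row; scores require complete rows")
    if np.any((arr != np.round(arr)) | (arr < 0) | (arr > 2)):
        raise ValueError("risk-allele counts must be integers in {0, 1, 2}")
    return arr


def _weights(panel: SNPPanel, weight_fn: WeightFunction | None) -> np.ndarray:
    if weight_fn is None:
        w = np.asarray(panel.weights, dtype=float)
    else:
        w = np.asarray([weight_fn(s.or_literature) for s in panel], dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("all panel weights are zero; the weighted score is undefined")
    return w


def simple_score(counts_row: Sequence[int]) -> int:
    """Total number of risk alleles carried by one subject."""
    return int(_validate_counts(counts_row, len(counts_row)).sum())


def weighted_score(
    counts_row: Sequence[int],
    panel: SNPPanel,
    weight_fn: WeightFunction | None = None,
) -> float:
    """Normalised weighted risk score for one subject.

    ``weight_fn`` maps a literature OR to a weight (default ``ln``);
    the result is invariant to rescaling all weights by a positive
    constant.
    """
    a = _validate_counts(counts_row, panel.n)
    w = _weights(panel, weight_fn)
    return float(panel.n / w.sum() * (w * a).sum())


def score_cohort(
    gm: GenotypeMatrix,
    panel: SNPPanel,
    weight_fn: WeightFunction | None = None,
) -> pd.DataFrame:
    """Per-subject score table over a complete-case genotype matrix.

    Columns: subject_id, grs_simple, grs_weighted, grs7_simple,
    grs7_weighted (the last two from the secretion sub-panel).
    """
    if list(gm.rsids) != list(panel.rsids):
        raise ValueError("genotype matrix columns do not match the panel order")
    if gm.missing.any():
        raise ValueError(
            "genotype matrix contains missing calls; apply the complete-case filter first"
        )
    counts = gm.counts.astype(float)
    w = _weights(panel, weight_fn)
    sub = secretion_subset(panel)
    sub_idx = [panel.rsids.index(r) for r in sub.rsids]
    w7 = w[sub_idx]
    counts7 = counts[:, sub_idx]
    return pd.DataFrame(
        {
            "subject_id": gm.subject_ids,
            "grs_simple": counts.sum(axis=1).astype(int),
            "grs_weighted": panel.n / w.sum() * counts @ w,
            "grs7_simple": counts7.sum(axis=1).astype(int),
            "grs7_weighted": sub.n / w7.sum() * counts7 @ w7,
        }
    )
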