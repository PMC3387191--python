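"""Group-wise descriptive tables and forest-plot output.

The summary table mirrors the usual "characteristics of the study
population" layout: group columns ordered NGT, isolated IFG, isolated
IGT, IFG+IGT; continuous variables as mean +/- SD with each at-risk
group compared against NGT (Student's t for approximately normal
variables, Wilcoxon rank-sum for the configured right-skewed set);
binary variables as percentages with Fisher's exact test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats as st

__all__ = ["table1_summary", "forest_plot", "GROUP_ORDER"]

GROUP_ORDER = ("NGT", "ISOLATED_IFG", "ISOLATED_IGT", "IFG_IGT")

DEFAULT_CONTINUOUS = (
    "age",
    "bmi",
    "glucose_0_mmol_l",
    "glucose_120_mmol_l",
    "insulin_0_pmol_l",
    "insulin_120_pmol_l",
    "homa_b",
    "homa_ir",
    "triglycerides_mmol_l",
    "hdl_mmol_l",
    "ldl_mmol_l",
    "isi_matsuda",
)
DEFAULT_BINARY = ("family_history", "lipid_lowering", "antihypertensive")
# right-skewed variables compared by rank-sum instead of t
DEFAULT_SKEWED = (
    "insulin_0_pmol_l",
    "insulin_120_pmol_l",
    "homa_b",
    "homa_ir",
    "triglycerides_mmol_l",
    "isi_matsuda",
)


def table1_summary(
    data: pd.DataFrame,
    continuous: tuple[str, ...] = DEFAULT_CONTINUOUS,
    binary: tuple[str, ...] = DEFAULT_BINARY,
    skewed: tuple[str, ...] = DEFAULT_SKEWED,
    group_col: str = "category",
) -> pd.DataFrame:
    """Per-group mean +/- SD (or %) with each group tested against NGT.

    Returns a DataFrame indexed by variable with MultiIndex-free wide
    columns ``{group}_mean``/``{group}_sd``/``{group}_p`` (binary rows
    carry the percentage in the mean column and NaN SD). Groups with
    fewer than two subjects report NaN SD.
    """
    continuous = tuple(c for c in continuous if c in data.columns)
    binary = tuple(c for c in binary if c in data.columns)
    groups = {g: data.loc[data[group_col] == g] for g in GROUP_ORDER}
    ref = groups["NGT"]
    rows = {}
    for var in continuous:
        row = {"type": "continuous", "n_total": int(data[var].notna().sum())}
        x_ref = ref[var].dropna().to_numpy(dtype=float)
        for g, sub in groups.items():
            x = sub[var].dropna().to_numpy(dtype=float)
            row[f"{g}_mean"] = x.mean() if x.size else np.nan
            row[f"{g}_sd"] = x.std(ddof=1) if x.size >= 2 else np.nan
            if g == "NGT":
                row[f"{g}_p"] = np.nan
            elif x.size < 2 or x_ref.size < 2:
                row[f"{g}_p"] = np.nan
            elif var in skewed:
                row[f"{g}_p"] = st.mannwhitneyu(x, x_ref, alternative="two-sided").pvalue
            else:
                row[f"{g}_p"] = st.ttest_ind(x, x_ref).pvalue
        rows[var] = row
    for var in binary:
        row = {"type": "binary", "n_total": int(data[var].notna().sum())}
        k_ref = int(ref[var].sum())
        n_ref = int(ref[var].notna().sum())
        for g, sub in groups.items():
            k = int(sub[var].sum())
            n = int(sub[var].notna().sum())
            row[f"{g}_mean"] = 100.0 * k / n if n else np.nan
            row[f"{g}_sd"] = np.nan
            if g == "NGT" or n == 0 or n_ref == 0:
                row[f"{g}_p"] = np.nan
            else:
                row[f"{g}_p"] = st.fisher_exact([[k, n - k], [k_ref, n_ref - k_ref]])[1]
        rows[var] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "variable"
    return out


def forest_plot(forest: pd.DataFrame, path) -> None:
    """Render the stratified odds-ratio table as a forest plot (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    d = forest.iloc[::-1]
    y = np.arange(len(d))
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(d) + 1.2))
    ax.errorbar(
        d["or_per_allele"],
        y,
        xerr=[
            d["or_per_allele"] - d["or_ci_low"],
            d["or_ci_high"] - d["or_per_allele"],
        ],
        fmt="s",
        color="black",
        capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels([f"{s} (n={n})" for s, n in zip(d["stratum"], d["n"])])
    ax.set_xlabel("OR per risk allele (95% CI)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
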