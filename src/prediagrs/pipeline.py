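"""End-to-end orchestration: read -> QC -> classify -> indices -> score -> models.

`build_analysis_table` is the shared assembly step: it merges genotypes
and phenotypes, excludes diabetic subjects, applies the complete-case
filter, and appends glycemic categories, metabolic indices and risk
scores. `run_pipeline` wraps it with file I/O, the QC report, the model
grid, the stratified forest table, the power table, the group-summary
table and a run log sufficient to re-execute the run bit-identically.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    DEFAULT_LOG_TRANSFORM,
    run_primary_analyses,
    run_stratified_analyses,
)
from .genotype_qc import GenotypeMatrix, filter_complete, hwe_report, read_genotypes
from .glycemic import GlycemicCategory, classify_table, derive_groups
from .metabolic import INSULIN_PMOL_PER_UU, OGTT_MINUTES, add_metabolic_indices
from .power import required_effect_size
from .reporting import table1_summary
from .risk_score import score_cohort
from .snp_panel import SNPPanel, default_panel, load_panel

__all__ = ["PipelineConfig", "build_analysis_table", "run_pipeline", "power_table"]

logger = logging.getLogger(__name__)

REQUIRED_PHENOTYPES = (
    ["sex", "age", "bmi", "family_history", "lipid_lowering", "antihypertensive",
     "triglycerides_mmol_l", "hdl_mmol_l", "ldl_mmol_l"]
    + [f"glucose_{t}_mmol_l" for t in OGTT_MINUTES]
    + [f"insulin_{t}_pmol_l" for t in OGTT_MINUTES]
)


@dataclass
class PipelineConfig:
    genotypes: Path
    phenotypes: Path
    out_dir: Path
    panel: Path | None = None  # None -> packaged default panel
    log_transform: tuple[str, ...] = DEFAULT_LOG_TRANSFORM
    insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU
    alpha: float = 0.05
    power: float = 0.8
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("genotypes", "phenotypes", "out_dir", "panel"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "log_transform" in raw:
            raw["log_transform"] = tuple(raw["log_transform"])
        return cls(**raw)


def build_analysis_table(
    gm: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    panel: SNPPanel,
    insulin_pmol_per_uu: float = INSULIN_PMOL_PER_UU,
) -> tuple[pd.DataFrame, dict]:
    """Assemble the complete-case, non-diabetic analysis table.

    Returns the table (one row per retained subject, with category,
    indices and score columns) and a bookkeeping dict with exclusion
    counts.
    """
    gm_f, phen_f, filter_info = filter_complete(
        gm, phenotypes, required_columns=[c for c in REQUIRED_PHENOTYPES if c in phenotypes.columns]
    )
    phen_f = classify_table(phen_f)
    diabetic = phen_f["category"] == GlycemicCategory.DIABETES.value
    n_diabetic = int(diabetic.sum())
    if n_diabetic:
        keep_ids = phen_f.loc[~diabetic, "subject_id"].tolist()
        idx = [gm_f.subject_ids.index(s) for s in keep_ids]
        gm_f = GenotypeMatrix(keep_ids, list(gm_f.rsids), gm_f.counts[idx], gm_f.missing[idx])
        phen_f = phen_f.loc[~diabetic].reset_index(drop=True)
    phen_f = add_metabolic_indices(phen_f, insulin_pmol_per_uu=insulin_pmol_per_uu)
    scores = score_cohort(gm_f, panel)
    table = phen_f.merge(scores, on="subject_id", validate="one_to_one")
    info = dict(filter_info, n_excluded_diabetes=n_diabetic, n_analysis=len(table))
    return table, info


def power_table(
    group_sizes: dict[str, tuple[int, int]] | None = None,
    alpha: float = 0.05,
    power: float = 0.8,
) -> pd.DataFrame:
    """Minimum detectable Cohen's d per subgroup configuration.

    Default configurations compare each at-risk subgroup against the
    remainder of the cohort.
    """
    if group_sizes is None:
        group_sizes = {
            "prediabetes": (396, 1046),
            "IGT_combined": (254, 1188),
            "isolated_IGT": (140, 1302),
            "isolated_IFG": (142, 1300),
        }
    rows = [
        {
            "group": name,
            "n1": n1,
            "n2": n2,
            "alpha": alpha,
            "power": power,
            "min_detectable_d": required_effect_size(n1, n2, alpha, power),
        }
        for name, (n1, n2) in group_sizes.items()
    ]
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes hwe_qc.tsv, analysis_table.tsv, group_counts.json,
    model_grid.tsv, forest_table.tsv, power_table.tsv, table1.tsv and
    run_log.json into ``config.out_dir``; returns a dict of paths plus
    the in-memory results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(config.panel) if config.panel is not None else default_panel()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    gm = stage("read_genotypes", read_genotypes, config.genotypes, panel)
    phen = stage("read_phenotypes", pd.read_csv, config.phenotypes, sep="\t")
    qc = stage("hwe_qc", hwe_report, gm, panel)
    qc.to_csv(out / "hwe_qc.tsv", sep="\t", index=False)
    table, info = stage(
        "build_analysis_table", build_analysis_table, gm, phen, panel, config.insulin_pmol_per_uu
    )
    table.to_csv(out / "analysis_table.tsv", sep="\t", index=False)
    groups = stage("derive_groups", derive_groups, table["category"].tolist())
    primary = stage("primary_models", run_primary_analyses, table, config.log_transform)
    grid = pd.DataFrame([r.to_row() for r in primary])
    grid.to_csv(out / "model_grid.tsv", sep="\t", index=False)
    stratified, forest = stage("stratified_models", run_stratified_analyses, table)
    forest.to_csv(out / "forest_table.tsv", sep="\t", index=False)
    pw = stage(
        "power_table",
        power_table,
        {
            "prediabetes": (groups["prediabetes"], groups["NGT"]),
            "IGT_combined": (groups["IGT_combined"], groups["total"] - groups["IGT_combined"]),
            "isolated_IGT": (groups["isolated_IGT"], groups["total"] - groups["isolated_IGT"]),
            "isolated_IFG": (groups["isolated_IFG"], groups["total"] - groups["isolated_IFG"]),
        },
        config.alpha,
        config.power,
    )
    pw.to_csv(out / "power_table.tsv", sep="\t", index=False)
    t1 = stage("table1", table1_summary, table)
    t1.to_csv(out / "table1.tsv", sep="\t")

    run_log = {
        "prediagrs_version": __version__,
        "python": platform.python_version(),
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "settings": {
            "panel": str(config.panel) if config.panel else "packaged default",
            "log_transform": list(config.log_transform),
            "insulin_pmol_per_uu": config.insulin_pmol_per_uu,
            "alpha": config.alpha,
            "power": config.power,
        },
        "exclusions": info,
        "group_counts": groups,
        "isi_median_threshold": forest.attrs.get("isi_threshold"),
    }
    with open(out / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    with open(out / "group_counts.json", "w") as fh:
        json.dump(groups, fh, indent=2)
    return {
        "out_dir": out,
        "groups": groups,
        "primary": primary,
        "stratified": stratified,
        "forest": forest,
        "power_table": pw,
        "run_log": run_log,
        "analysis_table": table,
    }
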