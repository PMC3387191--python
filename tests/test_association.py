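import numpy as np
import pandas as pd
import pytest

from prediagrs.association import (
    ModelSpec,
    SeparationError,
    fit_model,
    run_primary_analyses,
    run_stratified_analyses,
)
from prediagrs.pipeline import build_analysis_table
from prediagrs.simulate import SimulationConfig, generate_cohort


def two_by_two_table(n11, n10, n01, n00):
    """Exposed/unexposed x case/NGT analysis table with a binary score."""
    return pd.DataFrame(
        {
            "category": (
                ["ISOLATED_IGT"] * n11 + ["NGT"] * n10 + ["ISOLATED_IGT"] * n01 + ["NGT"] * n00
            ),
            "grs_weighted": [1.0] * (n11 + n10) + [0.0] * (n01 + n00),
        }
    )


class TestFitModel:
    def test_saturated_model_recovers_contingency_or(self):
        data = two_by_two_table(30, 70, 10, 90)
        spec = ModelSpec(outcome="IGT_combined", covariates=(), log_transform=())
        result = fit_model(data, spec)
        assert result.or_per_allele == pytest.approx(30 * 90 / (70 * 10), rel=1e-6)
        assert result.n == 200 and result.n_cases == 40

    def test_lrt_p_invariant_to_affine_score_rescaling(self, analysis_table):
        spec = ModelSpec(outcome="IGT_combined")
        base = fit_model(analysis_table, spec)
        rescaled = analysis_table.copy()
        rescaled["grs_weighted"] = 2.0 * rescaled["grs_weighted"] + 5.0
        alt = fit_model(rescaled, spec)
        assert alt.lrt_p_score == pytest.approx(base.lrt_p_score, rel=1e-6)
        assert alt.or_per_allele == pytest.approx(np.sqrt(base.or_per_allele), rel=1e-5)

    def test_separation_is_flagged_not_silent(self):
        data = two_by_two_table(20, 0, 0, 20)  # score perfectly predicts outcome
        spec = ModelSpec(outcome="IGT_combined", covariates=(), log_transform=())
        with pytest.raises(SeparationError):
            fit_model(data, spec)

    def test_degenerate_outcome_is_error(self):
        data = two_by_two_table(0, 30, 0, 30)
        spec = ModelSpec(outcome="IGT_combined", covariates=(), log_transform=())
        with pytest.raises(ValueError, match="not binary"):
            fit_model(data, spec)

    def test_wald_ci_brackets_or(self, analysis_table):
        r = fit_model(analysis_table, ModelSpec(outcome="IGT_combined"))
        assert r.or_ci[0] < r.or_per_allele < r.or_ci[1]
        assert 0.0 < r.lrt_p_score <= 1.0

    def test_ci_coverage_at_known_or(self, panel):
        """95% Wald CIs cover an injected per-allele OR of 1.25 at near-nominal rate."""
        covered = 0
        reps = 200
        for s in range(reps):
            cfg = SimulationConfig(
                n_subjects=5000, beta_score=float(np.log(1.25)), seed=50_000 + s
            )
            gm, phen, _ = generate_cohort(cfg)
            table, _ = build_analysis_table(gm, phen, panel)
            r = fit_model(table, ModelSpec(outcome="IGT_combined"))
            covered += r.or_ci[0] <= 1.25 <= r.or_ci[1]
        assert covered / reps >= 0.93


class TestModelGrid:
    def test_grid_completeness_and_labels(self, analysis_table):
        results = run_primary_analyses(analysis_table)
        assert len(results) == 10
        outcomes = {r.spec.outcome for r in results}
        assert outcomes == {"IGT_combined", "prediabetes", "isolated_IGT", "isolated_IFG"}
        assert sum(r.spec.score_variable == "grs7_simple" for r in results) == 1
        extended = [r for r in results if "extended" in r.spec.label]
        assert len(extended) == 1 and "ln_triglycerides_mmol_l" in extended[0].coef

    def test_postload_effect_concentrates_in_igt_outcomes(self, panel):
        """Genetic effect injected on the 2-h liability shows up in IGT, not isolated IFG."""
        wins = 0
        reps = 15
        for s in range(reps):
            cfg = SimulationConfig(beta_score=float(np.log(1.3)), seed=60_000 + s)
            gm, phen, _ = generate_cohort(cfg)
            table, _ = build_analysis_table(gm, phen, panel)
            p_igt = fit_model(table, ModelSpec(outcome="IGT_combined")).lrt_p_score
            p_ifg = fit_model(table, ModelSpec(outcome="isolated_IFG")).lrt_p_score
            wins += p_igt < p_ifg
        assert wins > reps / 2


class TestStratifiedAnalyses:
    def test_forest_structure_and_partitions(self, analysis_table):
        results, forest = run_stratified_analyses(analysis_table)
        assert list(forest["stratum"]) == [
            "overall", "female", "male", "lean", "obese", "sensitive", "resistant",
        ]
        n = dict(zip(forest["stratum"], forest["n"]))
        cases = dict(zip(forest["stratum"], forest["n_cases"]))
        # strata partition the cohort (on the case side, which has no exclusions)
        assert cases["female"] + cases["male"] == cases["overall"]
        assert cases["lean"] + cases["obese"] == cases["overall"]
        assert cases["sensitive"] + cases["resistant"] == cases["overall"]
        assert n["female"] + n["male"] == n["overall"]
        assert forest.attrs["isi_threshold"] > 0

    def test_small_stratum_is_skipped_with_flag(self, analysis_table):
        # keep only 3 male combined-IGT cases
        male_cases = analysis_table.index[
            (analysis_table["sex"] == "male")
            & analysis_table["category"].isin(["ISOLATED_IGT", "IFG_IGT"])
        ]
        trimmed = analysis_table.drop(male_cases[3:])
        results, forest = run_stratified_analyses(trimmed)
        male = next(r for r in results if r.spec.stratum == "male")
        assert male.skipped and np.isnan(male.or_per_allele)
        assert len(forest) == 7
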