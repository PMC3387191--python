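import json

import numpy as np
import pandas as pd
import pytest

from prediagrs.genotype_qc import hwe_report, read_genotypes
from prediagrs.pipeline import build_analysis_table
from prediagrs.simulate import (
    CalibrationError,
    SimulationConfig,
    generate_cohort,
    write_fixture,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 5},
            {"female_fraction": 1.5},
            {"target_prediabetes_prev": 0.0},
            {"effect_modification": "bogus"},
            {"diabetes_fraction": 0.9},
            {"target_igt_prev": 0.5},  # above the prediabetes target
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(seed=42)
        gm1, phen1, truth1 = generate_cohort(cfg)
        gm2, phen2, truth2 = generate_cohort(SimulationConfig(seed=42))
        np.testing.assert_array_equal(gm1.counts, gm2.counts)
        pd.testing.assert_frame_equal(phen1, phen2)
        assert truth1 == truth2

    def test_demographics_match_targets(self, cohort):
        gm, phen, truth = cohort
        assert (phen["sex"] == "female").sum() == 959
        assert (phen["sex"] == "male").sum() == 483
        assert phen["age"].between(18, 80).all()
        assert abs((phen["bmi"] >= 30).mean() - 0.32) < 0.05

    def test_prevalence_calibration(self):
        prevs = [
            generate_cohort(SimulationConfig(seed=s))[2]["realized_prediabetes_prev"]
            for s in range(8)
        ]
        assert all(abs(p - 0.28) <= 0.02 for p in prevs)
        assert abs(np.mean(prevs) - 0.28) <= 0.02

    def test_genotypes_in_hwe(self, panel):
        pvals = []
        for s in range(30):
            gm, _, _ = generate_cohort(SimulationConfig(seed=300 + s))
            pvals.extend(hwe_report(gm, panel)["p_hwe_exact"])
        pvals = np.asarray(pvals)
        assert (pvals < 0.05).mean() <= 0.09
        assert 0.40 <= pvals.mean() <= 0.70

    def test_null_config_centres_or_on_one(self, panel):
        from prediagrs.association import ModelSpec, fit_model

        ors = []
        for s in range(40):
            gm, phen, _ = generate_cohort(SimulationConfig(beta_score=0.0, seed=700 + s))
            table, _ = build_analysis_table(gm, phen, panel)
            ors.append(fit_model(table, ModelSpec(outcome="IGT_combined")).or_per_allele)
        assert np.mean(ors) == pytest.approx(1.0, abs=0.02)

    def test_genetic_effect_is_postload_only_by_default(self, cohort):
        """The score should correlate with 2-h glucose but not fasting glucose."""
        from scipy.stats import pearsonr

        gm, phen, truth = cohort
        w = np.asarray(SimulationConfig().resolved_panel().weights)
        wgrs = 9 / w.sum() * gm.counts @ w
        r_fast, p_fast = pearsonr(wgrs, phen["glucose_0_mmol_l"])
        r_post, p_post = pearsonr(wgrs, phen["glucose_120_mmol_l"])
        assert r_post > r_fast
        assert p_post < 0.05

    def test_diabetes_injection_count(self, panel):
        cfg = SimulationConfig(diabetes_fraction=0.03, seed=5)
        gm, phen, truth = generate_cohort(cfg)
        assert truth["n_diabetic_injected"] == round(0.03 * 1442)
        table, info = build_analysis_table(gm, phen, panel)
        assert info["n_excluded_diabetes"] == truth["n_diabetic_injected"]

    def test_missing_genotype_rate(self, panel):
        cfg = SimulationConfig(missing_genotype_rate=0.02, seed=6)
        gm, phen, _ = generate_cohort(cfg)
        assert 0.01 < gm.missing.mean() < 0.04
        table, info = build_analysis_table(gm, phen, panel)
        assert info["n_dropped_genotype"] == int((~gm.complete_rows()).sum())

    def test_unreachable_calibration_target_raises(self):
        from prediagrs.simulate import _calibrate_intercept

        with pytest.raises(CalibrationError, match="outside achievable"):
            _calibrate_intercept(0.5, lambda a: 0.1)  # fraction stuck below target
        with pytest.raises(CalibrationError):
            # realized fraction is a coarse step function that never lands in tol
            _calibrate_intercept(0.5, lambda a: 0.0 if a < 0 else 1.0, tol=1e-6)


class TestWriteFixture:
    def test_round_trips_and_truth_completeness(self, panel, tmp_path):
        cfg = SimulationConfig(n_subjects=60, seed=9, missing_genotype_rate=0.05)
        gm, phen, truth = generate_cohort(cfg)
        paths = write_fixture(gm, phen, truth, tmp_path, panel=panel)
        for p in paths.values():
            assert p.exists()
        back_tsv = read_genotypes(paths["genotypes_tsv"], panel)
        back_vcf = read_genotypes(paths["vcf"], panel)
        np.testing.assert_array_equal(back_tsv.missing, gm.missing)
        np.testing.assert_array_equal(back_vcf.missing, gm.missing)
        np.testing.assert_array_equal(
            back_tsv.counts[~gm.missing], gm.counts[~gm.missing]
        )
        np.testing.assert_array_equal(
            back_vcf.counts[~gm.missing], gm.counts[~gm.missing]
        )
        with open(paths["truth_json"]) as fh:
            saved = json.load(fh)
        # every generating parameter is recorded
        for key in (
            "n_subjects", "female_fraction", "beta_score", "target_prediabetes_prev",
            "obesity_prev", "effect_modification", "seed", "allele_freqs",
        ):
            assert key in saved["config"]
        n_records = sum(
            1 for line in paths["vcf"].read_text().splitlines() if not line.startswith("#")
        )
        assert n_records == 9
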