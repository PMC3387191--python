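"""Synthetic cohort generator with known ground truth.

Emulates a clinical OGTT cohort enriched for diabetes risk: 9 biallelic
SNPs in Hardy-Weinberg equilibrium, female predominance, ~28% prediabetes
and ~32% obesity. IGT and IFG statuses are drawn from explicit logistic
liabilities sharing age, BMI and a latent insulin-resistance variable;
the genetic term (per-allele log-OR on the weighted risk score) enters
the IGT liability only, so the score associates with post-load but not
fasting glucose. Because the binary statuses are generated directly from
a logistic model, a logistic regression of IGT on the score and
covariates is correctly specified and the injected per-allele OR is
recoverable. Glucose values are then drawn from status-conditional
truncated normals whose means/SDs match a typical at-risk European
cohort; insulin curves depend on the latent resistance (not on glycemic
status), keeping the Matsuda-ISI covariate nearly outcome-free.

Liability intercepts are calibrated by bisection: the IGT intercept to
the target IGT prevalence, then the IFG intercept to the target
*prediabetes* (union) prevalence.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.special import expit

from .genotype_qc import GenotypeMatrix, write_genotypes_tsv, write_genotypes_vcf
from .snp_panel import SNPPanel, default_panel

__all__ = ["SimulationConfig", "CalibrationError", "generate_cohort", "write_fixture"]

EFFECT_MODIFICATION_RULES = (None, "obese", "resistant", "obese_and_resistant")


class CalibrationError(RuntimeError):
    """Raised when liability-intercept bisection cannot reach its target."""


@dataclass
class SimulationConfig:
    """Generating parameters; defaults encode the emulated study conditions.

    ``beta_score`` is the log-OR per weighted-score unit (per risk
    allele) on the IGT liability. ``beta_lnisi``/``beta_lnisi_ifg`` are
    the liability coefficients on the latent log insulin-sensitivity
    scale (negative: lower sensitivity, higher risk).
    """

    n_subjects: int = 1442
    female_fraction: float = 959 / 1442
    panel: SNPPanel | None = None
    allele_freqs: tuple[float, ...] | None = None  # overrides panel frequencies
    beta_score: float = float(np.log(1.15))
    beta_age: float = 0.5
    beta_bmi: float = 0.4
    beta_lnisi: float = -1.0
    beta_age_ifg: float = 0.55
    beta_bmi_ifg: float = 0.5
    beta_lnisi_ifg: float = -0.7
    target_prediabetes_prev: float = 0.28
    target_igt_prev: float = 254 / 1442
    obesity_prev: float = 0.32
    effect_modification: str | None = None
    genetic_effect_on_fasting: bool = False  # robustness switch: add score to IFG liability
    diabetes_fraction: float = 0.0
    missing_genotype_rate: float = 0.0
    calibration_tol: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 10:
            raise ValueError("n_subjects must be at least 10")
        for name in ("female_fraction", "target_prediabetes_prev", "target_igt_prev", "obesity_prev"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.effect_modification not in EFFECT_MODIFICATION_RULES:
            raise ValueError(
                f"effect_modification must be one of {EFFECT_MODIFICATION_RULES}"
            )
        if not (0.0 <= self.diabetes_fraction < 0.5):
            raise ValueError("diabetes_fraction must lie in [0, 0.5)")
        if self.target_igt_prev >= self.target_prediabetes_prev:
            raise ValueError("target_igt_prev must be below target_prediabetes_prev")

    def resolved_panel(self) -> SNPPanel:
        return self.panel if self.panel is not None else default_panel()

    def resolved_freqs(self, panel: SNPPanel) -> np.ndarray:
        if self.allele_freqs is not None:
            f = np.asarray(self.allele_freqs, dtype=float)
            if f.shape != (panel.n,):
                raise ValueError("allele_freqs length must match the panel")
        else:
            if any(s.risk_allele_freq is None for s in panel):
                raise ValueError("panel lacks risk_allele_freq and no allele_freqs given")
            f = np.asarray([s.risk_allele_freq for s in panel], dtype=float)
        if np.any((f <= 0) | (f >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")
        return f


def _truncnorm(rng, lo, hi, loc, scale, size=None):
    """Inverse-CDF truncated-normal sampler, vectorised over array params."""
    lo_z = (np.asarray(lo, dtype=float) - loc) / scale
    hi_z = (np.asarray(hi, dtype=float) - loc) / scale
    a = st.norm.cdf(lo_z)
    b = st.norm.cdf(hi_z)
    u = rng.uniform(size=size if size is not None else np.broadcast(a, b).shape)
    x = loc + scale * st.norm.ppf(a + u * (b - a))
    return np.clip(x, lo, hi)


def _calibrate_intercept(target, realized_frac, lo=-30.0, hi=30.0, tol=0.005, max_iter=200):
    """Bisect the liability intercept until the realized fraction hits the target."""
    f_lo, f_hi = realized_frac(lo), realized_frac(hi)
    if not (f_lo <= target <= f_hi):
        raise CalibrationError(
            f"target {target:.3f} outside achievable range [{f_lo:.3f}, {f_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = realized_frac(mid)
        if abs(f - target) <= tol:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"bisection did not reach target {target:.3f} +/- {tol} in {max_iter} iterations "
        f"(last fraction {f:.3f}); the realized fraction moves in steps of 1/n — "
        "loosen calibration_tol for very small cohorts"
    )


def generate_cohort(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, dict]:
    """Generate one cohort: genotypes, phenotype table and a truth record.

    Deterministic given ``config`` (all randomness flows from
    ``config.seed``); repeated calls return identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    panel = config.resolved_panel()
    freqs = config.resolved_freqs(panel)
    tol = max(config.calibration_tol, 1.5 / n)

    subject_ids = [f"S{i + 1:05d}" for i in range(n)]
    n_female = int(round(n * config.female_fraction))
    sex = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(sex)

    age = _truncnorm(rng, 18.0, 80.0, 39.5, 13.0, size=n)
    z_age = (age - 40.0) / 13.0

    # lognormal BMI: median 28; sigma chosen so P(BMI >= 30) hits the target
    bmi_sigma = np.log(30.0 / 28.0) / st.norm.isf(config.obesity_prev)
    z_bmi = rng.standard_normal(n)
    bmi = 28.0 * np.exp(bmi_sigma * z_bmi)

    # latent log insulin resistance; lnS = -lnR is the log-sensitivity scale
    ln_r = 0.6 * z_bmi + 0.25 * z_age + rng.normal(0.0, 0.6, size=n)
    ln_s = -ln_r

    # genotypes: two independent Bernoulli(f) alleles per SNP -> HWE by construction
    counts = rng.binomial(2, freqs, size=(n, panel.n)).astype(np.int64)
    w = np.asarray(panel.weights)
    mean_wgrs = panel.n / w.sum() * float((w * 2 * freqs).sum())
    wgrs = panel.n / w.sum() * counts @ w
    score_c = wgrs - mean_wgrs

    obese = bmi >= 30.0
    resistant_latent = ln_r > np.median(ln_r)
    if config.effect_modification is None:
        modifier = np.ones(n)
    elif config.effect_modification == "obese":
        modifier = obese.astype(float)
    elif config.effect_modification == "resistant":
        modifier = resistant_latent.astype(float)
    else:
        modifier = (obese & resistant_latent).astype(float)

    eta_igt = (
        config.beta_score * modifier * score_c
        + config.beta_age * z_age
        + config.beta_bmi * z_bmi
        + config.beta_lnisi * ln_s
    )
    eta_ifg = (
        config.beta_age_ifg * z_age
        + config.beta_bmi_ifg * z_bmi
        + config.beta_lnisi_ifg * ln_s
    )
    if config.genetic_effect_on_fasting:
        eta_ifg = eta_ifg + config.beta_score * modifier * score_c
    u_igt = rng.uniform(size=n)
    u_ifg = rng.uniform(size=n)

    alpha_igt = _calibrate_intercept(
        config.target_igt_prev, lambda a: float(np.mean(u_igt < expit(a + eta_igt))), tol=tol
    )
    igt = u_igt < expit(alpha_igt + eta_igt)

    def union_frac(a: float) -> float:
        return float(np.mean(igt | (u_ifg < expit(a + eta_ifg))))

    alpha_ifg = _calibrate_intercept(config.target_prediabetes_prev, union_frac, tol=tol)
    ifg = u_ifg < expit(alpha_ifg + eta_ifg)

    # status-conditional glucose; mild continuous dependence on resistance
    g0 = np.where(
        ifg,
        _truncnorm(rng, 5.6, 6.99, 5.95 + 0.10 * ln_r, 0.30, size=n),
        _truncnorm(rng, 3.8, 5.599, 5.00 + 0.12 * ln_r, 0.35, size=n),
    )
    g120 = np.where(
        igt,
        _truncnorm(rng, 7.8, 11.09, 8.80 + 0.25 * ln_r, 0.90, size=n),
        _truncnorm(rng, 3.2, 7.799, 5.90 + 0.30 * ln_r, 1.00, size=n),
    )

    # injected diabetic subjects (for exclusion bookkeeping)
    n_diab = int(round(config.diabetes_fraction * n))
    diab_idx = rng.choice(n, size=n_diab, replace=False) if n_diab else np.array([], dtype=int)
    if n_diab:
        g0[diab_idx] = _truncnorm(rng, 7.0, 10.0, 7.8, 0.6, size=n_diab)
        g120[diab_idx] = _truncnorm(rng, 11.1, 18.0, 12.5, 1.2, size=n_diab)

    # OGTT curve interpolation with multiplicative noise
    g60 = np.maximum(g0, g120) + 1.2 * np.exp(rng.normal(0.0, 0.25, size=n))
    g30 = g0 + 0.75 * (g60 - g0) * np.exp(rng.normal(0.0, 0.15, size=n))
    g90 = g120 + 0.60 * (g60 - g120) * np.exp(rng.normal(0.0, 0.15, size=n))

    ins0 = 58.0 * np.exp(0.7 * ln_r + rng.normal(0.0, 0.2, size=n))
    curve_mult = {30: 6.5, 60: 6.0, 90: 5.0, 120: 4.5}
    insulin = {0: ins0}
    for t, m in curve_mult.items():
        insulin[t] = ins0 * m * np.exp(rng.normal(0.0, 0.18, size=n))

    triglycerides = np.exp(np.log(1.25) + 0.35 * z_bmi + 0.30 * ln_r + rng.normal(0.0, 0.4, size=n))
    hdl = np.clip(np.where(sex == "female", 1.5, 1.2) + rng.normal(0.0, 0.35, size=n), 0.5, None)
    ldl = np.clip(3.0 + 0.10 * z_age + rng.normal(0.0, 0.8, size=n), 0.8, None)
    family_history = (rng.uniform(size=n) < 0.48).astype(int)
    lipid_lowering = (rng.uniform(size=n) < 0.02 + 0.01 * (age > 50)).astype(int)
    antihypertensive = (rng.uniform(size=n) < expit(-2.6 + 0.05 * (age - 40.0))).astype(int)

    phen = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "family_history": family_history,
            "lipid_lowering": lipid_lowering,
            "antihypertensive": antihypertensive,
            "triglycerides_mmol_l": triglycerides,
            "hdl_mmol_l": hdl,
            "ldl_mmol_l": ldl,
            "glucose_0_mmol_l": g0,
            "glucose_30_mmol_l": g30,
            "glucose_60_mmol_l": g60,
            "glucose_90_mmol_l": g90,
            "glucose_120_mmol_l": g120,
            "insulin_0_pmol_l": insulin[0],
            "insulin_30_pmol_l": insulin[30],
            "insulin_60_pmol_l": insulin[60],
            "insulin_90_pmol_l": insulin[90],
            "insulin_120_pmol_l": insulin[120],
        }
    )

    missing = np.zeros_like(counts, dtype=bool)
    if config.missing_genotype_rate > 0:
        missing = rng.uniform(size=counts.shape) < config.missing_genotype_rate
    gm = GenotypeMatrix(subject_ids, list(panel.rsids), np.where(missing, 0, counts), missing)

    non_diab = np.ones(n, dtype=bool)
    non_diab[diab_idx] = False
    truth = {
        "config": _config_record(config, panel, freqs),
        "alpha_igt": alpha_igt,
        "alpha_ifg": alpha_ifg,
        "mean_weighted_score": float(wgrs.mean()),
        "sd_weighted_score": float(wgrs.std(ddof=1)),
        "expected_mean_weighted_score": mean_wgrs,
        "n_diabetic_injected": n_diab,
        "realized_igt_prev": float(igt[non_diab].mean()),
        "realized_ifg_prev": float(ifg[non_diab].mean()),
        "realized_prediabetes_prev": float((igt | ifg)[non_diab].mean()),
        "modified_fraction": float(modifier.mean()),
    }
    return gm, phen, truth


def _config_record(config: SimulationConfig, panel: SNPPanel, freqs: np.ndarray) -> dict:
    rec = asdict(config)
    rec["panel"] = panel.rsids
    rec["allele_freqs"] = [float(f) for f in freqs]
    return rec


def write_fixture(
    gm: GenotypeMatrix,
    phen: pd.DataFrame,
    truth: dict,
    out_dir: str | Path,
    panel: SNPPanel | None = None,
    risk_as_ref: tuple[str, ...] = ("rs13266634",),
) -> dict[str, Path]:
    """Write a generated cohort as plain-text fixture files.

    Emits genotypes.vcf (one SNP written risk-allele-as-REF so both VCF
    orientations are exercised), genotypes.tsv, phenotypes.tsv and
    truth.json; the genotype files round-trip losslessly through
    :func:`prediagrs.genotype_qc.read_genotypes`.
    """
    panel = panel if panel is not None else default_panel()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "genotypes_tsv": out / "genotypes.tsv",
        "phenotypes_tsv": out / "phenotypes.tsv",
        "truth_json": out / "truth.json",
    }
    write_genotypes_vcf(gm, panel, paths["vcf"], risk_as_ref=risk_as_ref)
    write_genotypes_tsv(gm, paths["genotypes_tsv"])
    phen.to_csv(paths["phenotypes_tsv"], sep="\t", index=False)
    with open(paths["truth_json"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
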