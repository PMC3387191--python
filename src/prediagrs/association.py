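"""Logistic association models for dichotomous glycemic outcomes.

Each model regresses a dichotomous prediabetes outcome on a genetic risk
score plus covariates. Controls are always the NGT group; subjects in the
complementary prediabetes categories are excluded from that model (e.g.
the isolated-IGT model drops isolated-IFG and IFG+IGT subjects). The
score term's p-value comes from a 1-df likelihood-ratio test (deviance
difference against the model without the score), while the per-allele OR
and its 95% CI are Wald-based — effect display and testing are kept
separate on purpose. Covariates listed in ``log_transform`` enter as
natural logarithms. No multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .glycemic import GlycemicCategory
from .metabolic import median_isi_split

__all__ = [
    "ModelSpec",
    "ModelResult",
    "SeparationError",
    "fit_model",
    "run_primary_analyses",
    "run_stratified_analyses",
    "BASE_COVARIATES",
    "EXTENDED_COVARIATES",
    "DEFAULT_LOG_TRANSFORM",
]

logger = logging.getLogger(__name__)

# outcome -> (case categories, categories excluded from the model)
OUTCOME_DEFS: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "IGT_combined": (
        frozenset({"ISOLATED_IGT", "IFG_IGT"}),
        frozenset({"ISOLATED_IFG"}),
    ),
    "prediabetes": (
        frozenset({"ISOLATED_IFG", "ISOLATED_IGT", "IFG_IGT"}),
        frozenset(),
    ),
    "isolated_IGT": (
        frozenset({"ISOLATED_IGT"}),
        frozenset({"ISOLATED_IFG", "IFG_IGT"}),
    ),
    "isolated_IFG": (
        frozenset({"ISOLATED_IFG"}),
        frozenset({"ISOLATED_IGT", "IFG_IGT"}),
    ),
}

BASE_COVARIATES = ("sex", "age", "bmi", "isi_matsuda")
EXTENDED_COVARIATES = BASE_COVARIATES + (
    "ldl_mmol_l",
    "hdl_mmol_l",
    "triglycerides_mmol_l",
    "lipid_lowering",
    "antihypertensive",
    "family_history",
)
# right-skewed by construction; configurable per ModelSpec
DEFAULT_LOG_TRANSFORM = ("isi_matsuda", "triglycerides_mmol_l")


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation detected during a logistic fit."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one logistic model."""

    outcome: str
    score_variable: str = "grs_weighted"
    covariates: tuple[str, ...] = BASE_COVARIATES
    log_transform: tuple[str, ...] = ("isi_matsuda",)
    stratum: str | None = None  # label; the caller supplies the row filter
    label: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_DEFS:
            raise ValueError(f"unknown outcome {self.outcome!r}; one of {sorted(OUTCOME_DEFS)}")
        extra = set(self.log_transform) - set(self.covariates)
        if extra:
            raise ValueError(f"log_transform names not among covariates: {sorted(extra)}")


@dataclass
class ModelResult:
    """Fitted logistic model summary for one ModelSpec."""

    spec: ModelSpec
    n: int
    n_cases: int
    coef: dict[str, float]
    se: dict[str, float]
    or_per_allele: float
    or_ci: tuple[float, float]
    lrt_p_score: float
    converged: bool
    skipped: bool = False
    note: str = ""

    def to_row(self) -> dict:
        return {
            "label": self.spec.label or self.spec.outcome,
            "outcome": self.spec.outcome,
            "score_variable": self.spec.score_variable,
            "stratum": self.spec.stratum or "overall",
            "n": self.n,
            "n_cases": self.n_cases,
            "or_per_allele": self.or_per_allele,
            "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1],
            "lrt_p_score": self.lrt_p_score,
            "converged": self.converged,
            "skipped": self.skipped,
            "note": self.note,
        }


def _build_design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.Series, pd.DataFrame]:
    cases, excluded = OUTCOME_DEFS[spec.outcome]
    cats = data["category"].astype(str)
    if (cats == GlycemicCategory.DIABETES.value).any():
        raise ValueError("diabetes rows must be excluded before model fitting")
    d = data.loc[~cats.isin(excluded)]
    y = d["category"].astype(str).isin(cases).astype(float)
    cols = {spec.score_variable: d[spec.score_variable].astype(float)}
    for cov in spec.covariates:
        if cov == "sex":
            vals = (d["sex"].astype(str).str.lower() == "male").astype(float)
        else:
            vals = d[cov].astype(float)
        if cov in spec.log_transform:
            if (vals <= 0).any():
                raise ValueError(f"covariate {cov} must be strictly positive for ln-transform")
            vals = np.log(vals)
            cov = f"ln_{cov}"
        cols[cov] = vals
    X = pd.DataFrame(cols, index=d.index)
    return y, X


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        res = model.fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed ({exc}); check for separation") from exc
    if np.abs(res.params).max() > 50:
        raise SeparationError(
            "diverging coefficients suggest (quasi-)separation: "
            + ", ".join(f"{k}={v:.1f}" for k, v in res.params.items() if abs(v) > 50)
        )
    return res


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> ModelResult:
    """Fit one logistic model and the score-term likelihood-ratio test.

    ``data`` is an analysis table with a ``category`` column (diabetes
    already excluded), the score columns and the covariates.
    """
    y, X = _build_design(data, spec)
    n = len(y)
    n_cases = int(y.sum())
    if n_cases == 0 or n_cases == n:
        raise ValueError(f"outcome {spec.outcome} is not binary after exclusions (cases={n_cases})")
    if n <= X.shape[1] + 1:
        raise ValueError(f"n={n} too small for {X.shape[1] + 1} parameters")
    full = _fit_logit(y.to_numpy(), X)
    reduced = _fit_logit(y.to_numpy(), X.drop(columns=[spec.score_variable]))
    lrt = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(st.chi2.sf(lrt, df=1))
    beta = float(full.params[spec.score_variable])
    se = float(full.bse[spec.score_variable])
    return ModelResult(
        spec=spec,
        n=n,
        n_cases=n_cases,
        coef=dict(full.params),
        se=dict(full.bse),
        or_per_allele=float(np.exp(beta)),
        or_ci=(float(np.exp(beta - 1.959964 * se)), float(np.exp(beta + 1.959964 * se))),
        lrt_p_score=min(max(p, np.nextafter(0, 1)), 1.0),
        converged=bool(full.mle_retvals.get("converged", True)),
    )


def run_primary_analyses(
    data: pd.DataFrame,
    log_transform: tuple[str, ...] = DEFAULT_LOG_TRANSFORM,
) -> list[ModelResult]:
    """The whole-cohort model grid.

    {simple, weighted} scores x {combined IGT, prediabetes, isolated IGT,
    isolated IFG} with sex/age/BMI/ln-ISI adjustment, plus the extended
    lipid/medication/family-history model for combined IGT with the
    weighted score, plus the 7-SNP secretion score model for prediabetes.
    """
    base_log = tuple(c for c in log_transform if c in BASE_COVARIATES)
    specs = [
        ModelSpec(
            outcome=outcome,
            score_variable=score,
            covariates=BASE_COVARIATES,
            log_transform=base_log,
            label=f"{outcome}~{score}",
        )
        for score in ("grs_simple", "grs_weighted")
        for outcome in OUTCOME_DEFS
    ]
    specs.append(
        ModelSpec(
            outcome="IGT_combined",
            score_variable="grs_weighted",
            covariates=EXTENDED_COVARIATES,
            log_transform=tuple(c for c in log_transform if c in EXTENDED_COVARIATES),
            label="IGT_combined~grs_weighted+extended",
        )
    )
    specs.append(
        ModelSpec(
            outcome="prediabetes",
            score_variable="grs7_simple",
            covariates=BASE_COVARIATES,
            log_transform=base_log,
            label="prediabetes~grs7_simple",
        )
    )
    return [fit_model(data, spec) for spec in specs]


def run_stratified_analyses(
    data: pd.DataFrame,
    score_variable: str = "grs_weighted",
    outcome: str = "IGT_combined",
    min_cases: int = 10,
) -> tuple[list[ModelResult], pd.DataFrame]:
    """Combined-IGT models within sex / obesity / insulin-sensitivity strata.

    The stratifying variable is dropped from the adjustment set within its
    own strata (sex strata adjust for age+BMI+ISI, BMI strata for
    sex+age+ISI, ISI strata for sex+age+BMI). Strata with fewer than
    ``min_cases`` outcome cases are flagged and skipped. Returns the
    results plus a 7-row forest table (overall, female, male, lean, obese,
    sensitive, resistant).
    """
    isi_threshold, resistant = median_isi_split(data["isi_matsuda"].to_numpy(dtype=float))
    sex = data["sex"].astype(str).str.lower()
    obese = data["bmi"].to_numpy(dtype=float) >= 30.0
    strata: list[tuple[str, np.ndarray, tuple[str, ...]]] = [
        ("overall", np.ones(len(data), dtype=bool), BASE_COVARIATES),
        ("female", (sex == "female").to_numpy(), ("age", "bmi", "isi_matsuda")),
        ("male", (sex == "male").to_numpy(), ("age", "bmi", "isi_matsuda")),
        ("lean", ~obese, ("sex", "age", "isi_matsuda")),
        ("obese", obese, ("sex", "age", "isi_matsuda")),
        ("sensitive", ~resistant, ("sex", "age", "bmi")),
        ("resistant", resistant, ("sex", "age", "bmi")),
    ]
    results = []
    for name, mask, covs in strata:
        sub = data.loc[mask]
        spec = ModelSpec(
            outcome=outcome,
            score_variable=score_variable,
            covariates=covs,
            log_transform=tuple(c for c in DEFAULT_LOG_TRANSFORM if c in covs),
            stratum=name,
            label=f"{outcome}~{score_variable}|{name}",
        )
        cases, excluded = OUTCOME_DEFS[outcome]
        cats = sub["category"].astype(str)
        n_cases = int(cats.isin(cases).sum())
        if n_cases < min_cases:
            logger.warning("stratum %s has %d cases (<%d); fit skipped", name, n_cases, min_cases)
            results.append(
                ModelResult(
                    spec=spec,
                    n=int((~cats.isin(excluded)).sum()),
                    n_cases=n_cases,
                    coef={},
                    se={},
                    or_per_allele=float("nan"),
                    or_ci=(float("nan"), float("nan")),
                    lrt_p_score=float("nan"),
                    converged=False,
                    skipped=True,
                    note=f"fewer than {min_cases} outcome cases",
                )
            )
            continue
        results.append(fit_model(sub, spec))
    forest = pd.DataFrame(
        {
            "stratum": [r.spec.stratum for r in results],
            "n": [r.n for r in results],
            "n_cases": [r.n_cases for r in results],
            "or_per_allele": [r.or_per_allele for r in results],
            "or_se": [
                r.or_per_allele * r.se.get(score_variable, float("nan")) for r in results
            ],
            "or_ci_low": [r.or_ci[0] for r in results],
            "or_ci_high": [r.or_ci[1] for r in results],
            "lrt_p_score": [r.lrt_p_score for r in results],
        }
    )
    forest.attrs["isi_threshold"] = isi_threshold
    return results, forest
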