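# Methods

`prediagrs` implements a cross-sectional association analysis between a
weighted genetic risk score (GRS) built from established type-2-diabetes
risk SNPs and prediabetes phenotypes defined from a 75-g oral glucose
tolerance test (OGTT), together with the power/sensitivity calculations
such a study requires and a synthetic-cohort generator with known ground
truth. This note records the models, the defaults and why they were
chosen, the numerical details, and what the synthetic data can and
cannot demonstrate.

## Risk scores

Each panel SNP is oriented to its risk allele and coded as the risk-allele
dosage a_ij ∈ {0, 1, 2}. The simple score is Σ_i a_ij. The weighted score
is

    ρ_j = (N / Σ_i w_i) · Σ_i w_i a_ij ,   w_i = ln(OR_i),

where OR_i is the literature per-allele odds ratio for diabetes. The
normalisation constant N/Σw restores the allele-count scale: ρ is bounded
by [0, 2N], equals the simple score when all ORs coincide, and is exactly
2N for a subject homozygous for every risk allele. ln(OR) is used because
per-allele effects are additive on the log-odds scale; the weight
function is pluggable so OR-scale weighting can be compared. The
secretion-restricted variants apply the same formulas to the sub-panel of
loci flagged as primarily insulin-secretion related (7 of the default 9;
the FTO and PPARG loci are the adiposity/sensitivity loci omitted),
renormalised by the sub-panel size.

The packaged panel ships literature-typical European-ancestry ORs and
risk-allele frequencies as *editable defaults* — they are configuration,
not estimates this package asserts. The loader refuses rows with OR < 1
instead of silently flipping alleles, because a silent flip can hide an
orientation error in the genotype file.

## Genotype handling and Hardy–Weinberg QC

Genotypes are read from VCF v4.x (GT fields, biallelic sites; dosage is
inverted automatically when the risk allele is REF) or from a tabular TSV
of 0/1/2/NA cells. Analysis is complete-case: subjects missing any panel
genotype or any required phenotype are dropped and counted; no imputation
is attempted, because fractional scores from partial panels would break
the scale comparability the normalisation exists to provide.

QC uses the exact conditional Hardy–Weinberg test: conditioning on the
observed allele counts, the p-value sums the probabilities of all
heterozygote counts no more probable than the one observed (two-sided by
probability ordering). Probabilities are computed with log-gamma
arithmetic and renormalised, which is stable to n in the thousands; the
test suite checks exhaustive agreement with an independent exact-rational
enumeration for every configuration with n ≤ 50. The QC report lists
p-values without auto-exclusion — a rejection threshold is a study-level
decision, not a package default.

## Glycemic classification

Fasting and 2-h OGTT glucose (mmol/l, compared without rounding) define
the categories: diabetes (fasting ≥ 7.0 or 2-h ≥ 11.1; excluded from all
analyses), otherwise an IFG flag at fasting ≥ 5.6 and an IGT flag at 2-h
≥ 7.8 give NGT / isolated IFG / isolated IGT / IFG+IGT. Two composites
are derived: *combined IGT* (any elevated 2-h glucose, independently of
fasting glycemia) and *prediabetes* (IFG and/or IGT). Classification is
monotone: raising either glucose value never yields a less severe
category.

## Metabolic indices

The Matsuda–DeFronzo whole-body insulin sensitivity index is
10000/√(G0·I0·Gmean·Imean) with glucose in mg/dl and insulin in µU/ml and
unweighted means over the five samples at 0/30/60/90/120 min (the
original five-point formulation). Inputs are mmol/l and pmol/l;
conversions 18.016 mg/dl per mmol/l and 6.0 pmol/l per µU/ml are applied
internally. The insulin divisor is configurable (6.945 is the other
common convention) and recorded in the run log; ISI values are therefore
comparable only within one convention. HOMA-IR and HOMA-B are the
standard HOMA1 fasting equations; HOMA-B is undefined at fasting glucose
≤ 3.5 mmol/l and returned as NaN with a warning rather than a spurious
number.

The insulin-resistant/-sensitive strata split the cohort at the sample
median ISI; subjects exactly at the median count as sensitive (the ≥
side), so with distinct values the two strata differ in size by at most
one.

## Association models

Each model is a maximum-likelihood logistic regression of a dichotomous
outcome on one score variable plus covariates. Controls are always NGT;
subjects in the complementary prediabetes categories are excluded from
that model (isolated-IGT models drop isolated-IFG and IFG+IGT subjects,
and so on), so each contrast is "this phenotype vs normal tolerance".
The score term's p-value is a 1-df likelihood-ratio test (deviance
difference against the model without the score); the per-allele OR and
95% CI are Wald-based. Keeping LRT for inference and Wald for display
mirrors standard epidemiological practice and makes the p-value invariant
to affine rescaling of the score.

The default adjustment set is sex, age, BMI and ln ISI; the extended
model adds LDL, HDL, ln triglycerides, lipid-lowering and
antihypertensive medication, and family history (total cholesterol is
omitted as collinear with LDL). The ln-transform set (ISI, triglycerides,
and for descriptive tables the insulin/HOMA variables) is configurable —
it encodes "right-skewed by construction" rather than a per-dataset
normality test. No multiple-testing correction is applied: the design
tests one hypothesis through a small, pre-specified grid. Quasi-complete
separation is detected (diverging coefficients or solver failure) and
raised as an explicit error, never returned silently; non-convergence is
flagged on the result.

Stratified analyses fit the combined-IGT model within sex, obesity
(BMI ≥ 30), and median-ISI strata, dropping the stratifying covariate
from its own strata's adjustment set. Strata with fewer than 10 outcome
cases are flagged and skipped. The output is a 7-row forest table
(overall, female/male, lean/obese, sensitive/resistant).

## Power and sensitivity analysis

The minimum detectable standardised difference for a two-group comparison
of sizes (n1, n2) at two-sided α and power 1−β uses the normal
approximation d = (z_{1−α/2} + z_{1−β})·√(1/n1 + 1/n2); a noncentral-t
refinement is available (`method="nct"`) and differs by < 0.001 at
cohort-scale n. Each at-risk subgroup is compared against the remainder
of the cohort, e.g. (396 vs 1046) for prediabetes in a cohort of 1442.
The minimal-n computation is the exact integer inversion of the power
function under a given allocation ratio. The minimum detectable
per-allele OR for a continuous-score logistic model uses the Hsieh-type
large-sample formula β_SD = (z_{1−α/2} + z_{1−β})/√(n·p(1−p)) rescaled by
the score SD; because this formula ignores intercept estimation it is
validated against a Monte-Carlo LRT power oracle in the tests (simulated
power at the returned OR falls near the 0.8 target) rather than trusted
blindly.

## Synthetic cohort generator

The generator emulates an OGTT cohort enriched for diabetes risk. Default
conditions: n = 1442 with 959 women; age truncated-normal (mean 39.5, SD
13, range 18–80); BMI lognormal with median 28 kg/m² and σ set so that
P(BMI ≥ 30) equals the 32% obesity target; a latent log insulin-resistance
variable R driven by BMI and age plus noise; 9 SNPs drawn as two
independent Bernoulli(f_i) alleles (Hardy–Weinberg by construction) with
the panel's default frequencies.

Binary glycemic statuses come from explicit logistic liabilities:

    logit P(IGT_j) = α_IGT + β·m_j·(ρ_j − E[ρ]) + 0.5·z_age + 0.4·z_BMI + ln R_j
    logit P(IFG_j) = α_IFG + 0.55·z_age + 0.5·z_BMI + 0.7·ln R_j

with β = ln(per-allele OR) (default 1.15) and m_j an optional
effect-modification mask (all subjects, obese only, resistant only, or
obese-and-resistant). The genetic term sits on the IGT liability only, so
the score associates with post-load but not fasting glucose; a config
switch adds it to the IFG liability for robustness testing. α_IGT is
calibrated by bisection to the IGT prevalence target (254/1442) and α_IFG
to the *union* (prediabetes) prevalence target of 28% ± the calibration
tolerance (0.005, floored at 1.5/n for small cohorts); calibrating the
union directly is what guarantees the headline prevalence, with the
isolated-IFG share implied (~16–18%).

Glucose values are then drawn from status-conditional truncated normals
matched to the group means/SDs of a typical at-risk European cohort
(e.g. non-IFG fasting 5.0 ± 0.35 below 5.6; IGT 2-h 8.8 ± 0.9 on
[7.8, 11.1)), with a mild continuous dependence on ln R; intermediate
OGTT points are interpolated with multiplicative noise. Insulin curves
scale with exp(0.7·ln R) and status-independent time-point multipliers.
Two generation choices are deliberate and load-bearing:

1. **Statuses are drawn from the logistic model, then glucose is drawn
   conditional on status** (rather than thresholding a continuous glucose
   that contains the genetic term). This makes the fitted logistic model
   correctly specified for the score term, so the injected per-allele OR
   is a well-defined estimand — the recovery check measures estimator
   bias, not model mismatch.
2. **Insulin curves do not depend on glycemic status given R.** The
   Matsuda ISI covariate is then only weakly outcome-dependent (through
   the glucose terms), keeping the attenuation of the score coefficient
   from adjusting for a partly outcome-caused covariate well under the 5%
   recovery tolerance. The cost is realism: real IGT subjects show
   markedly higher 2-h insulin than the generator produces for given
   resistance.

What passing tests on this generator do **not** show about real data:
the generator has no linkage disequilibrium between SNPs, no family
structure, no genotype–covariate correlation (so confounding of the score
by ancestry or lifestyle is absent by construction), Gaussian-ish
phenotype noise, and OGTT curve shapes that are plausible but
unconstrained at 30/60/90 min. Calibration and recovery results therefore
validate the *pipeline's statistics*, not any claim about a real cohort.

For the effect-modification demonstration the configured scenario is a
per-allele OR of 1.5 confined to obese *and* latent-resistant subjects.
The success criterion is the full qualitative pattern: score LRT p < 0.05
in the obese and resistant strata and p ≥ 0.05 in the lean and sensitive
strata. Because the sensitive stratum is defined by measured ISI while
the effect is gated on latent R (~90% concordant median splits), a small
contamination of the sensitive stratum is expected and the pattern
reproduces in roughly 85–90% of replicates, above the 80% acceptance
line.

## Numerical choices and degenerate inputs

- Thresholds are compared with ≥ on the elevated side, exactly as stated,
  without rounding.
- The HWE test treats ties in the probability ordering with a 1+1e-12
  relative tolerance so exact-rational ties are included.
- LRT statistics are clipped at 0 (optimizer noise can make the reduced
  model appear marginally better); p-values are clipped into (0, 1].
- Bisection for liability intercepts brackets [−30, 30] on the logit
  scale and errors with diagnostics if the target is unreachable.
- Monomorphic SNPs get HWE p = 1; empty secretion subsets, all-zero
  weight vectors, non-binary outcomes and empty complete-case
  intersections raise immediately.
- Problem sizes in the simulation-based checks (1000 null replicates at
  n = 1442; 100 recovery replicates at n = 5000; 5000 Monte-Carlo power
  replicates; 100 effect-modification replicates) were chosen so each
  check's Monte-Carlo error is small relative to its acceptance band
  while the whole suite stays quick to run.

## Known limitations

- Real-cohort coefficient magnitudes are not reproducible here: they
  depend on covariate scalings and collinearity structure (e.g. the
  negative BMI coefficient that appears once ISI is adjusted for in real
  data) that the generator does not emulate.
- The minimum detectable OR depends on the cohort's realized score SD;
  only orderings and simulation consistency are asserted, not specific
  published values.
- The default panel ORs/frequencies are placeholders for configuration;
  any substantive use requires current meta-analytic estimates.
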