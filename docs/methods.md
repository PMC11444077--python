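# Methods notes

This note records the modelling assumptions, default parameter choices,
numerical conventions, and known limitations behind each stage of the
package. It documents what the code does and why; every number quoted here
is either a configurable default or a value the tests and
`scripts/acceptance.py` actually compute.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes in a
pooled multi-cohort pregnancy study; it is the package's substitute for
access-controlled cohort microdata and is itself first-class, tested code.

**Cohort structure.** Defaults are 13 cohorts × 385 dyads (≈5000 dyads,
the scale of the pooled US analyses this mirrors). Cohorts differ by a
normal random intercept on gestational age (SD 0.30 weeks by default; in
binary-outcome mode the same parameter acts on the log-odds scale) and
alternate between creatinine and specific-gravity dilution measurement.

**Covariates.** Categorical prevalences default to the marginals of a
large pooled US pregnancy sample (43% non-Hispanic White, 24% non-Hispanic
Black, 25% Hispanic/Latino; five education levels; parity 0/1/2/3/4 with
6% missing; 6% tobacco use with 20% missing; balanced child sex); maternal
age is normal (mean 28.5, SD 5.8, truncated 16–45). Covariates shift both
outcomes (e.g., −0.375 weeks gestation and −267 g birthweight for
non-Hispanic Black vs White mothers) and the latent exposure propensity
(e.g., +0.20 log10 units for non-Hispanic Black mothers, −0.17 for some
college or more), so they are genuine confounders and adjustment is
exercised, not decorative.

**Exposure.** Each of 14 metabolites has a dyad-level latent log10 ng/mL
median (between-dyad SD 0.40) plus specimen-level noise (SD 0.25).
Defaults were calibrated once so that processed group molar-sum medians
land near published pooled-pregnancy values (LMW ≈ 423, HMW ≈ 155,
DEHP ≈ 101, phthalic acid ≈ 220, DiNP ≈ 28, DnOP ≈ 9, DiDP ≈ 5 nmol/L);
because only group medians/IQRs are published, the per-metabolite split is
a modelling choice, not a claim about any real cohort. Specimens inherit a
dilution multiplier (creatinine median 105 mg/dL or specific gravity
median 1.016, log-normal spread), so Boeninger standardization has real
work to do. Censoring compares the measured (diluted) concentration to the
per-metabolite LOD; the latent value is then discarded — only the flag and
the LOD survive, as in real assay output. Default LODs give >69% detection
for every metabolite. Specimens: per trimester, a dyad is sampled with
probability 0.45/0.75/0.70 and contributes 1–3 specimens (probabilities
0.70/0.20/0.10), with collection week uniform within the trimester; dyads
with no specimen anywhere are given one second-trimester specimen.

**Gestational age.** A single normal cannot simultaneously produce the
published mean (≈38.8 weeks), SD (≈1.8), and preterm fraction (≈8%): the
normal left tail below 37 weeks at those moments holds ≈16% of births,
twice the observed rate, because real gestational age is left-skewed. The
base draw is therefore a two-component mixture — a bulk component
(SD 0.58·ga_sd) and an early-delivery tail (probability 0.055, offset
−2.42·ga_sd, SD 1.04·ga_sd) — calibrated to mean ≈38.8, marginal SD ≈1.6,
and P(<37) ≈ 8% under the default covariate mix. Cohort, covariate, and
exposure effects shift the draw additively, so linear-model slope recovery
is unaffected by the skew. Exposure effects are per log10 unit of the
centred true group molar sum.

**Binary-outcome mode.** When a preterm odds ratio is configured, preterm
status is drawn first from the logistic model (base rate 8%, cohort
intercepts, covariate log-odds effects, exposure effect), and gestational
age is then drawn from truncated normals conditional on status — so the
derived <37-week flag carries exactly the configured odds ratios.

**Birthweight** is linear in gestational age (185 g/week around a
3312 g mean) plus covariate effects and N(0, 430 g) noise; birth length is
analogous. This makes birthweight-for-gestational-age z-scores exercisable;
no published generative model exists for these quantities, so the linear
form is the package's own choice.

**Determinism.** One integer seed drives all substreams through
`numpy.random.SeedSequence.spawn`; identical configs give byte-identical
tables.

**What the generator does not emulate** (hence what passing tests do not
show about real data): realistic between-metabolite correlation beyond the
shared demographic propensity, batch or laboratory effects, cohort-specific
covariate distributions, gestational-age measurement error, and the
distinction between spontaneous and medically induced preterm birth.

## Exposure processing

The processing order — LOD substitution, then dilution standardization,
then molar conversion, then group summation, then averaging, then log10 —
is a contract and is property-tested (scale equivariance, fixed point at
the cohort-median dilution, monotone group sums).

Choices on points the field leaves open:

- Boeninger standardization uses the conventional ratio forms with the
  cohort-specific median as anchor; phthalic acid is standardized like any
  other metabolite.
- Group sums are plain molar sums of constituents (no constituent
  weighting). A cohort missing any constituent assay contributes no values
  for that group but remains in all others.
- Detection filter denominators: specimens for the >50% rule, distinct
  participants for the ≥1000 rule.
- An unflagged concentration below the LOD is treated as below-LOD with a
  warning (conservative reading of assay output).
- Trimester cut points (no universal definition): T1 <14 completed weeks,
  T2 14–<28, T3 ≥28.
- Molecular weights ship as an editable constants table (MEP 194.18 …
  phthalic acid 166.13 g/mol).

## Outcome derivation

Preterm <37.0 weeks; term categories tile [20, 45) with half-open
intervals (preterm <37, early term 37–<39, term 39–<41, late term ≥41);
low birthweight <2500 g overall and within preterm/term strata.
Birthweight-for-gestational-age z-scores use a reference table by child
sex, binary parity stratum (nulliparous vs parous — finer strata are not
identifiable from the data sizes involved), and completed week; since the
published US reference is not redistributable, the package accepts any
reference CSV and provides an empirical builder (used in tests, where
self-standardisation must give mean 0, SD 1, and 10%/10% SGA/LGA tails).
Cells thinner than 20 births fall back to sex × week statistics. SGA/LGA
cut points default to the normal deciles ±1.2816 and are configurable.

## Association models

Linear outcomes: REML linear mixed model with a cohort random intercept
(statsmodels MixedLM). When the estimated intercept variance is
numerically negligible (ICC < 0.005), the GLS weights carry only noise, so
the model is refit as OLS; this also makes the zero-variance limit agree
exactly with the non-hierarchical fit. Single-cohort data degrade to a
fixed-intercept fit with a warning.

Binary outcomes: random-intercept logistic regression fit by maximum
likelihood with adaptive Gauss–Hermite quadrature (25 nodes; per-cluster
Newton recentring, Fisher-identity gradients, observed-information Wald
SEs). This is implemented in-package because no installed Python library
offers a frequentist binomial GLMM; a test cross-checks coefficient and SE
against R's `lme4::glmer` (nAGQ = 25) at 1–2% relative tolerance. Since
every binary outcome is <10% prevalent, odds ratios are read as risk
ratios downstream.

Covariate conventions: maternal age continuous (missing → dyad dropped);
race/ethnicity with non-Hispanic White reference; education dichotomised
(high school or less vs some college and higher) for modelling even though
descriptive tables keep finer levels; parity 0/1/≥2; categorical
missingness is kept as an explicit level rather than dropped, because the
data such analyses pool report substantial categorical missingness while
still using those covariates. Child sex and parity are excluded when the
outcome is the z-score (already standardised on them). Wald 95% CIs
throughout; no multiple-testing adjustment (grouping into seven chemical
classes is the comparison-reduction strategy); significance read at
nominal 0.05.

Sensitivity machinery: stratified refits (no interaction terms; strata
with <2 cohorts skipped), leave-one-out by cohort (influence flag on sign
flip or a >30%-of-estimate shift, configurable), and added-covariate
reports (percent coefficient change, flagged above 15%).

## Burden engine

The counterfactual sets everyone below the 10th exposure percentile to
zero effect, treats the 10–24th bin as reference, and assigns each higher
bin the exposure at its lower bound — a deliberately conservative binning.
Bin weights are the bin population fractions (0.25/0.25/0.15/0.10).

- Weighted percentiles use left-continuous CDF inversion (smallest sample
  value whose cumulative normalised weight reaches p) — the survey
  step-function convention, testable against brute-force enumeration.
- The continuous path turns decrements into probability increments by
  shifting a normal gestational-age distribution (μ 38.73, σ 2.82 weeks,
  threshold 37; 2018 US natality values). The closed form is verified
  against numerical quadrature to 1e-10.
- The logistic path uses ΔP = p0·(RR − 1). The published tabulations never
  state this formula; it is inferred from their arithmetic, with
  p0 = 0.1002 (the 2018 US preterm rate) as an explicit, configurable
  field. Note the published singleton ratio 242,019/3,664,651 ≈ 6.6% does
  *not* reproduce those tabulations; ≈10.0% does, which is why p0 is
  surfaced rather than derived.
- Per-bin risk ratios can be supplied directly (shipped values from pooled
  cohort fits — these are not a log-linear scaling of the per-log10 OR,
  so they evidently come from categorical fits) or generated by log-linear
  scaling RR_b = OR^(x_b − x10).
- Continuous-path slopes ship as 0.15 (DEHP), 0.461 (DiNP), and 0.279
  (DiDP) weeks per log10 unit — the values implied by the published
  decrement tables (the adjusted regression slopes, e.g. −0.253 for DEHP,
  are larger in magnitude; the published burden chain used the smaller
  figures, and both are accepted as config inputs).
- Two published per-case costs circulate ($67,836 from the CPI-adjusted
  2016 estimate; $67,665 in a tabulation footnote); both ship, selectable
  per run. Full-precision recomputation of the continuous DEHP chain gives
  24,039 cases where the source prints 24,003 (0.15%; intermediate
  rounding) — reports always show the full-precision value.
- Everything is computed at full precision; rounding (weeks to 3 decimals,
  percents to 2, cases to integers, dollars to units, billions to 2
  decimals) happens only in report formatting. Burdens are never summed
  across chemicals, and no uncertainty intervals are attached (the method
  propagates point estimates only). DnOP has no burden chain because its
  main metabolite is unmeasured in the survey wave the percentiles come
  from.

## Problem sizes and runtime

Tests run the full generator at 13 × 385 dyads where the pooled-sample
scale matters (calibration, recovery, acceptance) and 6 × 120 elsewhere;
null-coverage checks use 50 seeds at 10 × 200 (linear) and 13 × 385
(logistic). The complete suite runs in under two minutes on one CPU;
`scripts/acceptance.py` in a few seconds.

## Known limitations

- The logistic-path increment formula and baseline rate are inferences
  (see above), prominently configurable rather than hard-coded.
- The synthetic generator's per-metabolite distribution split and the
  birthweight model are conventions; parameter-recovery results show the
  estimators work under the assumed structure, not that the structure
  matches any particular cohort.
- Mixture/joint-exposure models, mediation through gestational diabetes or
  hypertensive disorders, batch-effect correction, and quantile regression
  are out of scope.
- Measured (pipeline-processed) exposure contains specimen noise, so
  slopes refit from it show ordinary regression-dilution attenuation
  relative to the configured truth; recovery tests that target the
  configured value use the generator's latent exposure columns.
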