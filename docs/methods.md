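# Methods

## Scientific setting

The package re-implements, as a tested pipeline, a gene–diet survival
analysis of the kind run on large Chinese prospective cohorts: a weighted
polygenic risk score (PRS) for stroke built from 534 biallelic SNPs, fruit
intake in three categories (<200 g/week, 200 g/week–100 g/day,
>100 g/day), and incident first-ever stroke over roughly a decade of
follow-up across three sub-cohorts. Because the individual-level data of
such studies are not publicly deposited, every stage is validated against a
synthetic cohort generator with known ground truth.

## Synthetic cohort generator

**Genotypes and PRS.** Each SNP is drawn independently under
Hardy–Weinberg equilibrium: the risk-allele count is Binomial(2, p) with p
uniform on (0.05, 0.95) per SNP. Weights are N(0, 0.05). With 534
independent loci the weighted score is approximately normal (checked by
Anderson–Darling), with mean Σ_j 2 p_j w_j. Linkage disequilibrium,
population structure and genotyping error are deliberately out of scope, so
passing tests say nothing about PRS behaviour under LD.

**Covariates.** Marginals are matched to the baseline table of the
motivating cohort: age N(55, 10) truncated to 35–95, 58% female, 49%
northern region, 16% urban, 47% high-school education, 23% current smokers,
23% alcohol drinkers, BMI N(24, 3.5), vegetables N(335, 157) g/day.
Physical-activity minutes and the four diet components (red meat, legumes,
fish, tea) use zero-inflated gamma/lognormal forms tuned so that ~63% reach
the ideal activity level (moderate + 2×vigorous ≥ 150 min/week) and ~53%
reach an ideal diet score (≥2 of 4 components). Blood pressure, fasting
glucose and lipids are drawn so the derived hypertension/diabetes/
dyslipidemia flags have realistic prevalence (~40%/8%/35%). Covariates are
mutually independent given sex; real cohorts correlate them, so adjusted
and unadjusted effects differ less here than in real data.

**Fruit intake.** A two-part model: a point mass of never-consumers
(probability 0.31) plus a lognormal(4.577, 0.670) for consumers. The
parameters were solved once so that the category boundaries 200/7 and
100 g/day each cut off about a third of the population while the mean stays
near 83 g/day (the achieved mean is ~84 g/day with SD ~95); mean and
tertile targets cannot be hit simultaneously by a two-parameter lognormal,
and the tertile placement was prioritized because the category contrasts
carry the analysis.

**Event times.** The stroke hazard is Weibull proportional hazards with
per-sub-cohort baseline cumulative hazard `scale_s · t^shape · exp(η)`,
sampled by inverse transform. The default shape is 1 (constant hazard over
follow-up time); age dependence enters through the age covariate effect
(log-HR 0.06/year) rather than through the shape, which keeps closed-form
oracles available. Sub-cohort scale multipliers (0.80, 1.00, 1.25) make
cohort-stratified and unstratified fits distinguishable. Competing
non-stroke death is exponential (0.010/year) and administrative censoring
uniform on 10–13 years, giving a median follow-up near 11 years; the
follow-up distribution is a modelling choice, not data-derived. The
observed time is the minimum of the three latent times. Event subtypes are
multinomial with probabilities proportional to 1834/439/55/258
(ischemic/hemorrhagic/both/unknown).

**Effect modes.** The true genetic/fruit signal enters the log hazard in
one of three ways: `continuous` (default; 0.147 per SD of the standardized
PRS, chosen so the implied top-vs-bottom-quintile HR is ≈1.5, plus fruit
category effects), `category` (log-HR per genetic risk group and fruit
group, with an optional extra interaction term), or `cells` (an explicit
3×3 grid of cell log-hazards, used for joint-effect and stratum-specific
recovery designs). Group truths are attached to the same quintile/tertile
groupings the analysis re-derives, so category-mode recovery is exact up to
sampling error.

**Calibration.** `calibrate_baseline_scale` bisects the baseline scale (in
log space) until the crude incidence of a 20,000-participant calibration
cohort hits the target (default 7.7 events per 1000 person-years). The
calibration cohort is regenerated with the same seed at every evaluation
(common random numbers), which makes the achieved rate monotone in the
scale and the search deterministic. The shipped default scale
(7.077e-3) is the output of this procedure at seed 20070101.

**Exclusion fixtures.** Disjoint participant sets are flagged as missing
fruit intake, prevalent disease, and missing follow-up (in that order of
precedence), so the preparation stage's cascade and audit can be tested
against exact counts (41,006 − 4856 − 1265 − 14 = 34,871).

## Cohort preparation

The exclusion cascade attributes each participant to the first matching
rule; the audit conserves counts exactly. Derived variables follow the
stated definitions with boundary semantics read literally: fruit "low" is
strictly below 200/7 g/day, "mid" is the closed interval up to 100 g/day,
"high" strictly above; the weekly-to-daily factor is fixed at 7. Diet score
awards one point per ideal component (red meat < 75 g/day strict, the
others ≥ their thresholds); ideal diet is a score ≥ 2. BMI is
weight/height². Clinical flags are OR-of-criteria (measurement thresholds
or medication use).

## Survival engine

The Cox partial likelihood is stratified by sub-cohort, uses Breslow tie
handling (the behaviour of the software family the motivating analysis
used; Efron weights are not offered), and is maximized by Newton–Raphson
with step-halving. Convergence requires max |score| < 1e-8 or a relative
log-likelihood change < 1e-10 within 50 iterations; diverging coefficients
(|β| > 20) raise a separation error. Covariates are centered internally for
conditioning; coefficients and the per-stratum Breslow baseline cumulative
hazard are reported on the original scale (baseline = all covariates at
zero). Risk sets support delayed entry (entry < t ≤ exit) for
age-as-timescale models via sorted suffix sums, so left-truncated fits cost
the same as ordinary ones. The engine agrees with lifelines'
`CoxPHFitter` to ~1e-6 on coefficients and standard errors (tested), and
with a brute-force partial-likelihood grid search to 1e-4 on small
fixtures; at β = 0 its baseline equals the Nelson–Aalen estimator exactly.

Diagnostics: the proportional-hazards test regresses scaled Schoenfeld
residuals on event time (Grambsch–Therneau, average-information
approximation; per-covariate χ²₁ and a global χ²_p). Wald confidence
intervals are used throughout (ordinary, not robust, matching the reported
analyses). Dose-response uses a restricted cubic spline with 3 knots at the
25th/50th/75th percentiles — one linear and one nonlinear coefficient, the
median as the HR reference; `p_nonlinear` is the Wald test of the single
nonlinear coefficient. Trend tests replace each participant's exposure with
the category median, entered as one continuous covariate. Adjusted
incidence rates come from a Poisson log-linear model with a log
person-years offset (statsmodels GLM), predicted at sample-mean age/sex.

## Interaction

The joint analysis fits 8 cell indicators (3 genetic × 3 fruit groups minus
the low-genetic/high-fruit reference) in one full-tier stratified fit.
Multiplicative interaction is the Wald test of the product term between the
extreme fruit and genetic categories, on those four cells' participants.
Additive interaction dichotomizes fruit at 200 g/week and genetic risk as
top vs bottom quintile by default (intermediates dropped; top-vs-rest is a
switch, and the coding used is recorded in the output):
RERI = HR11 − HR10 − HR01 + 1 and AP = RERI/HR11, with delta-method CIs
from the full 3×3 covariance block of the component log-HRs and optional
participant-level bootstrap CIs stratified by sub-cohort. The per-SNP scan
fits per-allele genotype × low-fruit product terms with base-tier
adjustment (full-tier adjustment for 534 separate fits adds cost without
changing the test's null behaviour) and flags Bonferroni significance at
0.05/n_snps.

## Absolute risk and stroke-free years

Standardized cumulative incidence comes from the joint fit in two modes:
`at_means` (incidence at the covariate means and size-weighted average
baseline — what the motivating figure states) and `marginal`
(g-computation over the cohort with cell membership overridden). The
at-means value is not a population average on the nonlinear link, so the
marginal mode is the recommended one; the default stays `at_means` for
fidelity. Horizons beyond the last event time of any stratum are refused
rather than extrapolated. ARRs (low-fruit minus high-fruit incidence per
genetic group) are trend-tested by weighted least squares on group scores
1, 2, 3 with inverse bootstrap-variance weights (equal weights when no
bootstrap is run); the group scores are a choice, as is the bootstrap
weighting.

Stroke-free years refit the full-tier model with chronological age as the
timescale (entry = baseline age; left-truncated risk sets). Standardized
survival from age 35 averages `exp(−(Λ₀s(a) − Λ₀s(35))·e^{η_i})` over the
standardization population (the full cohort for overall contrasts, the
stratum's participants for stratum-specific ones) with fruit membership
overridden; the baseline is carried flat beyond the last observed event
age, never extrapolated upward. Gained years are the trapezoid area between
curves on the age grid from 35 to a default horizon of 85 (configurable;
the upper horizon is a choice). CIs are percentile bootstrap (default 500
replicates; replicates that fail to converge are dropped and counted, >5%
drops is a failure).

## Validation design and problem sizes

Recovery checks simulate cohorts of n = 35,000 whose true effects are the
published point estimates (genetic HRs 1.19/1.51; fruit HRs 0.81/0.69;
joint corner 1.87; stratum-specific fruit HRs 0.72/0.68/0.70), re-estimate
them through the full pipeline over seeds 1–40, and require the geometric
mean of the per-seed HRs to lie within 2 empirical standard errors of the
truth. Forty seeds are used because a 20-seed 2-SE check has ~5%
false-failure probability per quantity under an exactly unbiased estimator
(~23% familywise over five recovered quantities); doubling the panel halves
the Monte-Carlo variance, and log-scale averaging is the natural summary
for ratio parameters. Null calibration of the Schoenfeld, multiplicative-
interaction and spline-nonlinearity tests uses 200 seeds at n = 2,000 with
an acceptance band of [0.015, 0.095] on the rejection rate — the central
~99.8% range of Binomial(200, 0.05), fixed before measurement. The
exponential-oracle check for standardized incidence averages three
n = 20,000 cohorts against a 3σ Monte-Carlo band.

## Known limitations

- No LD, population structure, or genotype missingness; the PRS behaves
  better than a real one.
- Covariates are independent given sex, so confounding is weaker than in
  real data; adjusted-vs-unadjusted contrasts are mild.
- The competing-risk refit (Fine–Gray) is not implemented; competing
  deaths are generated and treated as censoring, matching the main-analysis
  convention.
- The at-means standardization reproduces the stated method but is not a
  population average; use marginal mode for interpretable absolute risks.
- Exact published absolute quantities (cell-specific rates, RERI = 0.13,
  ARRs 1.3/1.8/2.3%, gained years 0.64–2.19) depend on the unpublished
  empirical baseline hazard and covariate joint distribution; the pipeline
  reproduces their orderings and signs, not their magnitudes.
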