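# strokeprs

Polygenic risk, fruit intake and incident stroke: a tested survival-analysis
pipeline with a synthetic cohort generator.

## The problem

Large prospective cohort studies ask whether the benefit of a healthy diet
depends on genetic predisposition: does eating more fruit reduce stroke risk
similarly for people at low and high polygenic risk, and — even when the
*relative* reduction is similar — do high-risk individuals gain more in
*absolute* terms? The individual-level data behind such studies are rarely
public, so this package pairs the full analysis pipeline with a cohort
generator whose ground truth is known, letting every stage be validated by
parameter recovery and closed-form oracles.

The pipeline implements:

- a weighted polygenic risk score, PRS_i = Σ_j g_ij·w_j over 534 SNPs
  (g_ij ∈ {0,1,2} risk-allele counts), with low/intermediate/high groups cut
  at the empirical 20th/80th percentiles;
- the exclusion cascade and derived variables of a three-cohort Chinese
  study design (fruit-intake categories <200 g/week, 200 g/week–100 g/day,
  >100 g/day; 0–4 diet score; ideal physical activity; clinical flags);
- cohort-stratified Cox proportional-hazards models (Breslow ties,
  Newton–Raphson, left truncation for age-as-timescale fits), Schoenfeld
  diagnostics, restricted-cubic-spline dose-response, category-median trend
  tests, and Poisson-adjusted incidence rates;
- joint 3×3 genetic×fruit hazard ratios, multiplicative interaction, and
  additive interaction: RERI = HR11 − HR10 − HR01 + 1, AP = RERI/HR11, with
  delta-method and bootstrap CIs, plus a per-SNP×fruit Bonferroni scan;
- covariate-standardized 10-year cumulative incidence, absolute risk
  reductions, and their weighted-least-squares trend across genetic groups;
- stroke-free years gained from age 35 (restricted-mean differences between
  standardized survival curves on the age timescale, bootstrap CIs).

## Worked example

Simulate the default cohort (41,006 genotyped participants with the
exclusion fixtures), prepare it and fit the main models:

```
python analysis/02_prepare_and_describe.py
python analysis/03_main_hazard_ratios.py
```

prints (abridged):

```
41006 genotyped -> excluded 4856 missing fruit, 1265 prevalent,
14 missing follow-up -> 34871 analytic participants
genetic risk groups: {'intermediate': 20922, 'low': 6975, 'high': 6974}

                            coef     se     hr  ci_lower  ci_upper
fruit_full   fruit_mid    -0.221  0.045  0.802     0.734     0.877
             fruit_high   -0.373  0.047  0.689     0.628     0.755

p trend (fruit): 3.15e-15; spline PRS: p nonlinear 0.619
age/sex-adjusted rates per 1000 PY: low 4.99, intermediate 6.44, high 8.06
proportional-hazards check (GLOBAL): p 0.464
```

Read: after exclusions the analytic cohort is exactly 34,871; the fully
adjusted hazard ratio for fruit intake >100 g/day vs <200 g/week is 0.69
(a 31% lower stroke hazard), the monotone fruit trend is strong, the PRS
effect shows no nonlinearity, and the adjusted incidence rises from 5.0 to
8.1 per 1000 person-years across genetic risk groups with no
proportional-hazards violation. The remaining drivers
(`analysis/04`–`07`) produce the joint grid with RERI/AP, the standardized
10-year risks with the ARR trend, stroke-free years gained per genetic
group, and the sensitivity suite. For instance,
`python analysis/06_stroke_free_years.py` prints

```
overall      gained +2.05 years (95% bootstrap CI 1.62 to 2.49)
low          gained +1.51 years (95% bootstrap CI 0.62 to 2.26)
intermediate gained +2.13 years (95% bootstrap CI 1.71 to 2.65)
high         gained +2.28 years (95% bootstrap CI 1.44 to 3.58)
```

— the stroke-free years gained from age 35 by moving from <200 g/week to
>100 g/day of fruit, increasing with genetic risk even though the relative
hazard reduction is common across strata.

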