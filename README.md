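# gemsnorm

Scoring, demographic norms and reliable-change statistics for a web-based,
self-administered cognitive screening battery.

Brief screening instruments estimate global cognitive functioning from a
handful of short tasks and are used to triage people at risk of mild
cognitive impairment. A self-administered web battery scores itself: every
response is machine-readable, so the entire clinical pipeline — item scoring,
comparison with a healthy normative sample, and the decision whether a
retest score reflects real change — can be implemented as reproducible code.
`gemsnorm` is that pipeline for an 11-task Italian-language battery
(orientation, immediate and delayed word recall, months backwards, puzzle,
spatial representation, picture naming, command comprehension, two
trail-making variants, metaphor comprehension), together with a 6-item
cognitive-reserve short form and a synthetic normative-cohort generator so
that every statistical component is testable offline.

## The statistics at the core

**Equal task weighting.** Each task yields a raw score on its own scale and
is re-weighted to 0–9: `w = raw × 9 / raw_max` (e.g. 3 of 6 recalled words →
3 × 9/6 = 4.5). The global score is the sum of the eleven weighted scores
rescaled to 0–100 (× 100/99), reported to one decimal.

**Regression-based norms (Crawford–Garthwaite).** The global score of a
healthy examinee is modelled by OLS on demographics,

    y = β₀ + β₁·age + β₂·education + β₃·CR + β₄·sex + ε,  ε ~ N(0, σ²).

An individual's observed score y₀ with predictor vector x₀ is referred to a
t distribution using the new-observation standard error,

    t = (y₀ − x₀ᵀβ̂) / (s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀)),   df = n − k − 1,

so the one-tailed p estimates the proportion of the healthy population
expected to score as low or lower given those demographics. Cut-offs invert
the same statistic; nested predictor sets are compared by Gaussian
full-likelihood AIC.

**Significant change.** A retest total is predicted from baseline by OLS;
scores outside the two-tailed new-observation prediction interval are
classified as worsened or improved. Because the intercept absorbs the mean
practice effect, "stable" means "changed no more than a typical healthy
retest". Test–retest reliability (Pearson r) and practice effects (paired t)
are computed for same-version (A→A) and parallel-version (A→B) designs.

**Psychometric validation.** Standardised Cronbach's alpha
(k·r̄ / (1 + (k−1)·r̄)), item–total correlations, maximum-likelihood
exploratory factor analysis with the Bartlett-corrected likelihood-ratio
chi-square (df = ((p−m)² − (p+m))/2) and varimax rotation, and a Table-style
descriptive summary.

**Synthetic cohorts.** The generator reproduces the published study
conditions: 1308 examinees in the exact age × education quota cells, totals
from the published four-predictor regression (age −0.29, education +0.81,
CR +0.05, sex −1.14; residual SD 8.5; mean 81.8), task scores distributed
through a speed/memory factor template, and retest pairs targeting r = 0.88
(A→A, practice gain +2.19) and r = 0.55 (A→B).

## Worked example

```sh
$ gems-norm simulate --n 1308 --seed 7 --out cohort.csv --retest AA
$ gems-norm norms fit cohort.csv --out model.json
n=1308 R2=0.469 residual_sd=8.08 AIC=9186
$ gems-norm compare model.json --age 71 --edu 8 --cr 110 --sex F --score 62
observed 62.0 vs predicted 70.5 (cut-off 57.2): above cut-off, p=0.1457
$ gems-norm change fit cohort_retest.csv --versions AA --out change.json
n=73 slope=0.934 intercept=7.25 residual_sd=5.33
$ gems-norm change classify change.json --baseline 78 --retest 85
retest 85.0 vs predicted 80.1 [69.4, 90.9]: stable
```

Reading the comparison: a 71-year-old with 8 years of education and a
cognitive-reserve index of 110 is predicted 70.5/100; the α = 0.05 cut-off
for those demographics is 57.2, so an observed 62.0 is above the cut-off —
about 14.6% of comparable healthy adults would score 62 or lower. On retest,
85 after a baseline of 78 lies inside the 95% prediction interval
[69.4, 90.9], i.e. within the range expected from measurement error plus
the normal practice gain.

The same operations are available as a library (`score_session`,
`fit_normative_model`, `single_case_test`, `cutoff_score`,
`fit_change_model`, `classify_change`, `standardized_alpha`, `ml_efa`,
`generate_cohort`, ...); `gems-norm score` and `gems-norm validate` score
raw session CSVs and audit cohort tables (schemas in `docs/formats.md`).

## Documentation

`docs/methods.md` describes the models, the synthetic-data assumptions and
their limits; `docs/formats.md` documents the CSV schemas.
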