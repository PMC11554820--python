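# Methods

## Scoring model

Each of the 11 tasks produces a raw score on its own scale; the battery's
design principle is that every task weighs the same on the global score, so
raw scores are mapped to a common 0–9 scale by `w = raw × 9 / raw_max`.
Eleven tasks at 9 points sum to 99 while the global score is conventionally
reported out of 100 with an attainable maximum of 100; we therefore rescale
the sum by 100/99 and round to one decimal (half-up, as clinical scores are
reported). A perfect protocol scores exactly 100.0 and a null protocol 0.0.

Typed-text items are matched lowercase and whitespace-trimmed, exact by
default; an edit-distance-1 leniency exists behind a flag but is off because
a strict rule is auditable. The two word-recall tasks are scored order-free
with one credit per target word: the raw score is the size of a maximum
matching between typed tokens and targets (for exact matching this reduces
to `Σ_t min(#tokens = t, #targets = t)`), so a word typed twice is never
credited twice. The orientation key is derived from the administration date;
seasons follow the astronomical calendar (21 Mar / 21 Jun / 23 Sep / 21 Dec)
and within ±7 days of a boundary either adjacent season is accepted, since
answers near a boundary are genuinely ambiguous.

The trail-making tasks record both accuracy and speed and the published
description fixes no combination rule, so the package defines one:
accuracy is the longest correct prefix of the 14-element target sequence
(a self-administered interface cannot re-cue after an error) divided by 14,
the speed factor falls linearly from 1 at `t_fast` to 0 at `t_slow`
(defaults A: 20/120 s, B: 30/180 s, chosen to bracket unimpaired and
severely slowed completion times), and `raw = accuracy × speed × 14`. The
mapping is deterministic and monotone in both inputs; the time bounds are
configuration.

The cognitive-reserve short form has six ordinal items (0–4), two per domain
(education, working activity, leisure). Each domain subscore is an affine
map `center + step × (i₁ + i₂ − 4)` onto a CRIq-style scale (defaults
center 122, step 11, giving a population mean near the observed 123 and a
plausible spread); the total is the mean of the three subscores. The true
item-to-index tables of the questionnaire are not published item by item, so
this mapping — like the word lists and option keys — is explicit, synthetic
configuration (`ScoringConfig`, YAML-serialisable), not a reconstruction.

## Normative model and single-case inference

Norms are OLS regressions of the global score on age, education,
cognitive-reserve and sex (F = 0, M = 1 by default; the coding is
configuration because the sign of the sex coefficient depends on it).
Missing predictors are dropped listwise — normative fitting must not impute
silently. Model comparison uses the Gaussian full-likelihood AIC,
`n·ln(2π·RSS/n) + n + 2(k+2)`, the convention of mainstream statistical
environments; only differences are meaningful.

A single case is compared with the Crawford–Garthwaite statistic: the
discrepancy between the observed and predicted score divided by the
new-observation standard error `s·√(1 + x₀ᵀ(XᵀX)⁻¹x₀)` is referred to a t
distribution with n − k − 1 df. The term under the square root makes
intervals wider for demographic profiles far from the sample centroid, and
the one-tailed p reads as the expected proportion of the healthy population
scoring as low or lower. The deficit direction (lower = abnormal) is the
clinical default with α = 0.05; two-tailed p is also reported. Cut-offs are
the exact inversion, `x₀ᵀβ̂ + t_α(df)·se_new`, so the score at the cut-off
has p = α by construction. A model with zero residual variance refuses
single-case inference rather than returning p ∈ {0, 1}.

## Change assessment

The retest total is regressed on the baseline total (baseline-only by
default; the published thresholds are keyed to the score alone). The
two-tailed new-observation prediction interval at α = 0.05 defines
worsened / stable / improved. Same-version and parallel-version designs run
through the identical code path; only the version-pair metadata differs.
Task-level thresholds are supported but exploratory. The paired t on
retest − baseline reports `mean(t1) − mean(t0)` so a positive value is an
improvement (practice gain), regardless of the sign convention used in any
particular write-up.

## Psychometrics

Internal consistency is the *standardised* Cronbach's alpha,
`k·r̄/(1 + (k−1)·r̄)` with r̄ the mean of the 55 pairwise correlations —
not the covariance-based raw alpha. Item–total correlations include the item
in the total by default (the corrected variant is behind a flag).

ML factor analysis follows the classical profile-likelihood formulation:
for trial uniquenesses Ψ the discrepancy `F = Σ_{j>m}(θ_j − ln θ_j) − (p−m)`
over the trailing eigenvalues of `Ψ^{-1/2} R Ψ^{-1/2}` is minimised with
L-BFGS-B on log-uniquenesses bounded below at 0.005; a solution on the
bound is a Heywood case and is flagged with a warning instead of being
returned unconstrained. The goodness-of-fit statistic is Bartlett-corrected,
`χ² = (n − 1 − (2p+5)/6 − 2m/3)·F_min` with `df = ((p−m)² − (p+m))/2`,
evaluated on the unrotated solution; rotation (varimax with Kaiser
normalisation by default) changes neither χ² nor the communalities, which
is asserted by the tests. The implementation is cross-checked against R's
`factanal` on simulated data: chi-square, p and uniquenesses agree to
~1e-3.

Descriptives report mean, SD (n−1), median, min, max, bias-corrected excess
kurtosis (G2), bias-corrected sample skewness (G1, "type 2"), and linearly
interpolated (type-7) quartiles — the defaults of the statistical
environment the field typically uses.

## Synthetic cohort generator

The generator encodes the normative study conditions so that every module is
testable without any data download.

- **Demographics.** The 7 age bands × 6 education bands quota table of the
  published n = 1308 sample is reproduced cell-exact (the cell counts were
  recovered from the published row and column totals; the solution is
  unique). Ages are uniform integers within band; education takes the band's
  representative year value (5, 8, 13, 16, 18, 21), since education is
  reported in years but stratified in bands; sex is Bernoulli with 60%
  female. For other n, cells are apportioned deterministically by largest
  remainder, so proportions are preserved to ±1 examinee. Cognitive reserve
  is `99.4 + 1.8·education + N(0, 14)` truncated to [70, 210]: an affine
  link calibrated so the CR marginal matches the observed mean ≈ 123, SD
  ≈ 16 and range 74–208, with a positive education–CR correlation. The
  true joint distribution of CR with age and education is not published;
  this is a documented modelling convenience.
- **Totals.** `total = β₀ + βᵀx + N(0, 8.5)`, with the published
  coefficients (age −0.29, education +0.81, CR +0.05, sex −1.14), residual
  SD 8.5 (total SD 11.4 at R² ≈ 0.44), and β₀ calibrated against the
  sampled demographic means so the cohort mean sits at 81.8. Totals are
  clipped to the instrument's [0, 100] range (configurable) and reported on
  a 0.1 grid. Clipping censors ~5% of the mass at the ceiling and therefore
  attenuates refitted coefficients slightly; estimator-calibration
  experiments should disable it, because censoring is a property of the data
  model, not of the estimator under test.
- **Task scores.** Conditional on the standardised total z, task j is
  `mean_j + r_j·sd_j·z + group + unique noise`, using the published task
  means, SDs and item–total correlations, with a trail-making speed factor
  and an episodic-memory factor carrying 70% of the non-global SD of their
  marker tasks (the working-memory factor has a single marker and folds
  into unique variance). Scores are clipped to [0, 9] and snapped to each
  task's raw grid. Because the total is generated exogenously, the sum of
  task scores equals the stored total only in expectation; the table's
  `total` column is the regression total.
- **Retest pairs.** Baseline profiles are drawn from the cohort; the retest
  total follows a bivariate-normal model,
  `t1 = (μ + shift) + r·(t0 − μ) + N(0, sd·√(1−r²))`, with r = 0.88 and
  shift = +2.19 for same-version retests and r = 0.55, shift 0 for parallel
  versions. Regression to the mean keeps high scorers inside the range
  instead of piling symmetric noise onto the ceiling, which would otherwise
  inflate the realised correlation and distort the practice gain. The total
  change is distributed over tasks proportionally to their share of common
  variance by a water-filling allocation that respects each task's [0, 9]
  box, on top of a per-task practice pattern concentrated on the memory
  tasks; retest task scores stay on a 0.1 grid because snapping back to
  coarse raw grids near the ceiling reflects noise upward.

What the generator does *not* emulate: the skewness/kurtosis of the real
score distributions (Gaussian residuals are used), item-level response
processes (it produces weighted scores, not keystrokes), real CR–age
structure, and dropout/quality-of-administration effects. Tests passing on
synthetic cohorts therefore validate the statistical machinery and its
calibration, not the field behaviour of the instrument.

## Numerical choices and degenerate inputs

Scores are rounded half-up to one decimal where reported; internal
computation is double precision. Zero-variance columns, constant baselines,
zero residual variance and rank-deficient designs raise typed errors naming
the offending columns instead of propagating NaNs. AIC of a numerically
perfect fit returns −∞ with a warning. Paired t with zero-variance nonzero
differences returns an infinite-t sentinel. Monte-Carlo test sizes (200
replicate refits at n = 1308; 10 000 simulated cases for calibration and
change coverage; 40 replicates for EFA goodness-of-fit calibration) were
chosen so that binomial/CLT error is well inside the asserted tolerance
bands while the suite stays quick to run.

## Known limitations

- The production instrument's exact answer keys, version-B items and the
  deployed normative coefficients (intercept, residual SD, design
  cross-products) are not published, so individual production cut-offs
  cannot be reproduced — only the method is.
- The trail-making speed-accuracy combination and the CR item mapping are
  this package's own explicit definitions (configurable), not published
  rules.
- The per-coefficient 2-SE recovery check sits exactly at the nominal
  coverage of a ±2 SE interval (95.4%), so at 200 replicates its pass/fail
  is dominated by binomial noise; the fixed-design calibration test is the
  statistically meaningful check of the estimator.
- Single-case inference assumes Gaussian residuals; with the left-skewed
  distributions typical of near-ceiling screening scores, lower-tail p
  values are approximate.
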