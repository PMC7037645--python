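# Methods

## Scope and model

The package evaluates a binary screen (the KidFit rule: SAMS time ≥ 5.43 s
and/or MSTP-predicted VO₂max ≤ 34.9/45.1 mL·kg⁻¹·min⁻¹ for girls/boys, both
boundaries inclusive) against three dichotomous reference states —
overweight/obesity (BMI-for-age ≥ 85th percentile), lowest motor quartile
(BOT2 percentile rank ≤ 25), and reduced cardiorespiratory fitness (measured
VO₂peak in the very poor/poor/fair band of the Cooper Institute reference).
The screen/state cross-classification yields a 2×2 table per state; the
estimators are the classical screening-validation set (sensitivity,
specificity, predictive values, likelihood ratios, odds ratio, efficiency
rate, Fisher's exact test, ROC/AUC), plus simultaneous-entry linear
regression and pooled t-tests for concurrent validity.

## Statistical choices

* **Proportion SEs** are Wald, √(p(1−p)/m), each on its *own* denominator
  (diseased margin for Se, healthy margin for Sp, screen margins for the
  predictive values). No continuity correction; estimates with a zero
  denominator are returned as undefined rather than raising.
* **Likelihood-ratio CIs** use the log method:
  exp(ln LR ± z·SE) with SE(ln LR⁺) = √(1/TP − 1/(TP+FN) + 1/FP − 1/(FP+TN))
  and the analogous FN/TN form for LR⁻. When FN = 0 the LR⁻ point estimate is
  exactly 0 and its interval is reported undefined (the SE involves 1/FN);
  symmetrically for LR⁺ with TP = 0. LR⁺ with Sp = 1 is undefined.
* **Odds ratio**: Woolf (log) interval. The Haldane–Anscombe correction
  (add 0.5 to *all four* cells) is applied only when at least one cell is
  zero, and the result carries a `corrected` flag. z = Φ⁻¹(0.975), not 1.96
  rounded.
* **Fisher's exact test** is two-sided by the point-probability ("minlike")
  rule — the SPSS/R convention: sum the hypergeometric probabilities of all
  tables with the observed margins whose probability is ≤ the observed
  table's, with a relative tie tolerance of 1e-7. A degenerate margin gives
  p = 1.
* **ROC/AUC**: every distinct score is swept as a threshold; the trapezoidal
  area equals the Mann–Whitney probability estimate with ties counted ½
  (ties are grouped so the curve takes the diagonal shortcut through tie
  blocks). SE by Hanley–McNeil with Q₁ = A/(2−A), Q₂ = 2A²/(1+A); the 95%
  Wald interval is clipped to [0, 1]. Accuracy bands are lower-inclusive:
  random < 0.5 ≤ poor < 0.7 ≤ moderate < 0.9 ≤ high, so an AUC of exactly
  0.9 is "high" and 0.895 is "moderate". The continuous score driving a ROC
  is never guessed: callers (and the CLI) must name the score column and its
  direction; the study-shaped pipeline defaults to SAMS time with
  higher-is-diseased.
* **Regression** is ordinary least squares (statsmodels under the surface)
  with listwise deletion, so each model's n follows the available cases (57
  for field measures; 24 for the laboratory subset in the default cohort).
  Standardized betas are b·sd(x)/sd(y) with sample SDs; the model p-value is
  the overall F test. Sex enters model 2 as a 0/1 indicator with male = 1
  (the opposite coding only flips the beta's sign).
* **t-tests** are pooled-variance (df = n₁+n₂−2, the form consistent with
  the study's reported df = 55 at n = 57), two-sided; a zero pooled variance
  returns an undefined marker rather than ±∞.

## Published-table validation

The original feasibility study prints the 2×2 cell counts for all three
state variables — (6,0,4,15), (9,1,12,35), (7,0,3,14) — which makes its
entire diagnostic table recomputable. `validate_against_table4` recomputes
every cell and compares at one unit in the last printed digit, with an
additional relative tolerance of 5e-4 for interval bounds because the
published bounds were evidently back-computed from 2-dp-rounded ratios
(exp(ln 44.78 + z·SE) reproduces the printed 956.84 exactly; the unrounded
ratio gives 956.79).

Two printed cells are arithmetically inconsistent with their own row and are
reported as `known_discrepancy` rather than pass or fail:

* the adiposity-row PPV SE is printed 0.153, but the Wald SE of PPV = 6/10
  is uniquely √(0.6·0.4/10) = 0.155;
* the adiposity-row Fisher p is printed "<0.001", but the exact two-sided p
  is C(6,6)·C(19,4)/C(25,10) = 0.0011858 — only the observed table itself
  qualifies under the point-probability rule, and the one-sided p is the
  same number, so no Fisher convention can produce a value below 0.001.

One acceptance test asserts the printed "<0.001" faithfully and therefore
fails by design; it documents the publication error instead of papering over
it.

## Synthetic cohort

No raw data accompany the study, so the generator emulates its published
structure: n = 57, age 12.57 ± 1.82 y (clipped to the 5–17 eligibility
window), 34/57 male, SAMS 4.68 ± 1.40 s (floored at 2.0 s), MSTP
21.83 ± 2.93 laps (rounded to the half-lap scoring granularity), VO₂peak
44.12 ± 11.02 mL·kg⁻¹·min⁻¹ and BMI percentile 51.84 ± 33.94 in a
laboratory subset of 24/57 (the usable treadmill subset), BOT2 percentile
61.42 ± 30.46. BOT2 raw-score moments (total 230 ± 35, gross 110 ± 20) are
nominal: they are not reported in the study summary and only their
correlation structure matters downstream.

Correlation is induced by a single standard-normal latent factor F per
child. Gaussian measures load as mean + sd·(s·λ·F + √(1−λ²)·ε) with sign s
chosen so that slower SAMS co-occurs with lower MSTP, lower VO₂peak, lower
motor percentile and higher BMI percentile. The fitness loading (MSTP,
VO₂peak) and motor loading (SAMS, BOT2, BMI) default to 0.92 and 0.78.
These were calibrated once, analytically, against the study's strongest
concurrent-validity result: with loadings (a, b) the population R² of
VO₂peak on (SAMS, MSTP) is c'Σ⁻¹c with c = (a², −ab) and offdiag(Σ) = −ab,
giving 0.741 at the defaults; the replicate-mean sample R² at n = 24 is
≈ 0.74, against the published 0.754.

Percentile-scale measures (BMI, BOT2 rank) do **not** use a clamped normal:
with sd ≈ 34 on a mean of ≈ 52, clamping to [0, 100] would shrink the SD by
more than 4 points and the configured moments could never be recovered.
Instead the standardized latent score passes through a Gaussian copula into
a scaled Beta whose shape parameters are moment-matched to the configured
mean/SD — exact moments, support inside (0, 100), and the strongly
over-dispersed (U-ish) shape real percentile ranks take in a mixed
recruitment cohort (an obese-enriched arm plus an all-comers arm). A
configured percentile SD too large for any distribution on [0, 100] is
rejected at validation time.

Sex is sampled independently of the latent factor (the study found no sex
differences in raw scores); an optional `male_vo2_offset` exists for power
studies. What the generator does *not* emulate: growth/maturation trends
(age is independent of fitness), measurement error models per instrument,
school-vs-lab recruitment clustering, or the published age and motor-rank
sex differences. Passing tests therefore demonstrate correctness of the
estimators and pipeline on data with the study's first- and second-moment
structure — not that the screen itself generalizes.

## The prediction equation

The MSTP→VO₂max equation is cited but not printed in the study, so it is a
required configuration input (`ScreeningRule.vo2_prediction_coefficients`).
The packaged example (intercept −24.617, slope 3.1263 per lap) is
moment-implied: slope = 9.16/2.93 (the ratio of the predicted-VO₂ and MSTP
SDs), anchored so the mean MSTP score of 21.83 predicts the reported mean
43.63. It is illustrative; real screening use should substitute the
published equation.

## Numerical and degenerate-input conventions

* LMS z-scores switch from the power form ((x/M)^L − 1)/(L·S) to the exact
  L→0 limit ln(x/M)/S when |L| < 1e-7: below that the power form collapses
  to 0/0 in double precision. Reference rows are linearly interpolated in
  age-in-months within sex; ages outside the tabulated range use the nearest
  boundary row.
* CRF bands are looked up by inclusive upper edges per sex; contiguity and
  ordering are validated on load. The male fair/good boundary sits exactly
  at the 45.1 cutoff, which keeps the band's "reduced" flag identical to the
  KidFit CRF flag at default cutoffs. One consequence: the study prose calls
  its boys' mean VO₂peak of 45.06 "good", but 45.06 ≤ 45.1 is reduced/fair
  by the tool's own cutoff — the package follows the cutoff.
* All report rounding lives in one formatting layer (CSV reports carry
  rounded strings; `report.json` carries full precision), so printed
  rounding never contaminates downstream computation.
* Determinism: the cohort is a pure function of its config (one
  `default_rng(seed)` with a fixed draw order), and every persisted artifact
  is byte-identical across runs with the same config and seed.

## Problem sizes

Defaults are the study's own sizes (57 children, lab subset 24). The
property checks use n = 1000 for moment recovery, 200 replicate cohorts for
the R² calibration check, and exhaustive enumeration oracles for Fisher and
AUC at N ≤ 60; the whole suite and the reproduction script each run in
seconds on one CPU.

## Known limitations

* Table-level quantities that depend on the unavailable raw data (the exact
  regression table, the published AUCs of 0.895/0.822/0.912, the cohort
  summary) are validated distributionally or as banding examples, not
  reproduced exactly.
* The Cooper-Institute band edges ship as an editable reference fixture for
  13–19-year-old norms applied to a wider age range, mirroring the study's
  own acknowledged limitation; only the 34.9/45.1 reduced cutoffs are
  normative to the KidFit rule.
* Wald intervals are used throughout where the study used them; no exact
  (Clopper–Pearson) proportion CIs, DeLong AUC variance, or paired
  screen-comparison tests.
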