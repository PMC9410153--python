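# Methods

## Scope

`mrcomplexity` implements a complete analysis pipeline for studying
medication regimen complexity (MRC) in critically ill adults: two scoring
engines (MRCI and MRC-ICU), cohort filtering and outcome derivation,
descriptive group comparisons, multivariable logistic association models
with stepwise forward selection and a LASSO confirmation, and logistic
outcome classifiers evaluated by leave-one-out cross-validation (LOOCV).
Because patient-level ICU data cannot be redistributed, the package ships a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes, with every planted parameter recorded so that recovery
can be verified end to end.

## Scoring model

**MRCI** is the weighted sum of three sections over a patient's regimen:

- Section A: dosage-form weights, summed over distinct (drug, form) pairs;
- Section B: dosing-frequency weights, one per drug — when a drug carries
  several schedules inside a window the highest-weight schedule counts
  (configurable to `per_schedule`);
- Section C: additional-direction weights over distinct (drug, direction)
  pairs.

Scheduled and as-needed (PRN) medications both contribute.  **MRC-ICU**
sums a fixed item weight per distinct (drug, item) pair; agents not on the
item list contribute nothing.  Two published anchor weights (vancomycin 3
points, continuous IV saline 1 point) are enforced as invariants of any
MRC-ICU weight table.  Weight tables are data, not code: TSV files with a
`# version:` header, one `item_key/weight/notes` row per item.  The shipped
defaults reproduce the two anchors and populate the remaining items with
editable defaults spanning the instruments' categories; a site running the
pipeline on real data should substitute its licensed tables.  All scoring
arithmetic is table-independent and verified against a brute-force
summation oracle.

**Windows.** Scores are evaluated at 24 h and 48 h after ICU admission.
Windows are cumulative by default (`[0, w)` hours from admission, order
intervals intersected with the window; open orders active until window
close; pre-admission starts retained only while still active at
admission), making the 24 h and 48 h covariates nested and monotone.  A
`daily` mode scoring only `[w-24, w)` is available because the source
instruments are sometimes applied day-by-day; the cumulative default was
chosen so that the 48 h score can never decrease, which is testable and
matches the interpretation of "complexity accumulated so far".

**Dichotomization.** High-complexity labels use strict cutoffs
(MRCI > 63, MRC-ICU > 6), the cohort medians of the 24 h scores; a
`median` mode recomputes the cutoffs from the data at hand.

## Cohort rules and outcomes

Inclusion: age ≥ 18, ICU stay strictly > 24 h, stay ≤ 40 days, all
required admission labs present (default BUN, creatinine, sodium,
potassium — the rule is configurable because "missing laboratory values"
does not pin down a lab list).  The filter is total, idempotent, and emits
an audit report that partitions the input exactly.

Outcomes per included patient: ICU mortality; prolonged stay
(`los_hours >= 48` — the printed rule assigns < 48 to 0 and > 48 to 1 and
is silent at exactly 48, so the boundary is closed upward to keep the map
total); and mechanical ventilation over the first 48 h (`within48h`:
any ventilated time; `at48h`: still ventilated at hour 48).  Hemodynamic
instability is the disjunction SBP < 100 mmHg, MAP < 65 mmHg, heart rate
< 60 or > 100 bpm, or a documented arrhythmia; arrhythmia is code-based
(configurable ICD-10 set) because waveform data are absent from tabular
extracts.

## Descriptive statistics

Continuous variables: median (IQR) summaries; Student's t test by default,
Wilcoxon rank-sum for the regimen-complexity scores.  (The rank-sum test
is used for unpaired group contrasts; the signed-rank variant exists for
paired data only, where it is defined.)  Categorical variables: count
(percent); chi-squared without continuity correction (equal to the closed
form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) on 2×2 tables, with a config switch
for the Yates correction), falling back to Fisher's exact test when any
expected cell is below 5.  Zero-variance contrasts are reported as
undefined rather than tested.

## Association models

Four candidate sets per binary outcome: Model I (demographics, APACHE II,
SAPS II, CCI, 15 medication-class indicators), Model II (demographics,
MRCI 24 h/48 h, CCI, classes), Model III (demographics, MRC-ICU 24 h/48 h,
CCI, classes), Model IV (the union).  For the prolonged-stay outcome the
48 h scores are excluded — the outcome is defined at the same threshold.
Demographics are age, sex, height, weight, BMI and race indicators against
a composite non-White/non-Hispanic reference (reference levels are a
package choice; they are config, not science).

Stepwise forward selection adds, at each step, the candidate with the
smallest add-one Wald p-value while that p < 0.05, with exact ties broken
lexicographically; candidates whose trial fit does not converge (e.g.
separation) are simply not addable at that step.  The final model is
refitted jointly; ORs use Wald 95% CIs.  Fits run on internally
standardised predictors — the logistic MLE is equivariant under affine
predictor maps, so Wald statistics are unchanged while convergence is far
more reliable — and coefficients are mapped back to the original scale.
Complete-case analysis throughout (no imputation).

LASSO confirmation: predictors standardised, penalty chosen on a
log-spaced grid by 10-fold cross-validated deviance (minimum rule;
one-standard-error rule available), nonzero set reported for comparison
with the stepwise selection.  Because the L1 solution with strongly
correlated predictors at the CV-chosen (mild) penalty may retain both, the
collinearity property — at most one of two collinear copies survives — is
asserted at the strong end of the penalty path, where it holds.

## Prediction models

Seven logistic classifiers per outcome, fixed variable sets, no selection;
demographics in every set; SAPS II (not APACHE II) in the combined models
because the two severity scores are nearly collinear — a Pearson screen
(default |r| > 0.7) reports such pairs rather than dropping anything
silently.  The admission set is demographics + SAPS II + CCI + GCS (its
exact composition is config).

Evaluation: deterministic LOOCV produces one out-of-fold probability per
patient; the point AUC is the Mann–Whitney rank statistic; the AUC median
and 95% CI come from bootstrap resampling of the (probability, outcome)
pairs (default 10,000 draws, single-class resamples redrawn; seeded and
bit-reproducible).  LOOCV itself is deterministic, so repeated-resampling
language applies to the bootstrap, not the folds.  Sensitivity and
specificity default to the Youden-optimal threshold on the out-of-fold
probabilities (a fixed 0.5 rule is available).  AIC is deviance + 2k of
the full-data fit.  Variable importance is |coefficient| × predictor SD
(the log-odds effect of a one-SD move), descending, exact ties broken
alphabetically; a permutation-importance alternative exists.

**A note on null LOOCV AUC.** Pooled leave-one-out probabilities are
mildly pessimistic under the null: deleting a case shifts the training
base rate and the fit away from that case's class, so with pure-noise
predictors the AUC distribution centres slightly below 0.5 (measured mean
≈ 0.46 at n = 200 with three noise predictors, within the ±0.05 band a
chance-level statistic warrants).  This is a property of pooled LOOCV
probabilities, not a defect of the AUC statistic; it shrinks with n and
is negligible next to genuine signal.

## Synthetic cohort generator

The generator's defaults are the study conditions: 317 adult ICU patients;
marginal outcome rates 23% mortality, 51% prolonged stay, 31% ventilation;
right-skewed score distributions with 24 h medians near 63 (MRCI) and 6
(MRC-ICU); demographic mix 55.2% male, 65% White, 11.7% Hispanic;
medication mix led by IV fluids, GI agents, analgesics, electrolytes and
anti-infectives.

Each patient draws a latent severity factor z ~ N(0,1) that drives
severity scores, vitals, acuity-linked diagnoses and medication volume.
Medication orders are sampled from a built-in catalog of ~50 representative
agents across the 15 classes (forms, schedules and MRC-ICU item keys are
real item keys of the shipped weight tables), with class probabilities
proportional to configured prescription shares.  The day-1 order volume
(`meds_day1 = 15.5` mean draws at z = 0) and the charting rate of MRC-ICU
item keys (`mrc_item_rate = 0.8`) were calibrated once, by simulation
against the score-median targets, and are fixed defaults — the engine then
scores the generated orders, so the scoring and modelling stages are
exercised jointly.  Class shares are interpreted as relative prescription
shares (normalised before sampling) rather than per-patient exposure
probabilities: the published top-five percentages sum to well over 1
across 15 classes and, read as exposures, would cap regimens at ~3 drugs,
contradicting both ICU practice and the median-63 MRCI target.  The
ordering of the top five classes is preserved.

Outcomes are Bernoulli draws from a logistic model in the engine-computed
24 h MRC-ICU score with planted per-point odds ratios (defaults 1.12
mortality, 1.17 prolonged stay, 1.21 ventilation) and intercepts solved
numerically (Brent root-finding) so the marginal rates hit their targets;
an unreachable rate raises a calibration error with the achievable range.
Outcomes correlate with each other and with severity only through the
shared score, so the planted ORs are the true conditional effects a
correctly specified model should recover — a direct latent-to-outcome path
would confound them.  LOS is drawn consistently with the prolonged-stay
flag inside (24 h, 40 d), ventilated hours consistently with the MV flag,
and non-survivors receive a planted ~1.5× BUN shift mirroring the
survivor/non-survivor renal contrast.  A `direct_scores` mode draws
lognormal score-like covariates without the regimen machinery for
statistics-only simulations (type-I error, parameter recovery), where
generating full regimens would only add runtime.

What the generator does *not* emulate: informative missingness, measured
confounding between severity and outcome conditional on the score,
ICD-code co-occurrence structure, order times truncated at discharge, and
the strong severity-driven discrimination of real cohorts.  Consequently
LOOCV AUCs on synthetic cohorts (~0.5–0.7) are deliberately modest — they
reflect only the planted conditional score effects — and passing tests
certify the machinery (scoring, selection, calibration, reproducibility),
not clinical performance on real data.

## Problem sizes and numerical choices

Default validation sizes: parameter recovery uses 200 replicates of
n = 1,000 (bias tolerance 0.02 on the log-OR; Wald coverage band
0.90–0.99); null selection uses 1,000 replicates at n = 317; null LOOCV
uses 200 replicates at n = 200; oracle equivalence uses 1,000 random
regimens, 100 AUC draws (n ≤ 50), 150 Fisher tables (N ≤ 40) and 500
chi-squared tables.  Logistic fits: statsmodels Newton MLE (association),
scikit-learn `newton-cholesky` with C = 10¹² (prediction; effectively
unpenalized), ridge (C = 1) only as a flagged per-fold fallback.  Bootstrap
CIs and every simulation are driven by seeded `numpy` generators; a fixed
seed reproduces scores, fits and CIs bit-for-bit.

## Known limitations

- Shipped weight tables are editable defaults anchored at two published
  weights, not the licensed instruments; absolute score levels depend on
  the table contents, though every engine property is table-independent.
- Stepwise p-values are not corrected for selection; they are reported as
  the field conventionally reports them.
- The MV flag reduces to ventilated-hours information; without ventilation
  episode timestamps the `within48h`/`at48h` distinction is approximate.
- LOOCV AUC inherits the mild pooled-probability pessimism described
  above.
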