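# Methods

This note documents the statistical procedures implemented in
`plasmapanel`, the assumptions behind them, and the choices made where the
design was genuinely open.

## Cohort model and clinical questions

A cohort is one row per subject: id, age, sex, diagnostic group (SCD, MCI,
AD dementia, FTD, DLB, or `control_other`), adjudicated amyloid status, and
the plasma panel (P-tau181, GFAP, NfL, optionally age-corrected NfL and the
Abeta42/40 ratio; concentrations in pg/mL, the ratio unitless). Two clinical
invariants are enforced at load: AD-dementia subjects must be
amyloid-positive (the diagnosis is biological), and concentrations must be
positive. Subjects with missing markers are retained and counted in a load
report; they are dropped per-question as complete cases, never at load.

The six questions are fixed contrasts: Q1 amyloid-positive vs -negative in
the whole cohort; Q2 the same in SCD+MCI; Q3 AD vs FTD; Q4 controls
(amyloid-negative SCD) vs FTD; Q5 AD vs DLB; Q6 controls vs DLB. Subjects
with unknown amyloid are excluded from the amyloid-dependent questions
(Q1, Q2, Q4, Q6) at subsetting. The positive class is the amyloid-positive
set for Q1/Q2, AD for Q3/Q5, and the dementia group (FTD/DLB) for Q4/Q6;
the orientation is recorded in every serialized model.

## Harmonization

**Kit-lot alignment.** Re-measuring a subsample of one cohort with another
cohort's kit lot gives paired values related by an approximately affine
map. We fit classical Passing–Bablok regression (part I, the
positive-correlation variant, appropriate because re-measurements of the
same samples are strongly positively correlated): the slope is the shifted
median of all pairwise slopes S_ij = (y_j − y_i)/(x_j − x_i), i < j,
excluding undefined pairs and slopes exactly −1, with shift K = #{S < −1};
the intercept is median(y − slope·x); 95% CIs use the rank-based normal
approximation. Even slope counts average the two central order statistics.
Because Youden thresholds are rank-based, thresholds transform by the same
affine map as the data (alignment and threshold recomputation commute);
this is property-tested.

**NfL age correction.** NfL rises strongly with age even within disease
groups. The correction is configurable: `identity` (default — the published
reference-curve coefficients are not bundled and must not be invented) or
`log_linear_reference`, which returns the observed-to-age-expected ratio
nfl / exp(b0 + b1·age) given user-supplied coefficients. The spec of the
correction travels inside each serialized model so patient classification
applies it consistently.

**Amyloid adjudication.** The reference standard is adjudicated from an
ordered evidence list. PET visual reads take precedence over centiloid
quantification (> 30 positive), which takes precedence over CSF assays,
then chart records. CSF cutoffs implemented: Innotest
P-tau181/Abeta42 > 0.06; Elecsys ratio > 0.02; Innotest Abeta42 < 880.5
pg/mL (fallback when P-tau181 is unavailable); Lumipulse Abeta42/40 < 0.069
or Abeta42 < 725 pg/mL; Lumipulse (SPIN) ratio < 0.062. Conflicting
same-precedence evidence resolves to the first-listed item with a warning;
empty evidence yields `unknown`.

## Marker selection

Alpha is tuned once per question: linear LASSO of the 0/1 outcome on
z-scored candidate markers, 10-fold CV (seeded fold assignment), grid of 60
log-spaced values on [1e−4, 1], choosing the minimum mean squared error.
The linear (not logistic) LASSO is used deliberately: MSE is the linear
model's CV criterion, matching the published tuning procedure. Selection
frequencies then come from bootstrap resampling: each resample (same n,
with replacement) is z-scored internally, the LASSO refit at the fixed
alpha, and a marker counts as selected when |coef| > 1e−8. Single-class
resamples are redrawn and counted, keeping the denominator at the nominal
iteration count. The panel rule is strict: a marker enters the shared panel
iff its frequency is exactly 1.0 for at least one question.

A caveat worth knowing: with the generator's uniform positive inter-marker
correlation, a marker with *no* marginal outcome association can acquire a
non-zero partial coefficient (classical suppression) and hence a high
selection frequency at small alpha. The null-marker selection frequency
falls monotonically with alpha (property-tested); at the upper end of the
realistic penalty range (~0.1) null markers are excluded essentially
always.

## Question models and likelihood zones

The per-question model is maximum-likelihood logistic regression of the
outcome on raw marker values — raw units so the serialized coefficients can
be filled out directly with a patient's pg/mL results. Perfect separation
is detected (per-marker range check plus convergence check) and raised as
an explicit error naming the separating marker.

Discrimination is reported as ROC-AUC with stratified 10-fold
cross-validation: the panel model is refit on each training fold and the
pooled out-of-fold probabilities are scored once; single markers use their
raw values as scores (AUC is invariant to monotone transforms, so per-fold
refitting is unnecessary). The 95% CI is DeLong's on the pooled scores.

Thresholds are computed *without* cross-validation on the full development
data. Candidate cutoffs are midpoints between adjacent distinct observed
values plus the boundaries (±∞ for markers, 0 and 1 for probabilities).
The Youden cutoff maximizes J = sensitivity + specificity − 1, ties broken
toward higher specificity and then smaller |cutoff|. The two zone bounds
are sens90 (largest cutoff with sensitivity ≥ 0.90) and spec90 (smallest
cutoff with specificity ≥ 0.90), with a positive call defined as
probability ≥ cutoff. Zones: **low** ≤ sens90, **high** ≥ spec90 (boundary
inclusive on the high side), **indeterminate** between. This is the
standard rule-out/rule-in construction; a `literal` zone convention switch
restores the alternative pairing (low below spec90, high above sens90).
When a model separates better than 90/90, sens90 > spec90 and the zones
would invert; the model then carries `inverted_zones=True` and
interpretation degrades to the Youden cutoff alone.

## External validation

Given a frozen development model and a validation cohort subset:

- **Case-mix (membership) model**: logistic regression of cohort membership
  on the panel markers plus, by default, the question outcome; pooled
  out-of-fold AUC over stratified 10-fold CV. Near 0.5 ⇒ similar case mix
  (reproducibility setting); high ⇒ different (transportability setting).
  No hard cutoff is applied. This model is fit with a near-unpenalized
  ridge-stabilized solver because genuinely disjoint cohorts separate
  perfectly and must yield AUC ≈ 1, not an error.
- **Discrimination**: AUC (DeLong CI) of the frozen model's probabilities;
  accuracy/sensitivity/specificity and the confusion matrix
  ([[TP, FN], [FP, TN]]) at the development Youden probability cutoff
  (recorded in the report; the choice of transported cutoff is a
  documented convention).
- **Calibration**: with LP the frozen linear predictor,
  calibration-in-the-large is the intercept of outcome ~ offset(LP)
  (perfect value 0) and the calibration slope the LP coefficient of
  outcome ~ LP (perfect value 1), both by binomial GLM. The calibration
  plot uses equal-count deciles (reduced with a warning below 5 subjects
  per bin) and a lowess smooth (span 0.75, 100-point grid).
- **Threshold recalculation**: per-marker Youden and probability cutoffs
  recomputed on the validation subset, reported next to the development
  values with relative differences.

## Interpretation graphics

Subjects are flagged normal/abnormal per marker by the Youden cutoffs
(abnormal above the cutoff, or below it for the Abeta42/40 ratio). The
UpSet summary tallies all 2^k flag patterns — empty patterns kept with
count 0 — ordered by descending count, ties by the pattern's binary value;
rendering is matrix-dot columns under bars stacked by outcome class, with
an optional highlight box around the patient's column. Density plots use a
Gaussian kernel with Silverman bandwidth and boundary reflection at 0 and
1 (probabilities live on [0, 1]); classes with fewer than 5 points fall
back to a rug with a warning. Threshold lines are drawn vertically on the
probability axis (an orientation choice). The patient report combines the
value-vs-threshold table, the highlighted UpSet, the density plot with the
patient's probability line, and the zone statement; the clinical question
is chosen by the caller. Figures are written as SVG plus 300-dpi PNG.

## Synthetic cohort generator

The generator emulates a memory-clinic development cohort of 1199 subjects
in seven strata (SCD and MCI split by amyloid status, AD dementia, FTD,
DLB) with the published group sizes, per-group marker means and SDs, age
moments, and female fractions (bundled in `data/table1_defaults.yaml`).
Markers are drawn from a Gaussian copula (default uniform pairwise
correlation 0.3 — a declared assumption, configurable) with lognormal
marginals matched to the natural-scale moments by the method of moments
(σ² = ln(1 + sd²/mean²), μ = ln mean − σ²/2). Lognormal rather than normal
marginals because several published SDs approach the mean (NfL in FTD:
38.3 ± 38), which would otherwise generate negative concentrations.
Amyloid status is fixed in the stratified groups, certain (1.0) for AD
dementia, and Bernoulli mixtures for FTD (0.17) and DLB (0.49) matching the
reported co-pathology prevalences. Ages are truncated-normal on [18, 100].

What the generator does **not** emulate: age–marker coupling (off by
default; a log-linear NfL age slope can be enabled to exercise the
correction), amyloid-stratified marker shifts within FTD/DLB (markers are
drawn from the pooled group distribution; an optional co-pathology shift
parameter, default 0, sharpens the structure for tests), the true
inter-marker correlation matrix, and assay-level measurement error or
missingness patterns. A green end-to-end test therefore establishes that
the *procedures* behave correctly in a world with the published marginal
structure — not that the resulting coefficients or thresholds equal the
clinical ones, which depend on unpublished joint structure. An optional
per-marker affine site shift emulates a different kit lot and closes the
loop with the Passing–Bablok module: the configured (slope, intercept) is
recovered within its 95% CI from ~35 paired re-measurements.

## Numerical conventions and degenerate inputs

- "Selected" in LASSO means |coefficient| > 1e−8 after within-resample
  standardization; constant columns are zeroed rather than divided by 0.
- Constant score vectors raise an explicit error in threshold search;
  constant predictions collapse the calibration plot to a single bin with
  a warning.
- All stochastic procedures (fold assignment, bootstrap, generator) are
  driven by explicit integer seeds; identical seed + config reproduces
  results bit-for-bit.
- Aligned concentrations that become non-positive are flagged per value.
- Youden tie-breaks: higher specificity first, then smaller |cutoff|.

## Known limitations

- The published NfL age-correction coefficients and CSF assay
  transformation formulas are not bundled; hooks exist but default to
  identity / unsupported.
- Selection frequencies near the strict 100% rule are sensitive to the
  penalty and to the synthetic correlation structure; the panel rule is
  exact by design and small simulations can legitimately fail to reproduce
  a 100% row.
- P-tau217, covariate-augmented models (APOE, sex, MMSE), elastic net and
  other selection methods, longitudinal visits, and interactive interfaces
  are out of scope.
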