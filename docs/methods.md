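# Methods

## Risk model

Both scoring variants are logistic models on the log marker levels:

    PI    = A + w_HE4 · ln(HE4 [pmol/l]) + w_CA125 · ln(CA125 [U/ml])
    risk% = 100 · exp(PI) / (1 + exp(PI))

The age-stratified variant assigns each patient to one of eight age
intervals and uses that stratum's coefficient triple:

| stratum | ages | A | w_HE4 | w_CA125 |
|---|---|---|---|---|
| W1 | ≤ 20 | −12.00 | 2.38 | 0.063 |
| W2 | 21–30 | −11.44 | 2.19 | 0.158 |
| W3 | 31–40 | −10.88 | 2.00 | 0.254 |
| W4 | 41–50 | −10.32 | 1.81 | 0.349 |
| W5 | 51–60 | −9.77 | 1.61 | 0.445 |
| W6 | 61–70 | −9.21 | 1.42 | 0.541 |
| W7 | 71–80 | −8.65 | 1.23 | 0.636 |
| W8 | ≥ 81 | −8.09 | 1.04 | 0.732 |

The triples are stored as published constants and never recomputed at
scoring time: the linear stepping from the W1 to the W8 triple in seven
equal increments reproduces them only up to their printed precision (the
table mixes rounding and truncation — e.g. the linear W2 CA125 weight is
0.15857, printed 0.158), so `interpolate_coefficients` is exposed as a
generator/verifier, not as the runtime source. The standard comparator uses
the W1 triple for premenopausal and the W8 triple for postmenopausal
patients, which makes the two variants provably identical at the age
extremes.

### Design choices in the model

- **Logistic form.** The risk transform is the standard logistic
  exp(PI)/(1+exp(PI)); the superficially similar form with a minus sign in
  the denominator is negative and unbounded for PI > 0 and cannot produce a
  0–100 % risk scale, so it is rejected as a typographical variant. The
  transform is evaluated in the overflow-safe branch form and clamped to
  the nearest float inside (0, 100), so any finite PI (|PI| ≥ 700
  included) yields a usable in-range risk.
- **Age boundaries.** Published interval labels leave ages 20 and 81
  ambiguous; here W1 covers ≤ 20 and W8 covers ≥ 81, interior strata are
  closed integer decades, and fractional ages floor to whole years before
  lookup. This leaves no gaps on (0, ∞) and every positive age maps to
  exactly one stratum.
- **Cutoffs.** Defaults are 23.5 % for the age-stratified score on the
  whole population and 14.1 % / 25 % pre/post for the comparator. A score
  exactly at the cutoff is called high-risk (screening favours sensitivity
  at the boundary); the convention is a keyword argument.
- **Assay floors.** HE4 below 15 pmol/l or CA125 below 1 U/ml (the
  quantification limits of the Elecsys/ARCHITECT assays the coefficients
  presuppose) are accepted as given but flagged with a warning — benign
  cohorts do contain such values, and clamping would bias risks upward.
- **ln is the natural logarithm** throughout.

## Diagnostic evaluation

ROC curves are empirical: thresholds sweep the distinct observed scores,
higher scores indicating malignancy, with tied scores grouped at one
threshold. The trapezoidal AUC then equals the Mann–Whitney two-sample
U-statistic with ties counted ½ — the estimator whose variance DeLong's
placement-value theory describes. `delong_variance` computes the
structural-component variance from midrank placement values; the 95 % CI
is Wald on the AUC scale truncated to [0, 1] (a logit-scale option is
provided, as implementations differ and published intervals rarely say
which they used). `delong_compare` is the paired z-test using the
covariance of placement values across markers scored on the same subjects;
when two score vectors are identical the difference variance is zero and
the test reports z = 0, p = 1 by convention.

Cutoff selection maximizes Youden's J = sensitivity + specificity − 1 over
midpoints between adjacent distinct scores (plus sentinels beyond the
extremes), breaking ties toward the higher cutoff, i.e. toward higher
specificity. For perfectly separated classes this returns the midpoint of
the separating gap. Youden's J is the conventional ROC-derived operating
point; the published description of how the original cutoffs were derived
names only "the ROC curve and the DeLong method", so this choice is ours
and is documented here.

Confusion-matrix metrics (sensitivity, specificity, PPV, NPV, as
percentages) report an undefined metric — one whose denominator is an
empty class — as NaN with a warning, never as 0.

The Mann–Whitney test (used for group contrasts of marker levels and risk
values) uses exact enumeration for tie-free pooled samples of at most 20
and otherwise the normal approximation with midranks, tie-corrected
variance and continuity correction; p-values are two-sided by default.
Group contrasts of the two algorithms' risk values are performed unpaired,
matching the named test, although the scores are computed on the same
patients; a paired signed-rank test would be a defensible alternative.

## Synthetic cohorts

The generator emulates the structure of a 413-patient ovarian-tumor
case-control series — 162 malignant, 251 benign — so the pipeline can be
tested end-to-end without patient data:

- **Age.** Each record draws a stratum from per-class frequencies (benign
  mass concentrated in W1–W4, malignant in W4–W7; the malignant W1 cell is
  empty), then an integer age uniformly within the stratum (W1 sampled on
  16–20, W8 on 81–90). Menopausal status is deterministic: post iff age ≥
  51, the usual median age at natural menopause.
- **Markers.** HE4 and CA125 are log-normal per (class, stratum) cell.
  Medians come from the emulated series (e.g. benign CA125 16→9.5 U/ml
  falling with age, malignant CA125 medians in the hundreds, malignant HE4
  rising past 400 pmol/l in older strata). Dispersion matches each cell's
  printed min–max span to the central ~99 % mass of the log-normal,
  σ = ln(max/min)/(2·2.576). Benign HE4 medians follow the drift model
  41.5 · (1 + 0.4·(s−1)/5) pmol/l — about +40 % by the seventh decade
  relative to the youngest stratum, continuing mildly beyond — because the
  raw per-stratum medians of a finite series are non-monotone while the
  age trend itself is the phenomenon the age-stratified score exists for.
  Within-class HE4–CA125 log-correlation defaults to 0 (the true joint
  structure is unreported); a correlation knob exists.
- The benign W8 cell (one expected subject) has no published marker row;
  its CA125 parameters are extrapolated from the adjacent strata.

What passing tests on these cohorts show: the pipeline discriminates when
the generative classes differ as specified, the estimators are calibrated,
and the plumbing is correct. What they do not show: performance on real
patients — the synthetic data have exactly log-normal cells, no
marker-marker correlation, no assay censoring, and a deterministic
menopause-age mapping, none of which hold exactly in practice. Published
cohort-level AUCs and operating characteristics are therefore plausibility
ranges here, not reproduction targets.

## Problem sizes and numerics

The default evaluation runs at the emulated study size (n = 413).
Calibration checks in the test suite use 1000 replicates for the DeLong
type-I-error and CI-coverage simulations (n = 50 or 100 per class) and
2000 replicates for Mann–Whitney null calibration (n = 30 + 30); these
sizes give Monte-Carlo standard errors comfortably inside the asserted
bands. AUC equality with the exhaustive pair-count oracle is exact
(tolerance 1e−12) for n ≤ 30. The DeLong implementation is additionally
pinned against reference values computed independently with R's pROC on a
frozen 15 + 15 synthetic dataset, agreeing to 1e−8.

## Known limitations

- The coefficient table is specific to HE4 in pmol/l (Roche Elecsys scale)
  and CA125 in U/ml; no cross-platform recalibration is attempted.
- No partial AUC, covariate-adjusted ROC, bootstrap CIs, or
  multiple-testing correction.
- The binary high/low stratification is the only decision output; the
  package is not clinical decision support.
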