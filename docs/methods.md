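# Methods

This note documents the models implemented in `ogttmet`, the choices
made where a design was genuinely open, and what the synthetic cohort
does and does not emulate.

## Study design assumed

A two-phase (pre/post intervention) feeding-controlled cohort: 15
subjects enrolled, 12 completing the post-intervention test week, OGTT
blood draws at 0, 30, 60, 90 and 120 min with pre-intervention OGTT
series available for 13 subjects (completers nested within OGTT
subjects, OGTT subjects within enrolled).  Metabolite data are GC-TOF
peak heights of ~321 reported metabolites in long form; phenotype data
are per-draw glucose (mg/dL) and insulin (µU/mL).

## Preprocessing

* **Reporting filter.** A "sample" is one (subject, phase, time)
  injection.  A metabolite is retained if non-missing in ≥ 50 % of
  samples (inclusive).  Missingness is encoded as an empty field, never
  0: zero is a legal peak height and the filter needs true missingness.
* **Sum normalization.** Each intensity is divided by its sample's total
  reported intensity; missing values stay missing and do not enter the
  sum.  Normalization precedes transform selection — the order is a
  documented assumption, not forced by anything upstream.
* **Transform to normality.** Candidates are identity, log, √, ∛, x²,
  and Box–Cox with λ ∈ {−2, −1, −½, ½, 1, 2}; the winner minimizes the
  Anderson–Darling A² (composite normality, n−1 SD, small-sample
  multiplier 1 + 4/n − 25/n² applied to the statistic so it compares to
  the published 5 % critical value 0.752).  Candidates requiring
  positive support are marked infeasible on nonpositive data — no silent
  offsets, because offsets change inference invisibly.  Ties break
  toward the simpler family in the fixed order listed above.
* **Autoscaling.** Mean 0 / SD 1 per feature with the n−1 convention
  (consistent with the t statistics downstream).  Held-out samples are
  always projected with training centers and scales.

## Clinical indices

QUICKI uses base-10 logarithms — that convention is what makes the
screening cutoff 0.315 emerge from glucose 100 mg/dL and insulin
15 µU/mL.  HOMA-IR uses the mg/dL divisor 405.  The Matsuda index uses
the unweighted mean of glucose and insulin over the five scheduled
timepoints; with equal spacing this differs from the trapezoid mean only
in endpoint weights, and the unweighted version is the simplest to pin
down exactly.

## Incremental AUC

The excursion statistic is the trapezoidal integral of
(value(t) − value(0)) over the observed span.  It is *incremental*
(baseline-subtracted), not total: suppressed metabolites legitimately
produce negative areas, which a total AUC of non-negative intensities
cannot.  Interior missing timepoints are bridged linearly between their
flanking observations; a missing terminal timepoint restricts
integration to the observed span (no extrapolation), and the observed
span is recorded.  A usable series needs the fasting baseline and at
least three observed points.  The one-sample test against zero is
two-sided at α = 0.05, equivalent to the 95 % confidence interval
excluding zero; the four-way responsiveness class (both / pre-only /
post-only / neither) is determined solely by the two phase-level flags.

## Mixed model

Per metabolite and endpoint (fasting value or AUC):

y_ij = μ + β·phase_ij + b_i + ε_ij,  b_i ~ N(0, σ_b²), ε_ij ~ N(0, σ_e²)

fit by REML, profiling the single variance ratio ψ = σ_b²/σ_e² with
one-dimensional bounded optimization; for fixed ψ the per-subject
covariance I + ψJ inverts in closed form (Sherman–Morrison), so each
evaluation is O(N).  A ψ̂ at the zero boundary is allowed and reported.
Inference on β uses a Wald t with residual/containment degrees of
freedom N − n_subjects − 1 — closed-form and conservative for this
design (a deliberate departure from software defaults that use
Satterthwaite-type approximations).  On balanced complete pairs this
model reproduces the paired t-test exactly, which the suite checks, and
the paired t over completers is also reported separately.  Fold changes
are post/pre ratios of raw-scale (normalized, untransformed) group
means; the model is fit on the transformed scale.  Multiplicity is
handled with Benjamini–Hochberg step-up q-values at q = 0.05; raw-p and
q-based significance are reported side by side.

## PLS-DA

PLS1 NIPALS with y coded {0, 1} and centered; scores are mutually
orthogonal, weight vectors unit-norm, and the regression vector is
reconstructed as B = W(PᵀW)⁻¹q.  The component count maximizes
leave-one-out Q² = 1 − PRESS/TSS (autoscaling re-estimated inside every
fold; TSS about the overall response mean, the standard chemometrics
convention — a fold-mean TSS inflates null Q² noticeably), capped at 5.
LV1 is oriented so the post-intervention class mean score is positive;
for the OGTT time model, so the score–time correlation is positive.
Missing entries are imputed with the feature's training mean
(equivalently 0 after autoscaling).

**Feature selection.** The filter retains features whose model weights
differ significantly (p < 0.05, one-sample t) from the mean weight of
their sign group, positive and negative weights tested separately.  A
single fitted model yields one weight per feature, so replicates come
from the LOO folds the workflow already produces: each feature's
fold-wise LV1 weights (sign-aligned to the full model) are tested
against the sign group's mean full-model weight.  Because a LOO fold
perturbs only one sample, raw fold-to-fold scatter understates sampling
variance; the test uses the jackknife standard error
√((n−1)/n · Σ(w_f − w̄)²), which calibrates the null selection fraction
to ≲ 5 % per sign group (checked by simulation) while recovering
planted discriminators at 1.5 SD with sensitivity ≥ 0.8.  A selected
feature must additionally be more extreme than its group mean (away
from zero).

**Combined model.** Candidates are the selected fasting features, the
selected AUC features, and the clinical block (fasting insulin and
glucose, Matsuda, QUICKI).  After refitting and re-selecting, base-model
features dropped by re-selection are added back and flagged; the final
table carries each feature's provenance (fasting-only / AUC-only /
both / clinical) and its add-back status.

**Permutation validation.** For each of 100 splits, a stratified 2/3–1/3
train/test partition; Q² is the best LOO Q² on the training block,
RMSEP and AUROC are computed on the held-out block (AUROC by
Mann–Whitney pair counting with half-credit ties).  The null repeats the
identical procedure with labels permuted independently per split.
Empirical p uses the add-one rule (1 + exceedances)/(n + 1) against the
observed median (≥ for Q² and AUROC, ≤ for RMSEP), guaranteeing p > 0.

**OGTT time model.** Log intensities are intervention-adjusted by
subtracting each metabolite's phase-specific mean, then regressed on
time (minutes) as a continuous response.  Per-sample LV1/LV2 scores
describe the common post-load trajectory; LV1 loadings (positive =
rising through the OGTT under the fixed orientation) decorate the
chemical-similarity network.

## Chemical-similarity network

Vertices are metabolites with attributes loading_lv1 (signed), size
(= |loading|) and direction (increase / decrease / unclear, with a
configurable dead-band ε, default 0); edges join pairs with Tanimoto
similarity strictly greater than 0.7 — strict, so a pair at exactly the
threshold is excluded.  Fingerprints are an *input* (any uniform-length
binary vector, bitstring or MSB-first hex); computing them from
structures is outside the core so the network stays testable with
synthetic fingerprints.

## Cross-correlation panel

Variables enter only if their PLS-DA loading deviates from the mean
loading by strictly more than one SD.  Correlations are Spearman
(average-tied ranks, two-sided t-approximation p with df = n − 2,
pairwise-complete observations, |ρ| = 1 reported at the smallest
positive float), unadjusted p with the conventional star coding and an
optional BH column.

## Synthetic cohort

Log-normal peak heights: log I = base_m + σ·amp_m·template_m(t) +
b_{s,m} + effect + ε with per-(subject, metabolite) intercepts
b ~ N(0, subject_sd²), residuals ε ~ N(0, residual_sd²), and σ the total
log-SD.  Five archetypes with piecewise-linear templates at the five
timepoints: lipid-suppressed (monotone decline to −1 σ by 120 min),
carb-raised (peak at 30 min), late-rise xeno (rising to +1 σ),
fasting-shifted and inert (flat).  Planted responders (default 20,
alternating channels) shift the post phase by 1.5 σ — as a level shift
for the fasting channel (invisible to the baseline-subtracted AUC) or a
mid-excursion bump for the AUC channel.  Defaults chosen once as
plausible for GC-TOF plasma data: subject_sd 0.35 and residual_sd 0.30
on the natural-log scale (≈ 35–45 % CV), 5 % missing completely at
random, class mix 25/20/5/10/40 % across the archetypes.  The phenotype
generator draws OGTT glucose/insulin curves whose excursion multipliers
are calibrated so the pre-intervention cohort-mean Matsuda index sits
near 2 (insulin-resistant) and rises post-intervention; fasting insulin
falls by the fold 0.74 per subject, modulated by a log-normal
per-subject response magnitude (SD 0.30) that leaves a null effect
exactly null.

What the generator does *not* emulate: chromatographic artifacts, batch
or injection-order drift, intensity-dependent missingness,
cross-metabolite correlation beyond the shared subject intercept, or
kinetic realism of the excursion shapes.  Passing tests therefore show
that the statistics behave correctly under the declared data-generating
process, not that they are robust to every failure mode of real data.

A consequence worth knowing: pre and post samples of the same subject
share their intercepts b_{s,m} across *all* metabolites, so a
fasting-level classifier faced with many features and a modest planted
effect latches onto subject identity, and its held-out predictions are
pulled toward the partner sample's class — permutation validation then
rightly fails.  The AUC endpoint subtracts the baseline and cancels the
intercepts, which is why the AUC model validates at the same planted
effect size.  This mirrors a real design hazard of paired cohorts, and
the package reports both endpoints' permutation results so it is
visible.

## Problem sizes used in the checks

The test suite exercises the full 15/12/13-subject design throughout;
metabolite panels are 40–60 for unit tests, 50 per cohort for the
mixed-model null calibration (20 cohorts, 1,000 tests), and the full
321 for the feature-selection recovery checks.  Permutation suites use
the same n = 100 splits as the analysis default.

## Known limitations

* The mixed model supports exactly one fixed effect (phase); no
  covariates, slopes or multi-factor designs.
* No imputation: missing values are excluded pairwise (or mean-imputed
  only inside PLS, where an all-complete matrix is required).
* The weight-based selection filter is a calibrated heuristic, not an
  error-controlled procedure; its null selection fraction is checked by
  simulation, not guaranteed.
* Empirical permutation p-values are bounded below by 1/(n+1) ≈ 0.0099
  at n = 100.
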