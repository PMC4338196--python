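# Methods

`mirnadx` implements a serum microRNA diagnostic-marker discovery procedure
for pancreato-biliary cancer: bespoke single-channel microarray
preprocessing, stratified train/test marker selection with independent
validation, an exhaustive Fisher-linear-discriminant panel search, and
ROC/confusion-matrix evaluation. A synthetic cohort generator emulates the
originating study design so that every stage is testable without external
data. This note records the model, its assumptions, the defaults, and the
numerical choices where the design was genuinely open.

## Study design being modelled

571 serum samples in eight clinical groups (150 healthy controls, 100
pancreatic cancers, 98 biliary-tract cancers, 21 non-malignant
pancreato-biliary abnormalities, and 50/50/50/52 colon, stomach, esophageal
and liver cancers), profiled on a single-channel array carrying 2,555 miRNA
probes plus negative-control probes. Five paired comparisons are built in;
the pooled comparison (`pb_vs_all`) treats pancreatic + biliary cancer as
the detection target against everything else. Samples are randomly divided,
stratified by clinical group, into a training cohort (2/3) used for marker
selection and model fitting and a test cohort (1/3) used only for
validation.

## Preprocessing

Per array, in fixed order:

1. **Negative-control summary.** The top and bottom `floor(0.05·n)`
   negative-control signals ranked by intensity are removed; the trimmed
   mean m and sample (n−1) standard deviation s give the presence threshold
   m + 2s. The sample SD is a convention choice (population SD would be
   equally defensible at n ≈ 100; the difference is < 1%).
2. **Present call and background subtraction.** A probe is present iff its
   linear signal strictly exceeds the threshold; present signals have m
   subtracted. Thresholding and subtraction act on the linear scale.
3. **Floor replacement.** Present signals are log2-transformed; undetected
   or non-positive values are replaced by that array's minimum detected
   log2 signal minus 0.1. The floor is per array, interpreting the minimum
   as array-specific.
4. **Quantile normalization** across arrays (rank-mean). Ties within an
   array receive the mean of the reference values at their tied ranks.
   Normalization pools all arrays by default; a `groups` argument
   normalizes per batch instead, since the arrays of each clinical group
   were hybridized together in the original design and either pooling is
   defensible.

Two consequences of these choices are worth knowing. First, with
tie-averaging, sorted columns are identical across arrays only in the
absence of ties; floored values form large tie runs, so the bottom of the
distribution differs slightly between arrays. Second, quantile
normalization transmits planted rank changes: a probe whose baseline lies
between a marker's two group levels changes rank between groups and
acquires a small deterministic shift (a few reference-quantile spacings,
about 0.004 log2 at 2,555 probes). This artifact is negligible at realistic
noise but reaches formal significance in the zero-noise limit; the test
suite characterizes it by effect magnitude.

## Marker selection and validation

Within the training cohort, each prevalent probe is tested with a pooled
two-sided Student's t-test (equal variances, df = n₁+n₀−2) and
Bonferroni-corrected at α = 0.01. The prevalence (robustness) filter keeps
probes showing a signal of at least 2⁶ in strictly more than 50% of samples
on at least one side of the comparison; it is applied before correction, so
the Bonferroni multiplicity is the number of prevalent probes (the stricter
reading; `bonferroni_scope="all"` switches to all 2,555). Training-selected
candidates are re-tested in the test cohort; the default validation mode
corrects over the carried-forward candidates (`validation_mode="raw"`
implements the looser reading of "p < 0.01"). Validation can never
resurrect a marker that failed training. Up/down direction is recorded and
a consistency flag is set when training and test disagree in sign.

## Diagnostic index

For a marker subset, the Fisher discriminant is w = S_w⁻¹(μ₁ − μ₀) with
S_w the pooled within-class covariance (denominator n₀+n₁−2), and the
intercept −w·(μ₀+μ₁)/2 places the cut-point 0 midway between the projected
class means (equal priors — the published index is cut at a fixed 0, which
is incompatible with empirical-prior offsets). Weights are left unscaled;
any positive rescaling of (w, b) classifies identically, which is why the
bundled published 4-miRNA function (1.20·miR-6075 − 0.93·miR-6799-5p −
0.22·miR-125a-3p + 0.71·miR-6836-3p − 8.55) is carried as a constant
fixture rather than reproduced from data. A singular S_w (collinear
markers) falls back to a ridge of 10⁻⁶ × mean diagonal. A sample scoring
strictly above 0 is classified to the cancer side; a score exactly at 0
falls on the control side with a warning.

The exhaustive search fits every non-empty subset of the shortlist
(2¹⁰ − 1 = 1,023 panels for ten markers), evaluates
sensitivity/specificity/accuracy on both cohorts and AUC on the test
cohort, and reports all per-size accuracy maxima (ties are real and are
listed). The single best panel uses the tie-break: highest test accuracy,
then fewest markers, then highest test AUC, then enumeration order.
Enumeration is capped at 20 markers (2²⁰ subsets) unless overridden.

AUC is the trapezoid area under the empirical ROC curve, equal to the
Mann–Whitney concordance with ties counted ½. Percentages are reported to
one decimal, half-up, retaining full precision internally.

## Cohort split

Within each group, IDs are sorted, shuffled with a single seeded generator,
and cut at floor(n·f + 0.5). Published per-group cohort sizes are not all
consistent with any one rounding rule, so an explicit per-group override
reproduces them exactly. Groups with fewer than two samples go entirely to
training with a warning.

## Synthetic cohort generator

Per probe p, a baseline b_p is drawn once per cohort from U[4, 14] (log2).
Sample values are b_p + ε with ε ~ N(0, noise_sd_log2); for the ten
reference markers, b_p is replaced by the published cancer-side or
control-side median log2 level, so the population median of each side
equals the planted value (medians and means coincide under the symmetric
noise — a documented simplification). Pancreatic and biliary samples share
the cancer-side level, consistent with the two groups being statistically
inseparable in the original analysis; per-group overrides allow
intermediate profiles. A fraction (default 0.3) of non-marker probes per
array is absent: background only. Negative controls and background draws
come from 2^N(4.0, 0.3).

By default the generator adds a background draw to every probe's linear
signal (`background_additive=True`). This is the physically coherent
reading: the published marker medians are medians of *normalized* signals,
i.e. after background subtraction, so planting them in a signal that never
contained background would double-count the subtraction and distort
low-expression markers (miR-125a-3p's control median 6.02 would emerge near
5.6 and fail the 2⁶ prevalence filter). With background addition,
preprocessing recovers the planted medians to within ~0.01 log2.
`background_additive=False` emits pure expression signals, useful for
exact-value tests.

Defaults: noise_sd_log2 = 0.5 (the original study reports no dispersion;
0.5 log2 ≈ 1.4-fold coefficient of variation is a realistic serum-array
figure), absent fraction 0.3, 100 negative controls, seed 7. For an
independent-marker panel with shift vector d the optimal linear index has
analytic AUC Φ(‖d‖/(σ√2)), used as a parameter-recovery target.

### What the generator does and does not emulate

It reproduces the group structure, planted effect sizes, absent-probe
mechanism and background model that the preprocessing assumes. It does not
model array spatial effects, batch/lot effects, probe-specific variance,
correlated miRNA co-regulation, or heavy-tailed patient-to-patient
variation. Passing the recovery suite therefore shows the pipeline is
correct under its own assumptions, not that the original markers would be
re-discovered in new clinical data.

### Known limitation: power at the weakest planted effects

Two planted markers are intrinsically marginal under the default
conditions, and recovery of all ten is seed-dependent by construction.
miR-4634's planted shift is 0.23 log2 against noise SD 0.5; its two-stage
(Bonferroni training + Bonferroni validation) power at the default cohort
sizes is roughly 15–20%. miR-125a-3p's control-side median of 6.02 sits at
the prevalence threshold 2⁶, giving a per-sample pass probability of ≈ 0.51
and a cohort-level pass rate of ≈ 60–70%. Typical runs validate 7–9 of the
ten planted markers. The published study's far smaller p-values imply an
effective per-sample dispersion closer to 0.2 log2, at which all ten are
recovered with overwhelming power; the default here deliberately keeps the
harder regime rather than calibrating noise to guarantee recovery.

## Problem sizes used in the test suite

Unit tests run on reduced cohorts (tens of samples, tens to hundreds of
probes); the end-to-end suite runs one full default cohort (571 samples ×
2,555 probes) shared across tests, a 100-replicate family-wise-error
simulation at 200 probes and 50+50 samples, and 1,000 fuzzed ROC instances.
The acceptance script re-runs the full default pipeline in about ten
seconds.
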