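# Methods

## Problem and pipeline shape

The package classifies stool samples as IBS-D or healthy from two
measurement channels obtained on the same samples: relative abundances
of microbial genera (compositional, rows sum to 1) and quantified
metabolite concentrations (positive, arbitrary units). One supervised
PLS-DA model is fitted per channel; the two per-sample posteriors are
fused into a single Bayesian classifier; and the fitted models are
condensed into a patient discrimination index (PDI) intended for
clinical interpretation. All model selection and evaluation is by
leave-one-out cross-validation (LOOCV), the natural choice at n = 44:
it removes fold-assignment randomness and keeps 43 samples in every
training set.

## PLS-DA core

Features are autoscaled (per-feature mean 0, unit *sample* variance,
ddof = 1; constant features are scaled by a 1e-12 floor rather than
dropped, mapping them to zero). The class vector is encoded IBS → +1,
HLT → −1 and centered. Components are extracted by NIPALS with deflation
of both X and y; the inner loop stops when successive weight estimates
differ by < 1e-10 in norm (or at 500 iterations — with a univariate
response the loop converges in two passes, the first weight being
Xᵀy/‖Xᵀy‖ exactly). NIPALS leaves each component's sign arbitrary; it is
fixed by forcing the largest-magnitude entry of every weight vector
positive, which makes fits reproducible bit for bit. Fitted invariants —
unit-norm weight columns, mutually orthogonal score columns — are the
exercised contract of the implementation and are property-tested, along
with agreement of the scores with an independent reference PLS
implementation (used only as a test oracle, never in the fit path).

`n_components` defaults to 2, matching the two-dimensional ordination
view (T vs T⊥) in which this kind of model is usually inspected;
explained y-variance is non-decreasing in the component count, so extra
components never hurt in-sample fit, and LOOCV guards against selecting
too many.

## Posterior calibration

The continuous PLS prediction ŷ is turned into p(IBS | ŷ) by fitting one
Gaussian per class to the training ŷ (means and sds, ddof = 1, sds
floored at 1e-12 with a warning for degenerate groups) and applying
Bayes' rule with a configurable prior (default 0.5). Computation is in
log space (logpdf difference through a logistic), which makes the
posterior invariant to any affine rescaling applied consistently to
training and test scores, and numerically safe far from the class means.
With equal class sds this posterior is exactly a logistic function of ŷ.
This two-Gaussian construction is the package's own design choice for
the calibration step; its parameters (two means, two sds, prior) are the
numerical parameters of the fused classifier.

## Fusion

The channels measure disjoint quantities, so conditional independence
given the class is assumed and posteriors combine by the odds product:
prior odds × odds(p_m) × odds(p_c). Probabilities are clipped to
[1e-12, 1 − 1e-12] before forming odds; an exactly certain channel (0 or
1) dominates the fusion, and two contradictory certainties raise rather
than silently pick a side. The combiner is symmetric, strictly
increasing in each argument, has 0.5 as neutral element, and sharpens
agreement (both channels > 0.5 ⇒ fused ≥ their max at prior 0.5) — all
property-tested. "Confidence" of an assignment is the posterior
probability of the assigned class, max(p, 1 − p); the decision threshold
is p ≥ 0.5 with ties deterministically assigned to IBS. Reports include
the mean confidence over all samples and over correctly assigned samples
separately, since either convention is defensible.

## Patient discrimination index

The top-k genera and an equal number of metabolites are selected by
descending first-component |weight| (ties: second-component |weight|,
then feature id). Each selected variable gets a direction d = sign(w₁ ·
c₁) mapped so +1 means elevated in IBS; variables depressed in IBS
contribute negated terms, which is what makes zero the natural decision
boundary of the index. Medians are computed over **all** training
samples, both groups pooled — not per group. Zero protection: when a
selected variable contains zeros in training, ε is half its smallest
positive training value, else 0; PDI is then finite for every valid
input. k is configurable 1–5 (default 3); the pipeline reports a
confusion matrix and ROC AUC for each k rather than auto-selecting.

## Evaluation

IBS is the positive class everywhere; PV_IBS is the positive predictive
value. LR+ = sens/(1−spec) (reported as infinity at perfect
specificity), LR− = (1−sens)/spec (undefined at zero specificity, never
coerced to 0). AUC uses the Mann–Whitney rank formulation with ties
credited 1/2, which equals the trapezoidal area under the stepped ROC
curve exactly; the ROC point sweep itself is delegated to a standard
library routine with no intermediate-point dropping. Mood's median test
dichotomizes at the pooled grand median ("above" vs "not above", ties
counted below) and uses the 1-df chi-square statistic without continuity
correction; a pooled sample that is degenerate at the grand median
yields statistic 0 and p = 1 with a warning.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets: 22 + 22
samples, 115 genera, 19 metabolites, a small disjoint set of driver
features (3 per channel) carrying a group fold change, multiplicative
log-normal noise. Per feature, log-values are baseline + group effect +
Normal(0, noise_sigma); baselines are drawn once per cohort from
Normal(0, baseline_logmean_spread = 2.0), giving the orders-of-magnitude
feature heterogeneity typical of abundance data. Driver directions are
random ±1 (elevated or depressed in IBS); realized fold changes are
exported as ground truth. Genus rows are closed to sum 1 after the draw —
closure is applied only there, since only genera are relative
abundances, and it distorts realized genus fold changes, which is why
genus-channel recovery is asserted as rank recovery (drivers in the
top-k) rather than fold-change magnitude; the closure-free metabolite
channel recovers the fold change directly (group mean ratio ≈ 3 at fold
3). Defaults: fold change 3.0, noise_sigma 0.6; the recovery and fusion
test batteries run at noise_sigma 0.3, a strong-signal regime in which
driver recovery should be essentially certain.

The random stream is ordered (genus baselines, metabolite baselines,
driver choice, driver directions, training samples) so that
`inject_unknown_samples` can regenerate the cohort structure from the
seed alone; unknown samples draw their noise from a stream derived as
`default_rng([seed, 104729])`, making them deterministic and independent
of the training draws.

What the generator does **not** emulate: microbe–microbe or
microbe–metabolite correlation structure, overdispersed zero-inflation
of rare taxa, batch effects, or any distributional feature of the real
cohorts beyond positivity, right skew and compositionality. Passing
tests on this generator therefore demonstrate correctness and internal
consistency of the pipeline, not expected performance on real stool
profiles.

## Problem sizes and determinism

Simulation-backed checks use 44-sample cohorts across 15–25 seeds
(recovery/fusion batteries) and 10–20 seeds (null safety), sizes at
which every battery completes in seconds. All randomness flows through
`numpy.random.default_rng` seeded from configs or the acceptance
script's `--seed`; identical configs give byte-identical pipeline
outputs (asserted in tests). TSV writing uses `repr` for floats so
write-then-read is the identity; table parsing converts cells with
Python's exact `float()` and reports the offending row/column on
failure.

## Known limitations

- The two-Gaussian calibration and the conditional-independence fusion
  are modelling choices; strongly correlated channels would make fused
  posteriors overconfident.
- LOOCV accuracy on 44 samples has high variance; single-seed numbers
  should not be over-read (the test batteries therefore average over
  seeds).
- Exactly two classes and exactly two channels are supported; no
  orthogonal-PLS variant, no VIP-based ranking (weight ranks only).
- The PDI epsilon rule depends on the training zeros of the selected
  variables; a variable that is identically zero in training is
  rejected.
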