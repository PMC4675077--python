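# gutfuse

Two-channel classification of diarrhea-predominant irritable bowel
syndrome (IBS-D) versus health from stool profiles: a PLS-DA model per
data channel (microbial genus relative abundances; quantified fecal
metabolites), Bayesian fusion of the two channel posteriors into a single
classifier, and a **patient discrimination index (PDI)** that condenses
the fitted models into one interpretable per-sample score. The package is
aimed at microbiome/metabolome researchers studying small balanced
case-control cohorts (on the order of 22 + 22 stool samples, ~115 genera,
~19 metabolites) who need a tested, reproducible reimplementation of this
analysis shape, exercised end to end on a seeded synthetic cohort
generator.

## The model

**Per channel.** Features are autoscaled (mean 0, unit sample variance)
and the encoded class vector (IBS → +1, HLT → −1) is regressed on them by
univariate-response NIPALS partial least squares with deflation, giving
unit-norm weight vectors **w**₁…**w**ₖ, orthogonal score vectors
**t**₁…**t**ₖ (the T vs T⊥ ordination axes at k = 2, the default) and a
continuous prediction ŷ. Class-conditional Gaussians fitted to the
training ŷ turn a new sample's ŷ into a posterior *p*(IBS | ŷ) by Bayes'
rule.

**Fusion.** The microbiota posterior *p_m* and metabolite posterior *p_c*
come from disjoint measurements, so they are combined assuming
conditional independence given the class:

    posterior odds = prior odds × p_m/(1−p_m) × p_c/(1−p_c)

**PDI.** The top-k genera and top-k metabolites by first-component
|PLS weight| (default k = 3), each with a direction d ∈ {+1, −1} (+1 =
elevated in IBS), are compared to their medians over *all* training
samples:

    PDI(x) = Σᵢ dᵢ · log₂((xᵢ + εᵢ) / (medianᵢ + εᵢ))

PDI > 0 marks an IBS-like sample, PDI < 0 a healthy-like one; εᵢ is half
the smallest positive training value when the variable contains zeros.

**Evaluation.** Leave-one-out cross-validation (fit, scaling and
calibration all recomputed per held-out sample), confusion diagnostics
with IBS as the positive class (sensitivity, specificity, accuracy,
PV_IBS, LR+ = sens/(1−spec), LR− = (1−sens)/spec), rank-based ROC/AUC,
and Mood's median test for the PDI group difference.

## Worked example

```python
import numpy as np
import gutfuse as gf

cfg = gf.CohortConfig(seed=11, noise_sigma=0.3)   # 22+22 samples, fold 3 drivers
genus, metab, meta, truth = gf.generate_cohort(cfg)

post_g = gf.loocv_posteriors(genus, meta)         # microbiota channel
post_m = gf.loocv_posteriors(metab, meta)         # metabolite channel
fused = gf.fuse_cohort(post_g, post_m)

true = np.array(meta.group)
rep = gf.confusion_metrics(true, [f.assigned_group for f in fused],
                           [f.confidence for f in fused])
print(f"fused LOOCV accuracy {rep.accuracy:.3f}, "
      f"mean confidence {rep.mean_confidence:.3f}")

gm = gf.fit_channel_model(genus, meta)
mm = gf.fit_channel_model(metab, meta)
pdi = gf.build_pdi(gm, mm, genus, metab, k=3)
vals = gf.pdi_cohort(genus, metab, pdi)
print(f"median PDI  IBS {np.median(vals[true=='IBS']):+.2f}  "
      f"HLT {np.median(vals[true=='HLT']):+.2f}")
```

prints

```
fused LOOCV accuracy 0.955, mean confidence 0.999
median PDI  IBS +4.23  HLT -4.87
```

i.e. on this low-noise synthetic cohort the fused classifier assigns 42
of the 44 held-out samples correctly, and the PDI separates the groups
around zero as designed (IBS-like samples positive, healthy-like
negative).

The same analysis is available from the shell:

```sh
gutfuse run --seed 11 --out runs/demo     # simulate → fit → fuse → PDI → evaluate
gutfuse --help                            # simulate / validate / fit / classify / pdi / evaluate / run
```

which writes the cohort tables, per-channel LOOCV posteriors, fused
assignments, a diffable plain-text model bundle, PDI values, ROC tables
and JSON evaluation reports, plus a manifest.

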