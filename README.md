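# transgrad

Transdiagnostic analysis of cortical effect maps: extraction of a shared
disease dimension from condition-wise cortical-thickness effect sizes, and
its multiscale contextualization against connectome gradients, laminar
profile features and neurotransmitter maps.

## The problem

Psychiatric and neurodevelopmental conditions (ASD, ADHD, MDD, OCD, bipolar
disorder, schizophrenia) show partially overlapping patterns of cortical
thickness alteration. Given a regions × conditions matrix **X** of
meta-analytic effect sizes on a cortical atlas (e.g. Desikan–Killiany, 68
regions), the *shared disease dimension* is the first principal component of
the column-centered matrix: one score per region describing the
transdiagnostic axis of morphological vulnerability,

&nbsp;&nbsp;&nbsp;&nbsp;X̃ = X − 1 x̄ᵀ, &nbsp; X̃ = U S Vᵀ, &nbsp; scores = U₁ s₁, &nbsp; loadings = V₁.

This package implements the full downstream workflow around that
decomposition, for researchers working with parcellated cortical maps:

- **Shared dimension** — PCA of the effect matrix with a fixed sign
  convention, variance explained, mean-effect map, and leave-one-condition-out
  sensitivity refits (`SharedDimension` → `SharedDimensionResults`).
- **Connectome gradients** — microstructural profile covariance (partial
  correlation of depth-wise intensity profiles controlling for the
  cortex-mean profile, zero-thresholded and log-transformed), Fisher r-to-z
  functional matrices, row-wise top-10% sparsification, normalized-angle
  affinity, and diffusion map embedding with α = 0.5, t = 0
  (`DiffusionGradients` → `GradientResults`).
- **Laminar profile features** — depth-profile moments (mean, SD, skewness,
  kurtosis) and externopyramidization
  EP = (peak/mean intensity) × (1 − d_peak), the shift of intensity toward
  supragranular layers.
- **Spin tests** — spatial-autocorrelation-preserving permutation
  correlations between parcel maps (random sphere rotations, mirrored across
  hemispheres, nearest-centroid reassignment), with Benjamini–Hochberg FDR
  across feature families, plus stratification by functional-community and
  hierarchy labels.
- **Multiscale prediction** — nested five-fold LASSO (inner folds select the
  penalty by mean absolute error), 100 repeats, feature selection
  frequencies, and a region-shuffling permutation test
  (`MultiscaleLasso` → `PredictionResults`).
- **Synthetic cohorts** — a first-class generator producing parcellations on
  the sphere, spatially autocorrelated maps, effect matrices with a planted
  rank-1 shared component, unimodal depth profiles, connectivity with a
  planted 1-D axis, and feature panels with known informative columns, so
  every stage is verifiable against planted ground truth without any imaging
  data.

## Worked example

```python
import numpy as np
import transgrad as tg

cfg = tg.SimulationConfig(seed=7)            # 68 regions, 6 conditions
meta = tg.make_parcellation(cfg)
planted = tg.simulate_smooth_map(meta, cfg.lengthscale, seed=11)
effects = tg.simulate_effect_matrix(meta, planted, cfg)

res = tg.fit_shared_dimension(effects)
print(res.summary())
```

```
Shared dimension (principal components of effect matrix)
==========================================================
Regions: 68    Conditions: 6    Scaling: center
Orientation: corr(scores, column-mean map) > 0

Component   Var.explained   Cumulative
PC1               0.6178       0.6178
PC2               0.1425       0.7603
...
```

The first dimension explains 61.8% of the variance in this simulated cohort
(the planted shared component carries ~50% of the generative variance; PC1
additionally absorbs aligned noise). It recovers the planted map with
|r| = 0.95, and refitting without each condition in turn leaves it
essentially unchanged:

```python
print(tg.leave_one_condition_out(effects, res).to_string(index=False))
```

```
held_out    abs_r
     ASD 0.986304
    ADHD 0.973605
     MDD 0.989804
     OCD 0.987929
      BD 0.985391
     SCZ 0.992796
```

Spin-test the dimension against a multiscale feature panel and predict it
with nested-CV LASSO:

```python
panel = tg.simulate_feature_panel(meta, planted, cfg)
spins = tg.generate_spins(meta, n_rotations=1000, seed=1)
table = tg.test_feature_panel(res.score_map(0), panel, spins)  # r, p_spin, q_fdr

pred = tg.nested_lasso_predict(panel, res.score_map(0), n_repeats=100, seed=0)
print(pred.summary())
```

## Command line

```bash
transgrad simulate --out sim/ --seed 1            # synthetic inputs + ground truth
transgrad shared-dim --effects sim/effects.tsv --meta sim/parcellation.tsv \
    --out out/ --loco
transgrad gradients --profiles sim/profiles.tsv --meta sim/parcellation.tsv \
    --out out/ --density 0.1 --alpha 0.5 --t 0
transgrad correlate --target out/shared_scores.tsv --panel sim/feature_panel.tsv \
    --meta sim/parcellation.tsv --out out/correlations.tsv --n-spins 1000 --seed 1
transgrad predict --panel sim/feature_panel.tsv --target out/shared_scores.tsv \
    --meta sim/parcellation.tsv --out out/ --repeats 100
transgrad run --config config.yaml --out out/    # full configuration-driven run
```

All tables are tab-delimited with a `region_id` first column; runs are
deterministic for a fixed configuration and seed.

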