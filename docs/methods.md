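# Methods

This note documents the models and procedures implemented in `transgrad`,
the numerical conventions they pin down, what the synthetic-data generator
does and does not emulate, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Shared disease dimension

Given a regions × conditions effect matrix **X** (no missing entries; use
`align_sources` first), the model column-centers each condition
(`scaling="center"`, the default) or additionally divides by the condition
SD (`scaling="zscore"`), then takes the SVD. Scores are `U S` (one value
per region), loadings are the right singular vectors (one weight per
condition), and variance explained is `s²ₖ / Σ s²`. Variance-explained
figures depend on the scaling mode, which is why both are exposed and the
mode is recorded on the results object.

**Orientation.** Eigenvector signs are arbitrary, so each component is
oriented so that its correlation with the column-mean effect map is
positive; with thickness *decreases* coded negative this means the regions
with the strongest average atrophy receive negative scores. If a component
is exactly orthogonal to the mean map, the entry of largest magnitude is
made positive instead. This single fixed rule makes all downstream
correlations reproducible.

**Sensitivity variants.** `mean_effect_map` is the row-wise arithmetic
mean. `leave_one_condition_out` refits on every (k−1)-condition submatrix
and reports the absolute correlation with the reference component-1 scores;
the absolute value is used because the refit eigenvector sign is not
comparable across fits.

## Similarity matrices and gradients

**Microstructural profile covariance (MPC).** For depth-wise intensity
profiles (rows = regions, columns = depth fractions, 0 pial → 1 white), the
entry (i, j) is the correlation of the residuals of profiles i and j after
regressing each on the cortex-mean profile (intercept included) — a partial
correlation controlling for the average profile. Negative entries are set
to zero; positive entries r are mapped by log(r / (1 − r)), with r clipped
at 1 − 1e-9 so perfectly correlated profiles produce a large finite value
rather than infinity. Note the log-odds of r < 0.5 is negative; the
thresholding guarantee is that no entry derives from a negative partial
correlation. Zero-variance residual profiles get their row/column zeroed
with a logged warning rather than aborting a whole matrix. The exact form
of the log transform is isolated in one place; downstream results depend
only on its monotonicity.

**Functional matrices.** `fisher_z_matrix` applies arctanh with ±(1 − 1e-9)
clipping and zeroes the diagonal.

**Sparsification and affinity.** `sparsify_rows` keeps the ⌈density · n⌉
largest off-diagonal entries per row (ties to the lower column index,
making the operation fully deterministic) and deliberately returns an
asymmetric matrix: the normalized-angle kernel that follows compares entire
rows, affinity(i,j) = 1 − arccos(cos θᵢⱼ)/π, and is symmetric by
construction, which is how the described order of operations resolves the
asymmetry. arccos loses ~√ε precision near its endpoints, so identical rows
score 1 only to about 1e-7.

**Diffusion map embedding.** With affinity **W**, the density-normalized
kernel is W' = D^(−α) W D^(−α) (α = 0.5 by default, balancing manifold
geometry against sampling density), and the transition operator is the
row-normalization of W'. Eigenvectors are computed through the symmetric
conjugate D₁^(−1/2) W' D₁^(−1/2) and mapped back, which keeps the solver a
dense symmetric eigendecomposition — parcellations have at most a few
hundred regions, so no iterative solver is needed. The trivial constant
eigenvector (eigenvalue 1) is dropped; component k is unit-normalized and
scaled by λₖ/(1 − λₖ) when t = 0 (the automatic-diffusion-time convention;
the parameter pair α = 0.5, t = 0 is only meaningful under it) or by λₖᵗ
for t > 0. Components are sign-oriented by their covariance with the first
centroid coordinate axis — arbitrary but fixed. Disconnected affinity
graphs are rejected with the component memberships listed.

The planted-axis connectivity produced by `simulate_connectivity` is itself
a valid affinity (symmetric, nonnegative, unit diagonal) and is embedded
directly in recovery tests; the sparsify → angle-kernel path is the
real-data pipeline. The angle kernel's 0.5 baseline (orthogonal sparse
rows) compresses banded planted structure, so axis recovery through the
full pipeline is weaker than through direct embedding — a property of the
kernel, not of the eigensolver.

## Laminar profile features

Moments per region: arithmetic mean; sample SD (n−1); population-moment
skewness g₁ = m₃/m₂^1.5 and excess kurtosis g₂ = m₄/m₂² − 3 with
n-denominator central moments — the default estimators of the scientific
Python stack, chosen so results are directly comparable with common
practice; swapping in bias-corrected estimators would only require changing
one call. Zero-variance profiles get skewness = kurtosis = 0 with a logged
warning instead of NaN.

Externopyramidization is EP = (peak intensity / mean intensity) ×
(1 − d_peak), where d_peak is the depth fraction of the profile maximum and
1 − d_peak = 1 − thickness_supra/thickness_total is the relative thickness
below the peak. Conventions pinned here: "intensity" in the numerator is
the *peak* intensity (the ratio to the mean is otherwise undefined for a
whole profile); the supra/total ratio enters as 1 − (t_supra/t_total), the
dimensionally consistent form matching the interpretation that superficial
peaks yield high EP; ties at the maximum resolve to the shallowest depth,
so a uniform profile has EP = 1. EP is invariant to positive rescaling of a
profile and, in the continuum, non-increasing as a bump moves deeper; on a
discrete depth grid d_peak snaps to samples, producing a small sawtooth
(~0.006 at 18 depths) on top of the monotone trend.

## Spin tests, FDR and stratification

Spatial autocorrelation inflates map-to-map correlations, so significance
uses spin permutations: per rotation, a uniform random 3-D rotation is
applied to one hemisphere's centroids and its reflection through the
sagittal plane to the other (preserving homotopy), and each original
centroid receives the value of the nearest rotated centroid within its
hemisphere. Duplicate assignments are accepted, as in standard parcel-level
spin schemes. Conventions pinned because they change p-values slightly: the
*target* map (first argument) is the one permuted, and the two-tailed
p-value uses the +1-corrected counting rule
p = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_rotations), which keeps p > 0 and
the test valid at finite rotation counts. The observed correlation is
computed through the same vectorized code path as the null so that an
identity assignment reproduces it exactly.

FDR across a feature family uses Benjamini–Hochberg step-up q-values
(via statsmodels), returned in input order. `stratify_map` reports
count/mean/SD per community or hierarchy class; empty classes appear with
count 0 and masked statistics.

Calibration is the headline property: with mutually independent but
spatially autocorrelated maps (lengthscale 0.6 rad, 68 regions, 1000
rotations) the empirical type-I error at α = 0.05 must stay within
Monte-Carlo bounds, and with spatially white maps the p-values must be
uniform; both are asserted in the acceptance suite.

## Nested-CV LASSO prediction

Outer five-fold CV provides held-out regions; within each outer training
set an inner five-fold CV picks the L1 penalty with the lowest mean
absolute error from a grid of 100 log-spaced values running from the
data-derived maximum (the smallest penalty that zeroes all coefficients)
down to 1e-4 of it — the conventional path when no grid is prescribed. Ties
resolve to the larger penalty. Features are standardized with
training-fold statistics only (LASSO is scale-sensitive and the panel
mixes units); the intercept is fitted on centered data and never penalized.
Per repeat, out-of-fold predictions are assembled across the five outer
folds and summarized as Pearson r and MAE; feature selection frequency is
the fraction of (outer fold × repeat) refits with a nonzero coefficient.

The permutation test shuffles the target across regions and reruns the
nested procedure; by default each of the shuffles uses a single repeat
(`reduced_repeats=1`) while the observed statistic keeps the full repeat
count — the null mean is insensitive to the repeat count, and rerunning
hundreds of full 100-repeat procedures would add nothing but cost.

Two statistical properties worth knowing. First, out-of-fold correlation is
*negatively* biased under the null (fold-mean predictions anti-correlate
with held-out values); the permutation null shares the bias, so inference
is unaffected, but a "null r ≈ 0" intuition is wrong by about −0.1 to −0.2
at these sizes. Second, penalty selection by minimum CV error is not
selection-consistent: when prediction is easy, the chosen penalty sits near
the unpenalized end and spuriously correlated features enter the model
freely, so selection frequencies of irrelevant features can be high even
though prediction performance and its permutation test are well behaved.
Both effects are intrinsic to the prescribed procedure, not implementation
artifacts, and both are visible in the synthetic experiments.

## Synthetic data: what it emulates, and what it does not

The generator plants recoverable structure matching the assumptions of each
stage. Parcellations place quasi-uniform centroids on each hemisphere of
the unit sphere by a deterministic golden-angle spiral (reproducible
coverage without iterative optimization), mirror-symmetric about the
sagittal plane; 7 community and 4 hierarchy labels come from fixed anchor
directions computed on mirrored coordinates so homotopic regions share
labels. Smooth maps are zero-mean unit-variance draws from a
squared-exponential kernel of great-circle distance with 1e-8 diagonal
jitter — the simplest stationary autocorrelation the spin test is designed
for. Effect matrices are loading × shared map + noise_sd × independent
smooth maps; profiles are a baseline plus a Gaussian bump in depth of fixed
width 0.15 (one free location parameter keeps recovery tests
interpretable); connectivity is a squared-exponential kernel of planted
axis differences; feature panels carry β × target + noise in a known
subset of columns.

Default study conditions, fixed once: 34 regions per hemisphere (68 total),
six conditions with loadings (1, 1, 1, 0.8, 0.8, 0.6), noise_sd = 0.88 so
the planted component carries ~50% of generative variance
(Σλ² = 4.64 = 6 × 0.88²), angular lengthscale 0.6 rad, 14 profile depths,
17 features with 3 informative at β = 1 (per-feature R² = 0.5).

What passing tests on these data do *not* show about real data: the
generator has no realistic cortical geometry or folding, no vertex-level
structure, no subject-level variability (matrices are group-level by
construction), stationary isotropic autocorrelation rather than the
regionally varying smoothness of real cortical maps, and noise that shares
the signal's lengthscale. Recovery thresholds met here bound what the
*algorithms* do under their own assumptions, not what any cohort will
yield. One consequence computed explicitly in the test suite: with
spatially smooth noise at 68 regions the effective number of independent
samples is ~12, so PC1 recovery of a planted component carrying half the
variance plateaus around r ≈ 0.93 — a sampling limit, not an implementation
one.

## Degenerate inputs and numerical choices

Missing data are explicit (masked entries / empty cells) and never imputed;
analyses either raise with a pointer to `align_sources` or operate on the
aligned intersection. Constant matrices, constant maps, zero-variance
profiles, disconnected graphs and all-zero affinity rows raise named
errors. Tables are written with 17 significant digits so write → read is
the identity to better than 1e-12 and two writes are byte-identical; spin
tables, fold splits and all generators are pure functions of their seeds.
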