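# Methods

This note records the models the package implements, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical choices that matter for reproducibility.

## Attraction-vector scoring

Scale means are computed only when at least 75% of a scale's items are
answered; otherwise the score is missing (NaN) and propagates — nothing is
imputed. Participants with missing behavior values are excluded from the
PLS stage with a logged warning.

The androphilia/gynephilia means (each in [1, 5]) define a vector whose
magnitude √(a² + g²) summarizes the overall strength of attractions
(attainable range [√2, √50] ≈ [1.41, 7.07]) and whose phase
arccos(a/magnitude) in degrees summarizes the androphilia–gynephilia
valence (attainable range ≈ [11.31°, 78.69°], symmetric ±33.69° about 45°).
Degrees, not radians, are used everywhere downstream. Internally all
computation keeps full precision; display rounding is half-up to two
decimals. The representation is exactly invertible:
a = m·cos θ, g = m·sin θ.

The gender-dysphoria screen is strict: a questionnaire mean < 3.00 flags
likely dysphoria; exactly 3.00 does not. Items are scored as given — no
reverse-keying is applied before averaging.

## ROI extraction

All three volumes (metric, gray-matter probability, integer labels) must
share a grid; a shape mismatch is a hard error. The gray-matter gate is
strict (probability > 0.40), so adding voxels at or below the threshold can
never change a summary — this is tested directly.

T1 histograms span the open interval (500, 5000) ms with 30 ms bins (values
at the bounds are excluded; a final partial bin is retained when the span
is not a multiple of the width). The regional T1 is the peak of an
interpolating cubic spline through the (bin center, count) pairs, evaluated
on a 1 ms grid over the histogram's nonzero support. An interpolating
spline was chosen over a smoothing spline because a smoothing parameter
would be an extra, hard-to-justify degree of freedom; the 1 ms grid search
makes the peak location deterministic and platform-stable. With fewer than
four bins of nonzero support the spline is underdetermined and the center
of the max-count bin is used instead (logged). The mode is invariant to
uniform rescaling of the counts.

MD summaries use the arithmetic mean of voxel values inside
(0.0005, 0.004) mm²/s. The window doubles as an outlier gate and can be
disabled. The MD bin width is 5 × 10⁻⁵ mm²/s (70 bins over the window),
stating the width in the map's native unit exactly as the T1 convention
does. Regions with fewer than 10 retained voxels are flagged and excluded
from downstream matrices.

## Group comparisons

Classical one-way ANOVA with Fisher's LSD post hocs (pooled MSE, unadjusted
p — LSD is unadjusted by definition) is the default. Levene's test uses
the group *mean* as center, matching the convention of mainstream
commercial statistics packages. When Levene's test is significant at
α = 0.05, the report switches to the heteroscedasticity-robust pair:
Welch's test (variance-weighted means, Satterthwaite-type denominator df)
and the Brown–Forsythe equal-means statistic
F\* = Σnᵢ(x̄ᵢ − x̄)² / Σ(1 − nᵢ/N)sᵢ², plus the Games–Howell post hoc
(Welch-type SE, Welch–Satterthwaite df, studentized-range reference).
Everything is two-tailed at α = 0.05. These routines are implemented from
the textbook formulas; the test suite cross-checks them against an
independent statistics library and against null-calibration simulations
(type-I error within [0.03, 0.07] at α = 0.05).

## Random-intercept T1→MD model

Observations are (participant, region) pairs; the model is
y = β₀ + β₁x + u_cluster + ε with a fixed slope and a participant-level
random intercept. Choices:

* **Grand standardization** (across all observations), not within-cluster:
  the question is the overall T1–MD association across cortex and
  participants, and sample SDs are used.
* **Full ML**, not REML (the default of the mixed-model software family
  this mirrors); REML is available behind a flag and the tests record that
  the difference at study scale is negligible.
* **Estimation** is a bounded one-dimensional profile over the variance
  ratio λ = var_intercept/var_residual: for fixed λ the GLS fixed effects
  and the profiled residual variance are closed-form (per-cluster rank-one
  downdates, O(N) per evaluation), so only λ is optimized (on log(1+λ),
  tolerance 10⁻¹⁰). The boundary λ = 0 (collapse to pooled OLS) is
  explicitly checked and permitted.
* **Inference** is a Wald z-test from the GLS information matrix;
  Satterthwaite-type df corrections are out of scope.

The fit is deterministic given the data and is verified in three
independent ways: against a dense-matrix GLS oracle on a balanced toy,
against an established mixed-model implementation, and against a 21 × 21
profile-likelihood grid around the returned variance components.

## Behavior PLS

The brain block is z-scored per column across all participants (sample SD).
For each group the Pearson correlations of the three behaviors with all 152
columns are stacked group-major into the 9 × 152 cross-block matrix R, and
R = V S Uᵀ is decomposed by SVD. The LV orientation is fixed
deterministically: each LV is flipped so the largest-|v| element is
positive (ties break to the lowest row index). Squared singular values are
conserved (Σs² = ‖R‖²_F, tested to 10⁻¹⁰) and are reported both as raw
values and as percentage shares.

* **Permutation test** (default 1000 samples): brain rows are permuted
  across the *whole* sample while behavior and group assignment stay fixed,
  the full cross-block + SVD pipeline is re-run, and
  p = (#{s_perm ≥ s_obs} + 1)/(n_perm + 1). The add-one form never reports
  zero; a p at the floor is rendered "< 1/(n_perm+1)". Whole-sample
  exchange is the standard null for this PLS flavor; a within-group scheme
  is available behind a flag. The null calibration (three groups of 15, 152
  columns) is verified by simulation.
* **Bootstrap** (default 1000 samples): participants are resampled with
  replacement within group, preserving group sizes. Each resample's (u, v)
  is rotated onto the original axes by orthogonal Procrustes on the v
  block before accumulating — without this, axis reflections inflate the
  SEs. Salience reliability is the ratio of the original salience to its
  bootstrap SE, thresholded at |ratio| ≥ 3; 95% percentile CIs are formed
  for the nine brain-score–behavior correlations per LV. Degenerate
  resamples (a behavior constant within a group) are redrawn and counted.
* All nine LVs are retained; significance is assessed per LV. Age enters
  in months untransformed; behaviors are not z-scored because within-group
  Pearson correlation is scale-invariant.

## Synthetic-data generators

All generators are pure functions of (spec, seed) via `numpy`'s
`default_rng`; the pipeline derives per-stage substreams from one run seed
so toggling a stage never perturbs another stage's draws.

**Cohort.** Group sizes default to 14/15/17 with ages uniform on per-group
windows within 147–216 months. Participant-level (strength, phase) pairs
are drawn from truncated normals at the group-level targets (strength
3.25/2.98/2.83, phase 64.60/46.99/30.94 with the corresponding SDs; the
dysphoric group's identity-questionnaire mean ≈ 2.17, the cisgender groups
≈ 4.9). Because the attainable (strength, phase) region is the image of
the [1, 5]² square, truncation would bias naive draws; the location
parameters are therefore solved so the *truncated* means hit the targets
(for strength, a single group-level location is solved, since individuals
at extreme phases cannot geometrically reach the group target). Item
responses are 1 + Binomial(4, (latent − 1)/4) per item — mean exactly the
latent value, no floor/ceiling clipping bias — and the participant table is
produced by re-scoring those items through the real scoring code. What is
*not* emulated: item covariance structure beyond the shared latent, the
empirical age–strength correlation (injectable via a shared factor,
default off), and the truncation-induced SD shrinkage of strength/degree
relative to the targets (means are matched; SDs run somewhat below
target). Passing cohort tests therefore show correct scoring and
group-moment behavior, not questionnaire psychometrics.

**Brain table.** On the z-scale, T1 columns are √ICC·aᵢ + noise with a
participant intercept aᵢ shared (rescaled) with the MD half so the
standardized T1→MD slope is the configured 0.089 at ICC 0.5. The planted
effect adds loading·effect_size·cᵢ to 38 of the 152 columns (29 T1 with
negative sign, 9 MD with positive sign — the split of the empirically
stable set) for participants in the two affected groups, where cᵢ is the
equal-weighted standardized behavior composite. The default effect size
1.0 against unit noise yields within-group brain–behavior correlations
near 0.7 on planted columns, the magnitude of the stable correlations the
method is expected to resolve. Spatial structure (lobe/hemisphere
lateralization, inter-region correlation) is not modeled.

**Phantom.** An integer grid is partitioned into 5 × 4 × 4 rectangular
blocks (76 labeled). Interior voxels get gray-matter probability 0.95; a
one-voxel rind gets 0.30, below the 0.40 gate, so rind voxels must never
contribute. Per-ROI T1 is offset + Gamma(shape 6, scale 15 ms) — positively
skewed, with analytic density mode offset + 75 ms stored as truth and
peaked enough that the ~700 interior voxels per ROI localize the histogram
mode well within one 30 ms bin. MD is constant per ROI, so gated means are
exact. Phantoms are already-fitted metric maps; no raw acquisition physics
is simulated.

## Problem sizes used in the validation suite

The resampling checks run at deliberately chosen scales: permutation null
calibration uses 500 replicates of 200 permutations (three groups of 15,
152 columns); planted-effect recovery uses n = 50/group with 1000
permutations and 1000 bootstraps; mixed-model recovery uses 200 replicates
at 46 × 76. These sizes give stable pass/fail behavior for the quantities
asserted (rejection rates, coverage, stability fractions) while keeping
the default test run fast.

## Known limitations

* The ROI extractor assumes co-registered inputs; registration,
  segmentation, tensor fitting, and T1-map computation are upstream of
  this package.
* Whether outliers should be excluded before or only at histogramming is
  ambiguous for real acquisitions; both behaviors sit behind the
  `gate` flag of the MD mean and the histogram bounds for T1.
* The mixed model offers no random slopes, crossed random effects, or
  sandwich SEs — it is exactly the default fixed-slope/random-intercept
  specification.
* Behavior PLS here is the group-stacked correlation ("behavior") flavor;
  mean-centered task PLS, seed PLS, and sparse/multi-block variants are
  out of scope, as is surface rendering.
* Bootstrap stability counts are sensitive to resampling noise at
  realistic sample sizes; the package asserts qualitative recovery
  (planted vs null separation), not exact stable-region counts.
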