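# Methods

This note records the modelling assumptions, numerical choices and default
parameters behind `bodycal`, and what the synthetic-data tests do and do
not establish about real scan data.

## Shape representation and alignment

A cohort is a set of corresponded meshes: vertex i is the same anatomical
location on every identity, so shapes can be compared coordinate-wise.
Head, neck, hands and feet are tagged `excluded` and dropped before any
statistics; the retained torso + limb vertices are flattened to vectors of
contiguous (x, y, z) triples in ascending vertex index, in centimetres.
The `full` vertex preset mirrors a high-resolution scanning pipeline
(79,522 raw vertices, 26,665 retained, 12,697 torso, hence 79,995-element
vectors); the `small` preset (600/560/300) is the default for simulation
and testing.  The flattening order is a convention — any fixed,
documented order works because all operations use the same index map —
and the interleaved per-vertex layout was chosen so one vertex's error is
a contiguous triple.

Superimposition is partial Procrustes: translation plus proper rotation
only.  Scaling is deliberately excluded because overall size is informative
about composition, and reflections are excluded because bodies must not be
mirrored; if the unconstrained orthogonal solution is a reflection, the
smallest singular direction of the cross-covariance is flipped (Kabsch
correction).  The transform is estimated on retained vertices only and
applied to the whole mesh.  The consensus procedure defaults to a single
pass — centre every shape on its retained centroid, average, fit each
shape to the average — with optional iteration of the average/fit cycle to
a tolerance of 1e-6 cm (cap 100), since whether iterating materially
changes the mean is an empirical question the single pass answers well
enough for cohorts in normal poses.

## PCA + regressions model

PCA is computed by SVD of the mean-centred shape matrix without
per-coordinate rescaling (all coordinates share units).  All components
with nonzero variance are retained, at most c − 1 for c identities; no
significance filtering is applied to the per-component regressions —
components unrelated to composition get near-zero slopes and contribute
nothing to predicted change, so filtering is unnecessary.  Component signs
are fixed by making each component's largest-magnitude loading positive,
purely for reproducibility.  Predictors are used in raw kg (or raw BMI),
so slopes are interpretable as shape change per kilogram.

Prediction at predictor values outside the training range is clamped to
the range with a warning by default (`refuse` and `allow` policies are
available): the model is linear and extrapolates formally, but its
accuracy outside the observed composition range cannot be verified.
Morphing an individual applies the *difference* of predicted component
scores between two composition states to the individual's own shape
vector, so the morph is exact at zero change and additive along paths.

## Leave-one-out evaluation

Within each fold, the consensus mean and the PCA basis are refit from the
n − 1 training identities, and the held-out scan is aligned to the fold
mean before errors are measured (a `full_mean` switch aligns to the
all-identity consensus instead; strict fold hygiene is the default).
Error is the mean Euclidean vertex distance over the torso only, because
arm and leg placement is idiosyncratic to each scan.  The paired
comparison reports t with a sign convention of "positive = model A
better" (the test is computed on error_B − error_A), two-tailed p, and
the paired effect size d_z = mean(diff)/SD(diff) = t/√n.  A zero-variance
difference (identical models) is reported as t = 0, p = 1 rather than
undefined.  Error heatmaps divide both models' per-vertex errors by their
shared maximum so both maps share one colour scale; if the maximum is
zero all proportions are defined as zero.

## Method-of-adjustment model

The response model is the minimal classical one: per-trial (fat, muscle)
settings are bivariate normal around the internal PSE with per-dimension
SDs equal to the true DLs and a configurable trial correlation.  Start
points are recorded but inert — anchoring effects are out of scope.  DL
estimates use the n − 1 denominator; this matters slightly for the shape
of the variability-vs-trials curve, which is why it is fixed here.  The
trial-count Monte Carlo (target DLs 0.5/1.0/2.0 kg, 5–90 trials, 10,000
resamples per cell) reports the SD of the DL estimates per cell; for
normal data this quantity has the closed form σ·√(1 − c₄(n)²), which the
tests use as an independent oracle, and the mean estimate shows the known
c₄(n) small-sample bias.

## Multivariate outcome regression

Y = XB + E is fit by OLS; per-coefficient t tests use the residual
covariance Σ̂ = E′E/(n − p) and the diagonal of (X′X)⁻¹.  Each predictor's
overall test is Wilks' Λ on a single-row (type III) contrast,
H = (LB̂)′(L(X′X)⁻¹L′)⁻¹(LB̂), Λ = det(E)/det(E + H); for a one-row
contrast Rao's F transform of Λ is exact, so no approximation error
enters.  Two-tailed p-values, no multiple-testing correction.  Scenario
pipelines operate in z-scores, so shift vectors (measured composition →
fitted outcome) are in z-score units.

## Synthetic data: what it emulates, and what it does not

**Composition cohorts.**  (fat, muscle) are drawn from a bivariate normal
truncated at physiological floors (fat ≥ 2 kg, muscle ≥ 15 kg) by
rejection.  Truncation shifts the moments of the kept sample, so the
default per-sex raw parameters are *calibrated*: they were solved once, by
fixed-point iteration on simulated truncated moments, so that the realized
cohort reproduces the target descriptives (men 14.53 ± 7.39 / 39.55 ±
5.61 kg, r = 0.45; women 17.65 ± 7.92 / 26.34 ± 2.79 kg, r = 0.38).
User-supplied parameters are used directly as raw values.  Weight is fat +
muscle + a residual mass affine in height with noise (floored at 5 kg),
chosen so mean BMI lands near 25.35 (men) / 23.8 (women); BMI is computed
from weight and height.

**Mesh cohorts.**  The base body is a stylised tube assembly with exact
per-region vertex counts.  Identity i's geometry is
base + FATM_i·d_fat + SMM_i·d_muscle + ε, followed by a small random
rigid transform (rotation SD 0.03 rad, translation SD 1 cm) emulating
posture/placement variation; ε is i.i.d. normal per coordinate with SD
0.2 cm by default, standing in for scanner and correspondence noise.  The
fat field pushes torso vertices radially outward, peaked at the belly;
the muscle field acts mainly on limbs and shoulders.  Both fields are
projected to have zero retained-region mean, zero torque against the
base, and symmetric cross-coupling, which makes the Procrustes fit of a
noiseless shape to the mean exactly the identity and keeps the
composition→shape map exactly linear — this is what lets tests assert
machine-precision ground-truth recovery.  Passing tests on these cohorts
establishes that the pipeline is correct for linear shape variation; they
do not establish that real bodies are linear in composition, that the
fields resemble real deposition patterns, or the error magnitudes to
expect on real scans.

**Simpson demonstration.**  The published covariances behind the original
figure are not available, so the joint model is this package's own: BMI
drives both masses upward (1.3 and 1.6 kg per BMI unit for fat and
muscle), and at fixed BMI a zero-sum share disturbance (SD 3 kg) moves
mass between fat and muscle, plus small independent muscle noise (SD
1 kg) and a 0.5 kg fat floor.  These defaults were chosen so the
qualitative pattern — positive marginal slope, five negative band slopes —
holds robustly (no sign failure in 2,000 simulated replications), and are
not presented as the original study's values.  BMI is rejection-sampled
from N(25.35, 3.79²) within each band.

**Toy scenarios.**  Standardized predictors with fat–muscle covariance
0.45 and a psych covariate independent of both; true coefficients
[[1,1,0,0],[1,0,1,0.5]] (self-estimate) and [[−2.5,0.1,0,0],[2.5,0,0.1,0]]
(ideal); residual SD 0.4 and n = 100 by default (the source toy data's n
and noise are unstated; these give realistically noisy estimates), with
n = 20,000 used where parameter recovery to ±0.05 is asserted.

## Measurement statistics

The ISAK ≥5% repeat criterion is evaluated as |m₁ − m₂|/mean(m₁, m₂)
(the defining document does not fix the denominator).  The ICC variant is
two-way random, absolute agreement, single measure — ICC(2,1) — with the
average-measures ICC(2,k) available; the choice matters little at the
near-unity reliabilities typical of bioimpedance repeats.  Bland–Altman
limits of agreement use the conventional 1.96 multiplier.

## Problem sizes and tolerances

Default test and acceptance problem sizes are chosen as the smallest that
make each property sharp: leave-one-out comparisons use 60 identities at
the `small` preset; generator calibration uses n = 50,000 (correlation
tolerance ±0.01); scenario recovery uses n = 20,000 (coefficient tolerance
±0.05); the DL Monte Carlo uses the full 10,000 resamples (5% agreement
with the closed form).  Exact linear-algebra identities are asserted at
1e-6 to 1e-12 depending on conditioning; stochastic assertions use fixed
seeds throughout.

## Known limitations

No nonlinear or per-segment composition→shape mappings; no non-rigid
registration or landmarking (meshes must arrive corresponded); no
age- or ancestry-specific deposition models; the synthetic base body is
deliberately schematic, not anatomical; Wilks' Λ is the only MANOVA
statistic provided (single-row contrasts make the alternatives
equivalent in the cases used here).
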