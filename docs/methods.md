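# Methods

This note documents the models implemented in `petquant`, the synthetic
data law that stands in for the animal study, the numerical choices, and
what the validation does and does not demonstrate.

## Acquisition model

All simulations use the study's 39-frame, 90-minute schedule (12 × 10 s,
3 × 20 s, 3 × 30 s, 3 × 60 s, 3 × 150 s, 15 × 300 s; 5400 s total).
Continuous curves live on a 1-s grid (bolus-resolution relative to the 10-s
early frames); frame values are exact trapezoid time-averages over each
frame interval. Activity is kBq/cm³, rate constants min⁻¹, V_T mL/cm³.

## Input function

The plasma input is a Feng-type tri-exponential bolus with appearance delay
t₀:

    Cp(t) = (A1·t' − A2 − A3)e^{−λ1 t'} + A2 e^{−λ2 t'} + A3 e^{−λ3 t'},  t' = t − t₀ > 0

with λ1 > λ2 > λ3 > 0; Cp ≡ 0 for t ≤ t₀, continuous at t₀ and non-negative
everywhere. Defaults (A1 = 300 kBq·mL⁻¹·min⁻¹, A2 = 6, A3 = 1 kBq/mL,
λ = 4, 0.5, 0.008 min⁻¹, t₀ = 0.5 min) give a ~31 kBq/mL peak at ~0.8 min
and a slowly decaying tail, typical of a mouse bolus injection. Whole blood
equals plasma throughout (ratio 1.0): the quantification convention applies
no plasma/whole-blood or radiometabolite correction, so the synthetic world
is generated under the same convention. Per-scan injected-dose variation is
modelled as a 5% log-normal amplitude jitter.

## Tissue forward model

The 2TCM response is computed analytically: with θ₁,₂ the eigenvalues of
the compartment matrix, C1 + C2 = K1/(θ₁−θ₂)·[(θ₁−k3−k4)e^{−θ₁t} +
(k3+k4−θ₂)e^{−θ₂t}] ⊗ Cp. Each exponential convolution is evaluated by the
exact first-order recursion for a piecewise-linear input (O(n), via an IIR
filter), which agrees with a stiff ODE oracle to ~1e-7 relative error.
Near-coincident eigenvalues (k2+k3 ≈ k4 with k3·k4 → 0) are evaluated by a
symmetric eigenvalue split of 5e-7·θ, a smooth-limit approximation with
O(1e-12) relative error.

## Noise model

Framed count-statistics noise: zero-mean Gaussian with per-frame
SD = noise_scale · sqrt(max(C, 0.1 kBq/cm³) / Δt_min) — variance
proportional to activity and inversely proportional to frame duration, the
standard approximation for decay-corrected framed PET (no decay term, since
decay correction is assumed applied). Negative noisy values are retained
for fitting realism. Defaults: noise_scale 0.1 for cohort TACs ("default
noise"), 0.05 for estimator-agreement studies ("low noise"), 0.5 per voxel
in the phantom (region averages then see ~0.5/√n_voxels). The framed input
curve receives half the regional noise scale, reflecting the high counts of
the blood pool.

## Micro-parameter ranges

Only V_T is constrained by the study's results, so cohort kinetics are
sampled as K1 ∈ [0.2, 0.8] mL·cm⁻³·min⁻¹, k3/k4 ∈ [0.5, 4], k4 ∈ [0.05,
0.2] min⁻¹, with k2 solved exactly from the target V_T (accepted when k2 ∈
[0.01, 2]). The k4 floor of 0.05 min⁻¹ keeps the bound compartment
equilibrating within the 90-minute scan (half-time ≤ ~14 min). This is a
deliberate restriction: with k4 → 0.02 the Logan plot is still curved at
the end of the scan and its V_T is biased low by up to ~7% even without
noise, which contradicts the design requirement that the generator's
configured means be recoverable (and is inconsistent with a tracer whose
empirical t* falls at 12.5–30 min). Within the adopted ranges the worst
noiseless Logan bias is ~1.6%.

## Cohort truth tables

The cohort generator draws each subject's regional V_T from
Normal(group mean, group SD) truncated positive. Cerebellum (all ages) and
striatum (6 months) use the published group means and SDs; the remaining
cells (thalamus, motor cortex, hippocampus, pons; striatum at 12/16 months)
are plausible defaults chosen once to respect the qualitative pattern —
HET > WT outside striatum, a genotype-independent ~17% decline from 6 to 12
months, stability thereafter, pons lowest. Regional TACs are generated as
blood-free tissue curves (V_B = 0): the configured means are tissue V_T, so
Logan on the generated TACs recovers them directly. Blood-volume admixture
(V_B = 3.6%) is exercised where it belongs: in the estimator-agreement
simulations and the 2TCM fit convention. (Logan applied to a
blood-contaminated curve estimates ≈ (1−V_B)·V_T + V_B, a −3% distortion at
V_T ≈ 6.6 that would otherwise be conflated with estimator error.)

## Phantom

The digital phantom is a 40×40×30 grid of 0.776-mm isotropic voxels with
ellipsoidal cerebellum, striatum and pons compartments and a left-ventricle
blood-pool ellipsoid ≥ 3.5 mm across carrying the framed input function.
Without a seed, each region receives canonical well-conditioned kinetics
(K1 = 0.5, k3/k4 = 2, k4 = 0.1, k2 solved for the target V_T) so that
quantification examples are well-posed; with a seed, kinetics are sampled
from the documented ranges (used for the varied-kinetics IDIF cohort). The
phantom deliberately omits scanner physics — no attenuation, scatter,
randoms, resolution modelling or motion — so IDIF and parametric-map tests
isolate the extraction and estimation logic, not reconstruction effects.

## IDIF extraction

A 3.5-mm-diameter sphere is centred on the operator hint; among frames with
midpoints in the first 2 minutes, the frame with maximal in-sphere mean is
found; voxels at or above 50% of that frame's in-sphere maximum form the
fixed extraction volume, whose per-frame mean (a design decision; the
alternative is the per-frame maximum) is the IDIF. The 2-minute early
window operationalizes "early frame of maximal activity" and avoids
late-frame spillover. An in-sphere peak below 1 kBq/cm³ is treated as a
missed blood pool and raises an extraction failure.

## Regional and voxel-wise quantification

2TCM fitting uses frame-duration weights (w ∝ Δt), bounds [1e-4, 5] on the
rates (2 for k4), eight fixed starting points spanning the documented
ranges, and best-residual selection with ties broken toward the smallest
parameter norm; non-convergence of all starts is flagged, not raised. The
Logan tissue integral uses the exact frame-step running sum at midpoints;
the input integral is a fine-grid trapezoid. t* candidates are frame
midpoints only. SRTM2 scans a 64-point logarithmic k2a grid on
[0.006, 0.6] min⁻¹ followed by a deterministic bounded refinement between
the best point's neighbours; SRTM (three parameters, two linear
coefficients per k2a) is provided for first-pass k2′ estimation and flags
boundary optima or non-physical parameters as failures, mirroring the
study's reason for excluding it from the primary analysis. Group k2′ is the
arithmetic mean of first-pass estimates within genotype across regions.

Voxel-wise Logan maps default to a single global t* selected from the mean
TAC over quantified voxels (per-voxel t* is available but ~10³ times
slower); voxels outside the activity mask, with non-positive late-frame
values, or failing the criterion are NaN, never 0. Gaussian smoothing uses
σ = FWHM/2.3548 in voxel units with normalized masking so NaNs neither
spread nor bias neighbouring values.

## Cluster inference

Cluster-level p-values come from a group-label permutation null of the
maximum supra-threshold cluster extent rather than random-field theory: the
peak threshold (p = 0.05 uncorrected, one-sided) and the extent threshold
(100 voxels by default) are preserved, and the null maximum is taken over
both contrast directions, so reported p-values are familywise over
direction. The published "100 voxels (0.8 mm³)" pairing is internally
inconsistent with 0.776-mm voxels; extent in voxels is primary here and mm³
is reported from the actual voxel size. Connectivity is 26-neighbour.

## Mixed model

statsmodels' MixedLM (REML, random subject intercept) is reparametrized to
genotype × age cell means for contrast construction. Tukey-Kramer
adjustment uses the studentized-range distribution over the k = 6 cells
with a containment-style degrees-of-freedom approximation: n_subjects − 2
for between-subject (genotype-within-time) contrasts, N − n_subjects − 4
for within-subject contrasts, the smaller for crossed contrasts. This is a
pragmatic stand-in for a full Satterthwaite computation; its adequacy is
established by simulation (empirical familywise type-I error ~1–2% at
nominal 5% under the null — conservative, not anti-conservative), not by
decimal agreement with any particular software's p-values. Subjects with
missing observations enter with their available rows. Fits with one
observation per subject, vanishing random-intercept variance, or optimizer
non-convergence are flagged degenerate.

## In-vitro quantification

The standards calibration is a strictly monotone piecewise-linear
interpolant from grey intensity to kBq/mg; queries outside the calibrated
range clamp to the end values and can be flagged. Density conversion is
pmol/mg = (kBq/mg) / (GBq/µmol): the decay-corrected molar activity is a
single user-supplied effective value (exposure-time bookkeeping is out of
scope). Specific binding is TB − NB, replicate sections averaged. IHC
positivity is "at or darker than the threshold" (grey ≤ 170 of 255, DAB
convention); the generator and quantifier share this convention, which is
fixed by decision since positivity direction is not derivable from the
threshold value alone.

The synthetic section generator renders 16-bit TB/NB autoradiograms by
inverting the standards curve at the ROI's total activity (specific +
nonspecific floor of 0.4 kBq/mg), with mild grey noise confined to the
local linear segment so ROI means map through the piecewise-linear curve
without bias, and 8-bit IHC images with an exactly planted positive-pixel
fraction per ROI.

## Problem sizes and determinism

Validation runs at desk scale: 40-curve cohorts for estimator agreement,
20 phantom subjects for IDIF fidelity, n = 20 for group-mean recovery,
500-replicate nulls for the type-I-error studies (10 subjects/genotype for
the mixed model; 16³-ish grids, 8 + 8 maps, 99 permutations for cluster
inference). All generators and fits are deterministic given data, seed and
configuration (fixed multi-start set, fixed basis grid, seeded RNGs).

## Limitations

The synthetic world omits scanner physics, motion, partial-volume effects,
anatomical realism, spill-over into the blood pool, radiometabolites, and
plasma/whole-blood kinetics; passing its round trips demonstrates
correctness of the estimators and their documented biases under the stated
data law, not robustness to those real-data effects. The reference-region
bias reproduction is qualitative by construction: the published
reference-based percentages cannot be recomputed because the underlying
group means were not printed. Percent differences follow the summary-table
convention of one-decimal truncation toward zero, which is what the printed
percentages recompute under.
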