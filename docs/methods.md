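# Methods

`mionmap` re-implements, as a tested library, the analysis chain of an
auditory block-design fMRI experiment in anesthetized macaques that used a
blood-pool contrast agent (MION) and clustered sparse temporal sampling.
Because the package is exercised exclusively on synthetic data, this note
describes both the analysis model and the generator that stands in for the
scanner, and states explicitly what passing tests do and do not show about
real data.

## Acquisition model

One functional run is 48 cycles of a 3.5 s scanner-silent gap followed by a
cluster of 7 EPI volumes spaced 646 ms apart (336 volumes, 385.06 s).  The
run duration is derived from this schedule rather than from any rounded
description of it.  One block occupies each gap: 32 stimulus blocks (4 per
subcategory; 6 stimuli of 0.5 s with 50 ms inter-stimulus intervals, 3.25 s
total) and 16 silent blocks, in a seeded uniformly random order.  Stimulus
blocks start 100–250 ms (uniform jitter) after the end of the previous
acquisition cluster.  The stimulus catalog has 2 main categories (macaque
vocalizations, non-vocal sounds) × 4 subcategories × 6 stimuli = 48 items;
stimuli exist only as labels and timings, no audio is handled.

## Hemodynamic model

MION makes activation *decrease* the measured signal.  The impulse response
is a sign-flipped gamma-variate kernel

    h(t) = −c (t/θ)^(k−1) e^(−t/θ)

with defaults k = 3, θ = 4 s (time-to-peak (k−1)θ = 8 s), 60 s support,
10 ms sampling, unit-peak normalization.  The form guarantees a single
extremum, no undershoot and a long tail; the exact parameters of the
original study's hand-designed response are unpublished, so these defaults
are a stated convention, not a reconstruction.  Because the reversal is
baked into the kernel, all downstream effects and t statistics are in
*neural* polarity (activation positive).

Task regressors are condition boxcars convolved with h on a fine grid and
evaluated at the non-uniform acquisition timestamps.  Boxcar edges are
coverage-weighted (fractional occupancy of grid cells), which makes
regressors second-order accurate in the grid step; halving the 10 ms step
changes them by < 1e−4.

## Synthetic data generator

The phantom is a 24×24×18 voxel grid at 1.5 mm isotropic: a gray-matter
interior with white-matter and CSF slabs (each ≥ 3 voxels thick so a 3 mm
erosion survives) and six bilateral spherical regions: A1-like and MGB-like
and IC-like (responding +1% signal change to every subcategory), F5-like
(+0.5% to vocalizations, −0.5% to non-vocal sounds), pMTG-like (±0.4%), and
an aTVA-like label with a weak unselective +0.2% response (vocalization
selectivity there is absent under anesthesia; the label exists mainly as an
anatomical placeholder).

Per voxel the generated signal is

    y(t) = B (1 + Σ_c a_c r_c(t)) + drift(t) + AR(1) noise + nuisance

with baseline B = 1000 arbitrary units, amplitudes a_c as fractions of
baseline, cubic Legendre drift (default coefficients (0, 0.2, −0.1, 0.05)
percent), stationary AR(1) noise (ρ = 0.3, innovation scaled to a 0.5%
marginal sd — a plausible thermal-noise level for a 1.5 mm voxel at 3 T),
and slowly varying latent nuisance time courses (AR(0.8), 1.5% sd, two per
compartment) with random loadings inside the white/CSF compartments.

By default nuisance loadings are zero outside white/CSF.  A configurable
`nuisance_gray_leak` (default 0) lets the same latents bleed into gray
matter; the component-count selection study uses a positive leak because
the compartment-PCA method presupposes physiological noise that is brain
wide but *measurable* in white/CSF — with strictly compartment-confined
nuisance, modeling its components cannot change gray-matter statistics and
the count search has nothing to find.

What the generator does **not** emulate: head motion, field inhomogeneity
and distortion, multiband reconstruction artifacts, spatially varying
baseline intensity, vascular and laminar structure, non-Gaussian physiology
(cardiac/respiratory quasi-periodicity), or registration error (data are
generated pre-aligned).  Passing tests therefore show the *estimators* are
correct and calibrated under the stated model, not that the pipeline is
robust to real-world artifacts — the preprocessing stages that handle those
(motion correction, unwarping, registration) are deliberately out of scope.

One global seed expands into per-subject and per-run sub-seeds through
`numpy.random.SeedSequence.spawn`, so any run can be regenerated in
isolation and cohorts are bit-reproducible.

## First-level model

Volumes are smoothed with a 3 mm FWHM Gaussian (twice the voxel size;
separable kernel, reflective boundary), then scaled to percent signal
change.  The percent reference is the *grand mean* over in-mask voxels and
volumes (one scalar per run).  A per-voxel temporal-mean reference is
available, but with 32 of 48 blocks containing sound and a long-tailed
response the task contributes several percent of each task voxel's own
temporal mean, compressing effect estimates by ~4–5%; the global reference
leaves them unbiased on the phantom's uniform baseline.  On real data with
heterogeneous baselines the voxelwise option trades that bias for local
interpretability — the choice is a config switch.

The GLM has one regressor per condition (either the 2 main categories for
the headline contrasts or all 8 subcategories for ROI profiles — two
separate fits, since a single model cannot serve both without ambiguity),
orthonormal polynomial drift of order 3 (cubic, the convention of the GLM
package family this design follows), and the nuisance components below.
Serial correlation is handled by two-pass AR(1) prewhitening: OLS, lag-1
coefficient from residuals, optional 3 mm spatial regularization of the
coefficient map, exact AR(1) whitening (first row scaled by √(1−ρ²)),
refit.  Voxels are grouped into ρ bins of 0.01 so each bin shares a
whitened design; df = n_volumes − n_columns.

Contrasts: Sound-vs-Silence is the mean of all sound columns against the
implicit silence baseline; Macaque-vs-NonVocal is mean(vocal) −
mean(non-vocal).  Runs are pooled within subject by fixed-effects
inverse-variance weighting (effect = Σe/s² / Σ1/s², sd = (Σ1/s²)^(−1/2),
df summed), before any group analysis and before the jackknife.

## Nuisance regression

White-matter and CSF masks are eroded with a cubic element spanning 3 mm
center-to-center per axis (3×3×3 voxels at 1.5 mm; the interpretation of a
"3 mm cube" on a 1.5 mm grid is ambiguous between 2 and 3 voxels per side —
3 is chosen and configurable).  Per run, the top principal component time
courses of each eroded compartment enter that run's design as covariates of
no interest (per-run entry respects run-wise drift structure; components
are never concatenated across runs).  The number of components per
compartment is either fixed (default 6 white / 4 CSF, the study's reported
averages) or optimized per subject by refitting over a (k_white, k_csf)
grid and maximizing the whole-brain peak t of the subject-level
Sound-vs-Silence map, ties broken toward fewer components (smallest total,
then smallest k_white).  Optimizing a model on the statistic it will report
is mildly circular; the option exists because it mirrors the original
procedure, is documented as such, and can be disabled.

## Group maps and random-field inference

Fixed effects: inverse-variance pooling of subject maps (valid for the
sampled subjects).  Random effects: one-sample analysis of subject effect
maps, t = mean/(sd/√n), df = n−1, requiring n ≥ 3; zero between-subject
variance is capped with a warning rather than propagating infinities.
Variance-ratio regularization is not applied by default.

Smoothness is estimated from standardized residual images: the lag-one
spatial autocorrelation of the normalized residual field is inverted under
a Gaussian autocorrelation model (ρ(1) = exp(−1/4σ²)), per axis; a known
applied kernel can be declared instead.  Resel counts: R₃ =
volume/∏FWHM, R₁ and R₂ from Worsley-style lattice edge/face counts
scaled by FWHM, R₀ = the mask's Euler characteristic.

The peak threshold t* solves E[EC(t)] = Σ_d R_d ρ_d(t) = α using the
Euler-characteristic densities of a t field in dimensions 0–3, by
bracketed root finding on the decreasing branch (cap configurable; maps
with df ≤ 4 skip peak thresholding with a warning).  Cluster inference
forms clusters at t_c, the upper-tail quantile at p = 0.001 in the
Gaussian limit (t_c = 3.09; a Student-t variant is available), labels them
with 6-connectivity by default (26 available), and computes the minimum
significant extent from the expected cluster count E[m] and expected
suprathreshold volume E[N]: P(size > k) ≈ exp(−βk^{2/3}) with
β = (Γ(5/2)·E[m]/E[N])^{2/3}, solving E[m]·P = α.  A cluster also survives
if it contains a voxel above t* (peak-OR-cluster decision).  The published
family-wise level (p < 0.05) and the cluster-forming rule (p = 0.001,
t = 3.09) are separate configuration keys.

Calibration measured by the package's own studies (seeded, desk scale):
voxelwise type-I error of the random-effects t at nominal 0.05 over 500
null cohorts of 11 subjects; family-wise error of the peak threshold over
500 smooth null t fields (df = 100, 15³-voxel search region at FWHM = 3
voxels, R₃ ≈ 125).  For the FWE study the field maximum is taken on a
3× spline-upsampled field, because the theory concerns the continuous
maximum and a coarse lattice misses inter-voxel peaks; smoothness is
estimated from an independent calibration stack rather than declared.
Random-field thresholds are expected to be mildly conservative at these
smoothness levels.

## Jackknife run selection

For each subject the whole-brain maximum t of Macaque-vs-NonVocal is
computed from all runs (T_all) and from each leave-one-run-out subset
(T₋ᵣ), using the subject-level fixed-effects combination each time (n+1
combinations for n runs).  A run is kept iff T₋ᵣ < T_all, strictly: the
procedure's stated rule makes a tie a drop, and the tie case is reachable
(a run carrying no finite weight leaves the maximum exactly unchanged).
The "whole brain" is the phantom's gray-matter-plus-regions mask by
configuration.  Selection is a single pass; group maps are then recomputed
from the selected runs.

## ROIs and profiles

Sphere ROIs use the voxel-center Euclidean inclusion rule; a 4.5 mm
diameter on the 1.5 mm grid gives exactly 19 voxels.  A1 ROIs are
per-subject intersections of the A1-like label with the subject's
significant Sound-vs-Silence voxels (t ≥ 3.09 by default); IC spheres sit
at the random-effects Sound-vs-Silence peak inside the IC-like label;
F5/pMTG spheres at the fixed-effects Macaque-vs-NonVocal peaks inside their
labels; aTVA spheres at configured (default: label-centroid) coordinates.
Bilateral regions are stored and reported as separate L/R ROIs.  Profile
extraction takes the *mean* t over ROI voxels per subcategory (peak t is a
config alternative), and group summaries report mean ± SEM across subjects
(SEM = sd/√n, requiring n ≥ 2).

## Numerical choices and degenerate inputs

* Rank deficiency of a design matrix is detected by pivoted QR and reported
  with the names of the dependent columns.
* AR coefficients are clipped to |ρ| ≤ 0.98; ρ binning at 0.01 bounds the
  whitening approximation error well below estimation noise.
* Voxels with invalid or zero sd are excluded from inverse-variance sums;
  voxels with no valid contribution are NaN, and background voxels stay
  exactly zero through percent scaling.
* Erosion of a structure thinner than the element yields an empty mask with
  a logged warning (the pipeline then disables compartment PCA rather than
  failing).
* An empty suprathreshold set is a valid empty cluster table, not an error.

## Problem sizes

The simulation studies use deliberately small cohorts (2–3 subjects, 2
runs, the 24×24×18 or 16×16×12 phantom) chosen as the smallest sizes at
which the measured quantities are stable; the full default pipeline
configuration (11 subjects, run counts drawn with median 12) reproduces the
study's cohort shape and can be run from the CLI.

## Known limitations

* The response-function parameters, drift order and AR order of the
  original analysis are unpublished; all are conventions exposed in the
  configuration.
* Smoothness estimation assumes a stationary Gaussian autocorrelation;
  resel counts use the voxel-count volume, which slightly overstates the
  continuous search volume of small masks.
* The component-count search optimizes the statistic it reports (see
  above); fixed counts are the default.
* Percent scaling by the grand mean is exactly interpretable only for a
  spatially uniform baseline (true on the phantom, approximate on real
  data).
* With very few subjects (df ≤ 4) random-effects maps receive only
  cluster-extent correction.
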