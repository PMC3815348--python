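# Methods

## Paradigm and rating model

The event-related design consists of contiguous 8 s trials: a 500 ms cue,
a cue-to-target interval drawn uniformly from 1.5–3.5 s (continuous, not
discretized — the acquisition literature the design follows does not state
discrete steps), a 1 s imperative stimulus for non-empty trials, and a
filler interval completing the slot. Two synonymous cues per task
de-confound task switching from cue switching; "empty" trials (default
fraction 1/8, a configurable choice since no canonical value exists) show
the cue word only. Trial sequences and cue-synonym assignments are drawn
uniformly at random under a seed; the original counterbalanced sequences
were produced by an external tool and are not reproducible, so no attempt
is made to match them.

Run-boundary ratings are modeled as seven values per scale (pre-run-1 and
post-run-i for i = 1..6), with the post-run-i and pre-run-(i+1) value being
one and the same boundary. Interpolation to per-event amplitudes is linear
in the event's *temporal* position within the run's task period
(trials_per_run × 8 s), not in trial index, and scaling is exact division by
100. Empty trials receive amplitudes like any other trial and enter the
unit regressor: every trial presents a cue and therefore evokes a response.

## Hemodynamic model and design matrix

The kernel is a single delayed Gamma, h(t) = ((t/(p·q))^p)·e^{p−t/q}, with
shape p = 8.6 and time scale q = 0.547 s (peak at ≈ 4.7 s), normalized to
unit peak and sampled at 0.1 s or finer. Events are impulses at trial onset
(not 8 s boxcars): the deconvolution framing treats each trial as an event.
Regressors are built per run by convolving impulse trains on the fine grid
and sampling at the retained volumes' acquisition times; the first retained
volume of each run defines t = 0 for that run's trials (the discarded
initial volumes cover the pre-task instruction period). One unit-amplitude
column is shared by all trials; per-condition unit columns were considered
and rejected because the single shared column is what the modeling
description implies. AMR impulse heights are the raw scaled amplitudes by
default; per-run mean-centering is available as a switch but changes the
unit column's interpretation, so it is off by default.

### Identifiability of the seven-regressor model

Each AMR column restricted to run r is pre_r·u_r + (post_r − pre_r)·v_r,
where u_r is the run's unit response and v_r its onset-ramp response. All
per-run coordinates of an AMR are linear in its n_runs + 1 boundary
ratings, so the seven task columns live in a shared subspace of dimension
n_runs + 1. Consequences, both verified by the test suite:

* with fewer than six runs the seven-column model is exactly rank
  deficient — six runs is the minimum identifiable design;
* at exactly six runs there are zero spare dimensions: the precision of the
  fatigue beta is governed by the conditioning of the 7 × 7 matrix of
  boundary-rating vectors, which for smooth, similar rating trajectories is
  poor and heavy-tailed across subjects. Single-subject fatigue-beta noise
  is therefore several times the volume-level noise, occasionally much
  more.

This is a property of the method being implemented, not of this
implementation. The pipeline mitigates it at the group stage by smoothing
subject-level beta maps (default 6 mm FWHM, ≈ 2 voxels) before the
two-sample comparison — standard practice in group fMRI — which also makes
the group map's noise smoothness match the cluster-calibration FWHM.
Pre-GLM smoothing of the BOLD series is a separate option, off by default.

## Detrending and fitting

Linear trends are removed per voxel and per run by OLS projection (mean
included; the residual series has zero mean per run). The GLM optionally
carries per-run intercept and linear drift columns; the experiment driver
enables them. Fitting is vectorized OLS; out-of-mask voxels carry NaN (the
field's conventional missing value), while in-mask voxels whose residual
variance is at floating-point cancellation level (an exactly-modeled
series) are flagged invalid with a zero statistic rather than propagating
NaN or ±inf. Contrast t maps use t = cᵀβ̂ / √(σ̂²·cᵀ(XᵀX)⁻¹c) with
df = n − rank(X). The group comparison regresses subject maps on
[intercept, group indicator, centered covariates]; without covariates this
is algebraically the pooled two-sample t (cross-checked against scipy), and
df = n₁ + n₂ − 2 − n_covariates. No autocorrelation (prewhitening),
motion, or physiological-noise modeling is performed; these are documented
simplifications relative to scanner pipelines.

## Cluster-extent inference

Null calibration simulates white Gaussian fields on the analysis grid,
smooths to a stated FWHM, standardizes within the mask, thresholds at the
normal quantile for the voxel p (|z| ≥ z_{1−p/2} when two-sided, tails
clustered separately), and records the maximum cluster size; k_α is the
smallest extent whose empirical exceedance probability is ≤ α. Application
converts voxel p to a t threshold using the map's df, retains ties at the
threshold (≥), removes clusters below k, and reports positive and negative
clusters separately. The default contiguity is the 26-neighborhood
(faces+edges+corners), configurable; calibration and application always
share one setting. The noise smoothness (mm FWHM) is a required input
because it is a property of the data — the published 66/33/38-voxel
thresholds for the original acquisition grid are not recoverable without
the (unstated) smoothness estimate, so the package calibrates afresh for
whatever grid, mask and smoothness it is given. ROI-restricted analyses
re-run the calibration with the ROI as mask; a smaller search volume yields
a smaller k. Cluster tables report 0-based voxel indices plus world (mm)
coordinates from the affine; standard-space coordinates are out of scope on
synthetic grids.

## Diffusion tensor and FA

The fit is ordinary log-linear least squares per voxel on
ln(S_i/S_0) = −b_i·g_iᵀDg_i, with S_0 the mean of all b = 0 volumes
(the emulated acquisition averages seven). A signal-weighted (WLS) variant
is available. Non-positive signals are clamped to 1e-6·S_0 and the voxel
flagged; negative eigenvalues are clamped to zero with a flag, never
silently dropped. FA uses the closed form on sorted eigenvalues and is 0
(flagged) where mean diffusivity is 0. Lesion handling removes the union of
all subjects' lesion masks from the analysis domain and reports the count.
The FA–fatigue regression is per-voxel OLS of FA on [intercept, FSS total,
age, education] within one group (df = n − 4); the FSS is stored as nine
1–7 items, and both the summed total (range 9–63) and the mean are exposed
— the total is the regression default because the emulated study reports
group scores on the summed scale. Skeleton-projection (TBSS-style) analysis
is deliberately replaced by voxelwise analysis on a common grid: skeleton
projection requires real anatomy and a published tool's internals.

## Synthetic cohorts

The generators are forward models of exactly the effects the pipeline
estimates, on a 24 × 24 × 16 grid at 3 mm (BOLD) and 16 × 16 × 10 (DWI) so
the full suite runs in minutes; the original acquisition grid
(64 × 64 × 32 at 3.438 × 3.438 × 4 mm) can be configured. Group sizes
default to 12 MS / 11 HC (BOLD) and 13 MS / 12 HC (DWI). Ratings follow
start + slope·t + jitter, clipped to [0, 100], with MS start/slope ranges
above control ranges (group offset without a strong time trend); the jitter
SD of 10 VAS points reflects the boundary-to-boundary variability of
momentary self-reports. BOLD series are baseline 100 + unit response +
effect×fatigue-AMR + per-voxel nuisance couplings to the other AMRs +
per-run linear drift + white Gaussian noise (SD 1, i.e. 1% of baseline).
The injected MS coupling defaults to 10 BOLD units per unit fatigue
amplitude — a deliberately strong, unambiguous ground truth (3–6% signal
excursion over the realized amplitude range) chosen so that detection is
limited by the method, not by the phantom, given the noise amplification
documented above. DWI signals follow S_0·e^{−b·gᵀDg} + Gaussian noise with
12 Fibonacci-hemisphere directions at b = 1000 s/mm² and 7 b = 0 volumes;
the tract region carries prolate tensors whose FA is
base (0.6) + slope·(FSS − reference), with the closed-form eigenvalue
parameterization λ1 = m(1+2δ), λ2 = λ3 = m(1−δ), δ = FA/√(3 − 2·FA²).
FSS items are drawn around group centers (MS 5.8, HC 2.0) with a
subject-level trait offset that reproduces group totals near 52 ± 11 (MS)
and 18 ± 7 (HC). Lesion masks are sparse random voxels outside the tract in
MS subjects.

What the generators do not emulate: anatomy, Rician noise, motion, eddy
currents, physiological confounds, spatial autocorrelation of BOLD noise,
and rating–behavior feedback. Passing tests therefore demonstrate the
correctness and calibration of the estimators under the stated noise model,
not robustness to real-scanner artifacts.

## Numerical choices and degenerate inputs

* Convolution grid step ≤ 0.1 s; onsets are snapped to the grid (< 50 ms).
* Rank checks use SVD with numpy's default tolerance; rank-deficiency
  errors name the most collinear column pair.
* Residual variance below 1e-24 of the mean squared signal is treated as
  exactly zero (degenerate voxel, flagged).
* Cluster labeling re-identifies components in lexicographic order of each
  cluster's first voxel, making reports deterministic.
* All randomness flows through `numpy.random.default_rng` seeds; drivers
  and generators are bit-reproducible given config + seed.

## Problem sizes used in validation

The validation suite runs the full-size default cohorts for the end-to-end
checks (23 BOLD subjects, 25 DWI subjects), 100 simulated subjects for the
fatigue-beta recovery at SNR 1, 200 eight-subject cohorts for the FA–FSS
slope recovery, 100 random 20³ fields for the flood-fill oracle, and
1000 + 500 Monte-Carlo iterations for the calibration validity check —
sizes chosen so the whole suite completes in a few minutes on one CPU while
keeping simulation standard errors well inside the asserted tolerances.
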