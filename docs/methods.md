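# Methods

This note documents the models, estimators and design choices behind
`freegaze`, in the order the pipeline runs them.

## Data model and screening

A recording is one participant × image exploration: a 4 s stream of
timestamped gaze positions at 500 Hz (2000 samples), in image-pixel
coordinates (0-based, origin top-left, x rightward, y downward). Samples
whose gaze fell off the image, or where the tracker lost the pupil, are
*retained* and flagged invalid rather than dropped, so the missing-data
fraction is always computable. A recording enters the analysis only if at
least 50% of its samples are valid (`validity_filter`); readers accept
durations of 3.9–4.1 s to tolerate file jitter. If binocular input is
supplied, the reader averages the valid eyes per sample — the
least-commitment merge into the single gaze stream the analysis assumes;
the interchange format itself is monocular.

Default geometry: 800×800 px stimuli subtending 19.6°×19.6° (≈40.6 px/°),
centered on a 1920×1080 screen.

## Calibration

Five targets (center, ±15° horizontal, ±8.5° vertical). Standard online
calibration fails with nystagmus, so calibration consumes manually selected
low-velocity windows of raw tracker data per target; window selection is an
input, not an automated step. The median raw position of each target's
windows is mapped to the target's pixel position by a full quadratic
polynomial per axis (6 coefficients over [1, u, v, uv, u², v²]). Features
are centered and scaled before the solve, and a tiny ridge penalty (1e-12)
selects the minimum-norm interpolant — on five points the quadratic is
otherwise rank-deficient. The penalty is small enough that a planted
affine-plus-mild-quadratic distortion is inverted to below 1e-6 px at the
targets. Calibration error is reported at the central target only, as the
distance (in degrees) between the calibrated median of a validation window
and the image center.

## Instantaneous velocity

The operator is a smoothed multi-sample central difference (see README for
the formula); the denominator 18 is the sum of the three index spans, so a
linear trajectory of slope *a* px/sample yields exactly *a*·SR/PPD °/s.
Samples whose ±4-sample neighbourhood touches an invalid sample — and the
first/last four of the trace — are flagged undefined and set to NaN, never
interpolated or zeroed: with nystagmus there is no principled interpolant.
Velocity is computed after calibration and before any gridding, with no
smoothing beyond the operator itself. Velocity-magnitude quantile
partitions (default 10 bins) break ties by stable sample order, making bin
sizes deterministic and near-equal (±1).

## Exploration entropy

Valid samples are counted on a 20×20 grid of half-open cells tiling the
image exactly (terminal edges fold into the last cell). The statistic is
plug-in Shannon entropy (base 2) divided by the Good–Turing coverage
estimate Ĉ = 1 − N₁/N, floored at 1/N so the all-singletons case stays
finite. Two choices deserve note:

* The division is applied to the *summed* entropy, not per cell: the
  coverage correction is a scalar adjustment for unobserved support; a
  per-summand division has no basis in the estimator literature.
* A "2° cell" on a 19.6° image cannot tile it with 20 cells; the cell
  *count* is treated as authoritative (40-px ≈ 0.98° cells), because the
  statistic depends on the number of cells, not their nominal label.
  Robustness grids are 40×40 ("1°") and 10×10 ("4°").

The correction vanishes as sampling grows (Ĉ→1), so corrected entropy
converges to plug-in entropy; this is asserted on a sample-size ladder in
the tests.

## Predictor maps

All maps are nonnegative, sum-normalized per-pixel matrices; every
constructor and transform re-asserts this. Convolutions use reflect
padding so no mass leaks across the border.

* **Empirical**: pixel-level valid-gaze counts pooled over the reference
  group's recordings of one image, smoothed with a unit-sum ("mass
  preserving") Gaussian of 2° FWHM (σ = FWHM/2.3548 · PPD), normalized.
  Counts are accumulated at pixel resolution — not gridded — and the
  excluded participant in leave-one-out mode contributes nothing, which is
  tested by perturbation.
* **Contrast**: Gaussian-weighted local standard deviation of intensity
  (window σ = 1° by default), then the standard FWHM smoothing. This is a
  deliberately simple low-level model: local luminance contrast correlates
  strongly with other low-level features and performs comparably to richer
  low-level models. A constant image has zero contrast; the map falls back
  to uniform and says so in its provenance.
* **External**: maps computed by other systems (e.g. deep-network saliency)
  are ingested from image files or text grids, validated for size and
  nonnegativity, and normalized. The pipeline itself never trains or runs a
  network.
* **Low-pass variants**: the stimulus is blurred by a Gaussian whose
  modulation transfer equals 0.67 at spatial frequency 1/cutoff cycles/°,
  i.e. σ_deg = cutoff·sqrt(ln(1/0.67))/(π·√2), for cutoffs 0.5/1/2°. The
  0.67 figure is read as amplitude attenuation at the cutoff — the only
  reading that pins down a concrete kernel.

## AUC

Gazed values are the map values at a participant's valid gaze pixels
(nearest-pixel lookup — the maps are already smoothed at 2° FWHM, so
interpolation would add nothing). Nongazed values are map values at
locations the *same participant* gazed on *other images*: any spatial bias
shared across images — the center bias of viewers and of photographic
composition alike — enters both classes equally and cancels. The nongazed
draw is uniform without replacement, matched in size to the gazed sample
(balanced classes; the U construction is size-agnostic but balance
simplifies its null), falling back to with-replacement (flagged) only when
the pool is smaller. Ties get midranks.

Each (participant, image, partition, seed) triple owns one reproducible
RNG stream, and the drawn *locations* are reused across predictor
families, so comparisons between families (and their AUC ratio) are paired
on the same null sample.

Decompositions:

* **Shuffled control**: image→map assignment is a seed-controlled
  derangement (Sattolo cycle; no image keeps its own map). Expected AUC
  0.5 when the measure is image-specific.
* **Time bins**: eight nonoverlapping 500 ms intervals. The nongazed pool
  is restricted to the *matching interval* of the other images; without
  interval matching, the enforced central start would make the first
  interval trivially classifiable rather than a true chance control.
* **Velocity bins**: ten participant-specific quantiles of velocity
  magnitude, pooled across that participant's recordings; only the gazed
  side is restricted (velocity is undefined for nongazed locations).

Participants with fewer than two images are skipped with a warning — their
nongazed pool is undefined.

## Repetition analysis

Entropies are joined to the trial design; a pair with either member
discarded by the validity filter is excluded entirely, since a
first-vs-second contrast is undefined for half-pairs. The order effect is
estimated per pair type by a linear mixed model (entropy ~ image order,
with group when several are present, participant random intercept).

## Group statistics

* Robust contrasts: IRLS with the bisquare weight function, tuning
  constant 4.685 (95% Gaussian efficiency — the conventional default).
  All pairwise group contrasts are tested at the family alpha divided by
  the number of pairs (0.05/6 for four groups). If the fit is exact the
  robust scale degenerates and the OLS solution is reported (the two
  estimators coincide in that limit).
* Mixed models: REML random-intercept fits. The backend provides no
  Satterthwaite denominator degrees of freedom; p-values therefore use a
  residual-df t reference, recorded as `df_method="residual"` in the
  result. Singular random-effect fits are flagged and reported from a
  fixed-effects-only refit.
* Recognition: binomial-logit models of per-image naming correctness with
  participant-level predictors (logMAR acuity, AUC) — image-level
  modelling keeps all information while the predictors vary only between
  participants. Three fits (each predictor alone, both) are compared by
  AIC and Tjur's discrimination index; perfect separation is flagged and
  refit with a weak L2 penalty.
* Correlations: product-moment r; two correlations are compared on the
  Fisher z scale with the independent-sample standard error.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the conditions every
downstream test runs under.

**Stimuli.** Each image is a textured object region on a low-contrast
background; its ground-truth attention map is a mixture of 2–5 isotropic
Gaussians (σ 0.8–1.8°) within ±3.5° of the image center, mirroring
photographs of centrally placed objects. 49 images in 7 categories by
default.

**Kinematics.** Gaze targets are drawn from map^(1/τ) (τ = 1 by default;
τ→0 collapses to the map mode), dwelled on for Normal(250, 80) ms
(floor 80 ms), joined by 60 ms linear transitions. Positional jitter is
temporally smoothed noise (Gaussian kernel, σ = 24 samples) scaled to 0.3°
× the dispersion factor — smooth enough that fixational velocity stays in
the physiological few-°/s range rather than the tens of °/s white noise
would produce. Nystagmus overlays a sawtooth on this trajectory: the slow
phase starts *on target* (the foveation period, velocity lowest right
after the corrective phase) and drifts away with exponentially growing
velocity (growth 6 s⁻¹), and the 20 ms fast phase snaps back. Horizontal
jerk: 5° amplitude at 4 Hz along x. Multiplanar-irregular: half amplitude,
with per-cycle random direction, ±30% period and amplitude jitter.
These defaults make median velocity magnitudes order as fixation <
multiplanar < jerk, the jerk waveform horizontally elongated
(h/v velocity-variance ratio > 3) and the multiplanar one not — the
qualitative group signatures the kinematic contrasts test for.

**Trials.** Two blocks × 14 trials: 7 same-image, 7 same-category, 14
different-category pairs, presented in participant-specific random order;
within non-identical pairs the presentation order is randomized across
participants, so image-level entropy differences cancel in the order
contrast. Every presentation starts with 500 ms anchored at the image
center (the inter-stimulus fixation dot), making first-interval AUC a true
chance control. Identical repeats redraw the second presentation's targets
from map^c (c = 2 by default), which narrows entropy specifically for
same-image pairs. Missing data are inserted as short invalid runs at an
*exact* per-recording rate (default 5%, within the 4–10% range typical of
such cohorts), so the 50% inclusion rule has a sharp boundary.

**Participants.** Default group sizes CC = 10, SC = 13, DC = 9, NC = 10
with multiplanar / fixation / fixation / jerk profiles respectively;
simulated logMAR acuity is uniform over 0–1.4. Recognition outcomes are
drawn from logistic(−4 − 2·logMAR + 9·AUC_truth), where AUC_truth is the
participant's AUC against the *ground-truth* maps — using the truth rather
than the estimated AUC keeps model-recovery tests non-circular.

**Determinism.** Every stream descends from `numpy` SeedSequences spawned
from the cohort seed; identical (spec, seed) reproduce sessions
bit-identically, and truth maps are identical whether or not pixels are
rendered.

**What the generator does not emulate.** Real images have structured,
semantically meaningful content; real nystagmus waveforms vary in shape
(pendular, jerk-with-extended-foveation) and interact with gaze direction;
blinks produce characteristic artifacts beyond missing runs; calibration
drift is not modelled. Passing tests therefore demonstrate that the
*estimators and contrasts* behave correctly under known ground truth — not
that any particular empirical effect size will be reproduced on human
data.

## Problem sizes and numerical choices

Chance-control and repetition analyses run on 12-participant, 28-trial
cohorts over 20 seeds — large enough that participant-mean AUCs are stable
to ±0.01 while a full run of the suite stays in the minutes range on one
CPU. Statistical-recovery suites use the smallest designs at which the
respective effects are near-ceiling (e.g. 8 per group for a 5·SD contrast,
6 per group × 7 intervals for slope signs). Grids, quantiles and ranks
break ties deterministically (half-open cells, stable sorts, midranks);
AUC endpoint identities (perfect separation = 1, identical multisets =
0.5) hold exactly, not approximately. Degenerate inputs — constant images,
zero-variance samples, singular mixed fits, separation in the logit model,
empty nongazed pools — are flagged or raised, never silently patched.

## Known limitations

* Mixed-model p-values use residual df, not Satterthwaite; for the
  balanced designs used here the difference is small, but exact df-method
  agreement with other tools should not be expected.
* The contrast map is a stand-in for trained low-level saliency models;
  externally computed maps should be supplied for fidelity runs.
* The calibration polynomial order (quadratic) is a convention; trackers
  differ, and the true mapping of a given device may need another order.
* Binocular merging by per-sample averaging of valid eyes is a choice;
  vergence-discrepant data would deserve a more careful rule.
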