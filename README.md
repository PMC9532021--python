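# freegaze

Free-viewing gaze analysis for cohorts that include nystagmus — tools for
asking *where* people look, *how stable* their gaze is, and *how well*
image-derived predictor maps explain their exploration, without ever
segmenting the data into fixations and saccades.

## The problem

Classic eye-tracking analyses reduce a recording to discrete fixations.
That breaks down for people with nystagmus (continuous, involuntary ocular
oscillation): there is no velocity threshold that separates "fixations"
from everything else. This package implements a sample-based alternative in
which every gaze sample enters the analysis, built around four statistics:

**Instantaneous gaze velocity.** A smoothed multi-sample central
difference, applied per axis:

    Velocity(n) = SR · (g(n+4) + g(n+3) + g(n+2) − g(n−2) − g(n−3) − g(n−4)) / (18 · PPD)

with SR the sampling rate (500 Hz), PPD pixels per degree (≈40.6), and 18
the sum of the index spans. On a linear trajectory of slope *a* px/sample it
returns exactly *a*·SR/PPD °/s.

**Coverage-corrected exploration entropy.** Valid samples are binned on a
20×20 grid over the image and summarized as

    H = −(Σᵢ pᵢ log₂ pᵢ) / Ĉ,     Ĉ = 1 − N₁/N,

where Ĉ is the Good–Turing coverage estimate (N₁ = singleton cells),
correcting the small-sample bias of plug-in entropy. Higher H = more
dispersed exploration.

**Predictor maps.** Per-pixel, sum-normalized maps that predict where gaze
lands: empirical gaze-density maps of a reference group (leave-one-out,
smoothed with a 2° FWHM Gaussian), local luminance-contrast maps, and
externally computed saliency maps; plus low-pass stimulus variants
(attenuation to 0.67 at cutoffs of 0.5/1/2 cycles-per-degree equivalents).

**Bias-controlled AUC.** How well map values classify gazed from nongazed
locations, scored by the Mann–Whitney construction

    U = R_gazed − n_gazed(n_gazed+1)/2,     AUC = U / (n_gazed · n_nongazed),

with the nongazed sample drawn from *the same participant's gaze on other
images* — cancelling center bias in both viewers and photographs. Controls
and decompositions: shuffled-image maps (derangement), eight 500 ms time
intervals with interval-matched nulls, and ten velocity-magnitude
quantiles.

On top of these sit the repetition analysis (entropy narrowing when an
image is shown twice), robust group contrasts (bisquare IRLS, Bonferroni
0.05/6), mixed-effects models with participant random intercepts, and a
binomial-logit model linking object recognition to visual acuity and AUC.

A first-class synthetic cohort generator produces stimuli, ground-truth
attention maps and gaze recordings with fixation–saccade, horizontal-jerk
or multiplanar-irregular kinematics, enforced central trial starts, exact
missing-data rates, and repeat-specific entropy narrowing — so the entire
pipeline is testable with no data download.

## Worked example

```python
import numpy as np
from freegaze import (map_driven_cohort, simulate_session,
                      auc_per_participant, shuffled_control,
                      entropy_from_recording)

cohort = map_driven_cohort(n_participants=4, seed=7)
session = simulate_session(cohort, pair_mix=(2, 2, 3))

maps = session.truth.maps
actual = auc_per_participant(maps, session.recordings, seed=0)
control = shuffled_control(maps, session.recordings, seed=0)
entropies = [entropy_from_recording(r) for r in session.recordings]

print("actual AUC  :", np.round([r.auc for r in actual], 3))
print("shuffled AUC:", np.round([r.auc for r in control], 3))
print("mean entropy: %.2f bits" % np.mean([e.H for e in entropies]))
```

Output:

```
actual AUC  : [0.662 0.674 0.682 0.667]
shuffled AUC: [0.478 0.463 0.472 0.453]
mean entropy: 4.31 bits
```

Gaze that is actually driven by each image's attention map is classified
well above chance (≈0.67), while the shuffled-image control collapses to
≈0.5 — the signature that the AUC measures image-specific structure, not a
shared spatial bias. Mean exploration entropy of ~4.3 bits corresponds to
an effective spread over ~20 of the 400 grid cells.

There is also a command-line interface (`freegaze simulate`, `freegaze
velocity`, `freegaze entropy`, `freegaze auc`, `freegaze repetition`,
`freegaze calibrate`, `freegaze pipeline run --config run.yaml`) operating
on plain TSV tables; see `docs/methods.md` for the model details and file
formats.

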