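"""Synthetic free-viewing cohort generator.

Generates grayscale stimuli with ground-truth attention maps and gaze
recordings carrying the statistical structure the analysis pipeline
assumes, so every stage is testable without any external download:

* **fixation_saccade** — dwell at saliency-driven targets with smooth,
  low-amplitude jitter, joined by brief high-velocity transitions (the
  kinematics of normally sighted viewers);
* **horizontal_jerk** — a sawtooth nystagmus waveform superimposed on the
  target trajectory: a slow drift phase (optionally accelerating) along the
  horizontal axis with a fast corrective phase, giving strongly
  horizontally elongated velocity distributions;
* **multiplanar_irregular** — a jerk-like waveform whose direction and
  amplitude vary cycle by cycle, giving directionally unstructured velocity
  distributions.

Targets are drawn from the image's ground-truth map sharpened by a
map-following temperature tau (p proportional to map^(1/tau)); repeated
images concentrate the second presentation's target distribution (map
raised to the power c >= 1), which narrows exploration entropy specifically
for identical repeats.  Every trial starts with an enforced central anchor
(the fixation dot precedes each image), and missing data are inserted at an
exact per-recording rate.

Default parameters mirror the study conditions: group sizes CC=10, SC=13,
DC=9, NC=10; 49 stimuli in 7 categories; two blocks of 14 trials with a
7 / 7 / 14 mix of same-image / same-category / different-category pairs;
500 Hz sampling, 4 s trials, 500 ms central start.  Nystagmus amplitudes
and frequencies are chosen so median velocity magnitudes order as
fixation < multiplanar < horizontal jerk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import expit

from .geometry import (
    CATEGORIES, GazeRecording, GeometrySpec, ImageStimulus, TrialPair,
)
from .maps import PredictorMap

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "SessionData",
    "generate_images",
    "simulate_recording",
    "simulate_session",
    "map_driven_cohort",
]

PROFILES = ("fixation_saccade", "horizontal_jerk", "multiplanar_irregular")

DEFAULT_GROUP_SIZES = {"CC": 10, "SC": 13, "DC": 9, "NC": 10}
DEFAULT_GROUP_PROFILES = {
    "CC": "multiplanar_irregular",
    "SC": "fixation_saccade",
    "DC": "fixation_saccade",
    "NC": "horizontal_jerk",
}

#: Trial design: (same_image, same_category, different_category) pair counts.
DEFAULT_PAIR_MIX = (7, 7, 14)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``tau`` is the map-following temperature (smaller = tighter adherence to
    the ground-truth map); ``repeat_concentration`` is the power c >= 1
    applied to the map for the second presentation of an identical repeat;
    ``dispersion`` scales the fixation jitter spread (the generator's
    spatial-dispersion dial for entropy calibration).
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    group_profiles: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROFILES))
    nystagmus_amplitude_deg: float = 5.0
    nystagmus_frequency_hz: float = 4.0
    slow_phase_acceleration: float = 6.0   # 1/s; 0 = linear slow phase
    fixation_duration_mean_ms: float = 250.0
    fixation_duration_sd_ms: float = 80.0
    saccade_duration_ms: float = 60.0
    tau: float = 1.0
    repeat_concentration: float = 2.0
    central_start_ms: float = 500.0
    missing_rate: float = 0.05
    jitter_deg: float = 0.3
    dispersion: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for g, prof in self.group_profiles.items():
            if prof not in PROFILES:
                raise ValueError(f"unknown kinematic profile {prof!r} for group {g}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.repeat_concentration < 1:
            raise ValueError("repeat_concentration must be >= 1")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth stored for every emitted recording."""

    maps: dict[str, PredictorMap]
    #: (participant, trial_index, presentation) -> (k, 2) target pixels
    target_sequences: dict[tuple[str, int, int], np.ndarray]
    #: (participant, trial_index) -> repeat narrowing applied to presentation 2
    repeat_applied: dict[tuple[str, int], bool]
    acuity_logmar: dict[str, float]
    truth_auc: dict[str, float]
    recognition_coefs: tuple[float, float, float]  # (intercept, acuity, auc)


@dataclass
class SessionData:
    """A complete simulated session: dataset plus its generating truth."""

    recordings: list[GazeRecording]
    pairs: list[TrialPair]
    images: list[ImageStimulus]
    truth: SyntheticTruth
    geometry: GeometrySpec
    cohort: CohortSpec


# ---------------------------------------------------------------------------
# Stimuli and ground-truth maps
# ---------------------------------------------------------------------------

def _truth_map_values(rng: np.random.Generator, geometry: GeometrySpec) -> np.ndarray:
    """Mixture of 2-5 isotropic Gaussians near the image center, sum 1."""
    w, h = geometry.image_size_px
    ppd = geometry.pixels_per_degree
    cx, cy = geometry.image_center_px
    k = int(rng.integers(2, 6))
    centers = np.column_stack([
        cx + rng.uniform(-3.5, 3.5, k) * ppd,
        cy + rng.uniform(-3.5, 3.5, k) * ppd,
    ])
    sigmas = rng.uniform(0.8, 1.8, k) * ppd
    weights = rng.dirichlet(np.ones(k))
    # separable evaluation in single precision keeps 49-map sets cheap;
    # the normalized result is promoted back to double
    xs = np.arange(w, dtype=np.float32)
    ys = np.arange(h, dtype=np.float32)
    out = np.zeros((h, w), dtype=np.float32)
    for (mx, my), s, wt in zip(centers, sigmas, weights):
        gx = np.exp(-0.5 * ((xs - np.float32(mx)) / np.float32(s)) ** 2)
        gy = np.exp(-0.5 * ((ys - np.float32(my)) / np.float32(s)) ** 2)
        out += np.float32(wt) * np.outer(gy, gx)
    out64 = out.astype(np.float64)
    return out64 / out64.sum()


def _render_pixels(
    rng: np.random.Generator, truth: np.ndarray, geometry: GeometrySpec
) -> np.ndarray:
    """Textured central object on a low-contrast background."""
    h, w = truth.shape
    mask = truth / truth.max()
    bg = gaussian_filter(rng.standard_normal((h, w)), sigma=12, mode="reflect")
    bg /= max(bg.std(), 1e-12)
    tex = gaussian_filter(rng.standard_normal((h, w)), sigma=2, mode="reflect")
    tex /= max(tex.std(), 1e-12)
    img = 0.5 + 0.02 * bg + mask * (0.12 * tex + 0.1)
    return np.clip(img, 0.0, 1.0)


def generate_images(
    n: int,
    categories: Sequence[str] = CATEGORIES,
    seed: int = 0,
    geometry: GeometrySpec | None = None,
    render_pixels: bool = True,
) -> tuple[list[ImageStimulus], list[PredictorMap]]:
    """Generate ``n`` stimuli with their ground-truth attention maps.

    Categories are assigned round-robin.  With ``render_pixels=False`` the
    stimuli carry a flat placeholder raster (map-only use); the truth maps
    are bit-identical either way for the same seed.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    geometry = geometry or GeometrySpec()
    images, truth_maps = [], []
    for i in range(n):
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(1, i))
        map_rng, pix_rng = [np.random.default_rng(c) for c in ss.spawn(2)]
        category = categories[i % len(categories)]
        image_id = f"img{i:03d}_{category}"
        values = _truth_map_values(map_rng, geometry)
        truth_maps.append(PredictorMap(values=values, provenance="synthetic_truth",
                                       image_id=image_id))
        if render_pixels:
            pixels = _render_pixels(pix_rng, values, geometry)
        else:
            w, h = geometry.image_size_px
            pixels = np.full((h, w), 0.5)
        images.append(ImageStimulus(image_id=image_id, category=category,
                                    pixels=pixels))
    return images, truth_maps


# ---------------------------------------------------------------------------
# Gaze trace synthesis
# ---------------------------------------------------------------------------

def _map_cdf(values: np.ndarray, power: float) -> np.ndarray:
    flat = values.ravel()
    if power != 1.0:
        # normalize by the mode before exponentiation so extreme sharpening
        # powers (tau -> 0) cannot underflow the whole distribution
        flat = (flat / flat.max()) ** power
    cdf = np.cumsum(flat)
    return cdf / cdf[-1]


def _draw_targets(
    cdf: np.ndarray, shape: tuple[int, int], k: int, rng: np.random.Generator,
    argmax: bool = False,
) -> np.ndarray:
    if argmax:
        # tau -> 0 limit: deterministic mode of the map
        idx = np.full(k, int(np.argmax(np.diff(np.concatenate([[0.0], cdf])))))
    else:
        idx = np.searchsorted(cdf, rng.random(k), side="right")
        idx = np.minimum(idx, cdf.size - 1)
    iy, ix = np.unravel_index(idx, shape)
    return np.column_stack([ix, iy]).astype(float)


def _nystagmus_offsets(
    n: int, profile: str, spec: CohortSpec, geometry: GeometrySpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (dx, dy) pixel offsets of the nystagmus waveform."""
    sr = geometry.sampling_rate
    ppd = geometry.pixels_per_degree
    amp_px = spec.nystagmus_amplitude_deg * ppd
    fast_len = max(int(round(0.020 * sr)), 2)
    dx = np.zeros(n)
    dy = np.zeros(n)
    irregular = profile == "multiplanar_irregular"
    if irregular:
        amp_px *= 0.5
    pos = 0
    while pos < n:
        period = sr / spec.nystagmus_frequency_hz
        if irregular:
            period *= rng.uniform(0.7, 1.3)
        cyc_len = max(int(round(period)), fast_len + 4)
        slow_len = cyc_len - fast_len
        # foveation at cycle start: the slow phase begins on target (offset 0,
        # lowest velocity) and drifts away, optionally with exponentially
        # growing velocity; the fast corrective phase returns to the target
        t_slow = np.arange(slow_len) / max(slow_len - 1, 1)
        if spec.slow_phase_acceleration > 0:
            g = spec.slow_phase_acceleration * slow_len / sr
            t_slow = (np.exp(g * t_slow) - 1.0) / (np.exp(g) - 1.0)
        a = amp_px * (rng.uniform(0.7, 1.3) if irregular else 1.0)
        slow = a * t_slow
        fast = a * (1.0 - np.arange(1, fast_len + 1) / fast_len)
        wave = np.concatenate([slow, fast])
        theta = rng.uniform(0, 2 * np.pi) if irregular else 0.0
        seg = wave[: n - pos]
        dx[pos: pos + seg.size] += seg * np.cos(theta)
        dy[pos: pos + seg.size] += seg * np.sin(theta)
        pos += cyc_len
    return dx, dy


def _insert_missing(valid: np.ndarray, rate: float, rng: np.random.Generator) -> None:
    """Mark an exact count round(rate * n) of samples invalid, in short runs."""
    n = valid.size
    n_missing = int(round(rate * n))
    if n_missing == 0:
        return
    invalid = np.zeros(n, dtype=bool)
    guard = 0
    while invalid.sum() < n_missing and guard < 10_000:
        start = int(rng.integers(0, n))
        length = int(rng.integers(10, 80))
        invalid[start: start + length] = True
        guard += 1
    excess = int(invalid.sum()) - n_missing
    if excess > 0:
        on = np.flatnonzero(invalid)
        off = rng.choice(on, size=excess, replace=False)
        invalid[off] = False
    valid &= ~invalid


def _simulate_trace(
    map_values: np.ndarray,
    cdf: np.ndarray,
    profile: str,
    spec: CohortSpec,
    geometry: GeometrySpec,
    rng: np.random.Generator,
    duration_s: float = 4.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Return (x, y, valid, targets) for one exploration."""
    sr = geometry.sampling_rate
    ppd = geometry.pixels_per_degree
    n = int(round(duration_s * sr))
    cx, cy = geometry.image_center_px

    # fixation schedule after the central anchor
    central = int(round(spec.central_start_ms / 1000.0 * sr))
    central = min(central, n)
    durations = []
    total = 0
    while total < n - central:
        d = rng.normal(spec.fixation_duration_mean_ms, spec.fixation_duration_sd_ms)
        d = max(d, 80.0)
        ds = max(int(round(d / 1000.0 * sr)), 1)
        durations.append(ds)
        total += ds
    k = len(durations)
    targets = _draw_targets(cdf, map_values.shape, max(k, 1), rng,
                            argmax=spec.tau < 1e-3)

    x = np.empty(n)
    y = np.empty(n)
    x[:central] = cx
    y[:central] = cy
    sac = max(int(round(spec.saccade_duration_ms / 1000.0 * sr)), 1)
    pos = central
    prev = np.array([cx, cy], dtype=float)
    for tgt, dur in zip(targets, durations):
        if pos >= n:
            break
        trans = min(sac, dur, n - pos)
        ramp = np.linspace(0.0, 1.0, trans + 1)[1:]
        x[pos: pos + trans] = prev[0] + (tgt[0] - prev[0]) * ramp
        y[pos: pos + trans] = prev[1] + (tgt[1] - prev[1]) * ramp
        dwell = min(dur - trans, n - pos - trans)
        x[pos + trans: pos + trans + dwell] = tgt[0]
        y[pos + trans: pos + trans + dwell] = tgt[1]
        pos += trans + dwell
        prev = tgt
    if pos < n:
        x[pos:] = prev[0]
        y[pos:] = prev[1]

    # smooth positional jitter (temporally correlated, so velocities stay low)
    jit_px = spec.jitter_deg * spec.dispersion * ppd
    for axis in (x, y):
        noise = gaussian_filter1d(rng.standard_normal(n), sigma=24.0, mode="reflect")
        axis += jit_px * noise / max(noise.std(), 1e-12)

    if profile in ("horizontal_jerk", "multiplanar_irregular"):
        dx, dy = _nystagmus_offsets(n, profile, spec, geometry, rng)
        x += dx
        y += dy

    valid = np.ones(n, dtype=bool)
    _insert_missing(valid, spec.missing_rate, rng)
    return x, y, valid, targets[:k]


def simulate_recording(
    truth_map: PredictorMap,
    profile: str,
    spec: CohortSpec,
    geometry: GeometrySpec | None = None,
    seed: int = 0,
    duration_s: float = 4.0,
    repeat: bool = False,
    participant_id: str = "p00",
    group: str = "SC",
    image_id: str | None = None,
    trial_index: int = 1,
    block: int = 1,
    presentation: int = 1,
) -> tuple[GazeRecording, np.ndarray]:
    """Simulate one exploration of an image; returns the recording and the
    ground-truth target sequence.  ``repeat=True`` applies the repeat
    concentration (map^c) to the target distribution."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    geometry = geometry or GeometrySpec()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    power = (spec.repeat_concentration if repeat else 1.0) / spec.tau
    cdf = _map_cdf(truth_map.values, power)
    x, y, valid, targets = _simulate_trace(
        truth_map.values, cdf, profile, spec, geometry, rng, duration_s)
    rec = GazeRecording(
        participant_id=participant_id, group=group,
        image_id=image_id or truth_map.image_id,
        trial_index=trial_index, block=block,
        t=np.arange(len(x)) / geometry.sampling_rate,
        x=x, y=y, valid=valid, geometry=geometry, presentation=presentation,
    )
    rec.revalidate_bounds()
    return rec, targets


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def _design_layout(mix: tuple[int, int, int]) -> tuple[list[str], list[tuple[str, int, int]]]:
    """Category sequence and pair structure for a generated stimulus set.

    Returns ``(categories, pairs)`` where pairs hold (pair_type, i, j) image
    indices; categories are cycled so every same-category pair is feasible
    for any pair mix.
    """
    from itertools import cycle

    n_si, n_soc, n_doc = mix
    cyc = cycle(CATEGORIES)
    cats: list[str] = []
    pairs: list[tuple[str, int, int]] = []
    for _ in range(n_si):
        c = next(cyc)
        idx = len(cats)
        cats.append(c)
        pairs.append(("same_image", idx, idx))
    for _ in range(n_soc):
        c = next(cyc)
        idx = len(cats)
        cats.extend([c, c])
        pairs.append(("same_category", idx, idx + 1))
    for _ in range(n_doc):
        a, b = next(cyc), next(cyc)
        idx = len(cats)
        cats.extend([a, b])
        pairs.append(("different_category", idx, idx + 1))
    return cats, pairs


def _design_pairs(
    images: Sequence[ImageStimulus],
    mix: tuple[int, int, int],
    rng: np.random.Generator,
) -> list[tuple[str, str, str]]:
    """Assign images to trial pairs: (pair_type, first_id, second_id)."""
    n_si, n_soc, n_doc = mix
    need = n_si + 2 * n_soc + 2 * n_doc
    if len(images) < need:
        raise ValueError(f"design needs {need} images, got {len(images)}")
    by_cat: dict[str, list[str]] = {}
    for img in images:
        by_cat.setdefault(img.category, []).append(img.image_id)
    for ids in by_cat.values():
        rng.shuffle(ids)
    cats = sorted(by_cat)

    pairs: list[tuple[str, str, str]] = []
    for i in range(n_si):
        cat = cats[i % len(cats)]
        if not by_cat[cat]:
            cat = max(by_cat, key=lambda c: len(by_cat[c]))
        img = by_cat[cat].pop()
        pairs.append(("same_image", img, img))
    for i in range(n_soc):
        # pick the category with most remaining images to keep pairs feasible
        cat = max(by_cat, key=lambda c: len(by_cat[c]))
        if len(by_cat[cat]) < 2:
            raise ValueError("not enough same-category images for the design")
        a, b = by_cat[cat].pop(), by_cat[cat].pop()
        pairs.append(("same_category", a, b))
    for i in range(n_doc):
        ordered = sorted(by_cat, key=lambda c: -len(by_cat[c]))
        if len(ordered) < 2 or not by_cat[ordered[0]] or not by_cat[ordered[1]]:
            raise ValueError("not enough cross-category images for the design")
        a = by_cat[ordered[0]].pop()
        b = by_cat[ordered[1]].pop()
        pairs.append(("different_category", a, b))
    return pairs


def simulate_session(
    cohort: CohortSpec,
    images: Sequence[ImageStimulus] | None = None,
    truth_maps: Sequence[PredictorMap] | None = None,
    pair_mix: tuple[int, int, int] = DEFAULT_PAIR_MIX,
    n_blocks: int = 2,
    render_images: bool = False,
    recognition: bool = True,
) -> SessionData:
    """Simulate a complete session for every participant of the cohort.

    The trial design pairs images once at the cohort level (7 same-image,
    7 same-category, 14 different-category pairs by default) and presents
    the pairs in a participant-specific random order over ``n_blocks``
    blocks.  Identical repeats regenerate the second exploration with the
    concentration factor c.  Recognition outcomes are drawn per presentation
    from logistic(a0 + a*acuity + b*truth_auc), where truth_auc is each
    participant's AUC against the ground-truth maps (so model-recovery tests
    are not circular in the estimated AUC).
    """
    geometry = GeometrySpec()
    root = np.random.SeedSequence(entropy=int(cohort.seed), spawn_key=(0,))
    design_rng, acuity_rng, recog_rng = [
        np.random.default_rng(c) for c in root.spawn(3)
    ]

    if images is None or truth_maps is None:
        cats, idx_pairs = _design_layout(pair_mix)
        images, truth_maps = generate_images(
            len(cats), categories=cats, seed=cohort.seed, geometry=geometry,
            render_pixels=render_images,
        )
        pair_assign = [
            (pt, images[i].image_id, images[j].image_id)
            for pt, i, j in idx_pairs
        ]
    else:
        pair_assign = _design_pairs(images, pair_mix, design_rng)
    maps_by_id = {m.image_id: m for m in truth_maps}
    n_trials = len(pair_assign)
    trials_per_block = int(np.ceil(n_trials / n_blocks))

    participants: list[tuple[str, str]] = []  # (pid, group)
    for group in sorted(cohort.group_sizes):
        for j in range(cohort.group_sizes[group]):
            participants.append((f"{group}{j:02d}", group))

    cdf_cache: dict[tuple[str, float], np.ndarray] = {}

    def cdf_for(image_id: str, power: float) -> np.ndarray:
        key = (image_id, power)
        if key not in cdf_cache:
            cdf_cache[key] = _map_cdf(maps_by_id[image_id].values, power)
        return cdf_cache[key]

    recordings: list[GazeRecording] = []
    target_sequences: dict[tuple[str, int, int], np.ndarray] = {}
    repeat_applied: dict[tuple[str, int], bool] = {}
    acuity = {}
    trial_meta: list[tuple[str, int, int, str, str, str]] = []

    for p_idx, (pid, group) in enumerate(participants):
        profile = cohort.group_profiles[group]
        acuity[pid] = float(acuity_rng.uniform(0.0, 1.4))
        p_ss = np.random.SeedSequence(entropy=int(cohort.seed), spawn_key=(2, p_idx))
        order_rng = np.random.default_rng(p_ss)
        order = order_rng.permutation(n_trials)
        for t_pos, pair_idx in enumerate(order):
            pair_type, first_id, second_id = pair_assign[pair_idx]
            # within-pair presentation order is randomized across subjects for
            # non-identical pairs, so image-level entropy differences cancel
            # in the group-level order contrast
            if pair_type != "same_image" and order_rng.random() < 0.5:
                first_id, second_id = second_id, first_id
            trial_index = t_pos + 1
            block = t_pos // trials_per_block + 1
            trial_meta.append((pid, block, trial_index, pair_type, first_id, second_id))
            for pres, image_id in ((1, first_id), (2, second_id)):
                repeat = pair_type == "same_image" and pres == 2
                power = (cohort.repeat_concentration if repeat else 1.0) / cohort.tau
                rec_ss = np.random.SeedSequence(
                    entropy=int(cohort.seed), spawn_key=(3, p_idx, t_pos, pres))
                rec_rng = np.random.default_rng(rec_ss)
                pmap = maps_by_id[image_id]
                x, y, valid, targets = _simulate_trace(
                    pmap.values, cdf_for(image_id, power), profile, cohort,
                    geometry, rec_rng,
                )
                rec = GazeRecording(
                    participant_id=pid, group=group, image_id=image_id,
                    trial_index=trial_index, block=block,
                    t=np.arange(len(x)) / geometry.sampling_rate,
                    x=x, y=y, valid=valid, geometry=geometry,
                    presentation=pres,
                )
                rec.revalidate_bounds()
                recordings.append(rec)
                target_sequences[(pid, trial_index, pres)] = targets
            repeat_applied[(pid, trial_index)] = pair_type == "same_image"

    # recognition outcomes from the truth-map AUC (avoids circularity in the
    # estimated AUC used downstream)
    coefs = (-4.0, -2.0, 9.0)
    truth_auc: dict[str, float] = {}
    pairs: list[TrialPair] = []
    if recognition:
        from .auc import auc_per_participant
        results = auc_per_participant(
            maps_by_id, recordings, seed=int(cohort.seed) % (2 ** 31))
        truth_auc = {r.participant_id: r.auc for r in results}
    for (pid, block, trial_index, pair_type, first_id, second_id) in trial_meta:
        if recognition and pid in truth_auc:
            a0, a, b = coefs
            p_correct = float(expit(a0 + a * acuity[pid] + b * truth_auc[pid]))
            c1 = bool(recog_rng.random() < p_correct)
            c2 = bool(recog_rng.random() < p_correct)
        else:
            c1 = c2 = True
        pairs.append(TrialPair(
            participant_id=pid, block=block, trial_index=trial_index,
            pair_type=pair_type, first_image_id=first_id,
            second_image_id=second_id,
            named_first_correct=c1, named_second_correct=c2,
        ))

    truth = SyntheticTruth(
        maps=maps_by_id, target_sequences=target_sequences,
        repeat_applied=repeat_applied, acuity_logmar=acuity,
        truth_auc=truth_auc, recognition_coefs=coefs,
    )
    return SessionData(recordings=recordings, pairs=pairs, images=list(images),
                       truth=truth, geometry=geometry, cohort=cohort)


def map_driven_cohort(
    n_participants: int = 12,
    seed: int = 0,
    profile: str = "fixation_saccade",
    **overrides,
) -> CohortSpec:
    """A single-group, map-driven cohort (tau = 1) used for chance-control
    and calibration analyses: ``n_participants`` viewers with identical
    kinematics exploring the default 28-trial design."""
    return CohortSpec(
        group_sizes={"SC": n_participants},
        group_profiles={"SC": profile},
        seed=seed,
        **overrides,
    )
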