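"""Bias-controlled AUC classification of gazed versus nongazed locations.

A predictor map is scored by how well its values separate locations a
participant gazed at from locations they did not.  The nongazed sample is
drawn from the *same participant's gaze on other images*, which cancels both
the viewer's spatial bias (e.g. center bias) and photographic composition
bias: any tendency shared across images contributes equally to both classes.

Classification success is the rank-based AUC of the ROC curve, computed from
the Mann-Whitney U statistic with midranks for ties:

    U   = R_gazed - n_gazed (n_gazed + 1) / 2
    AUC = U / (n_gazed * n_nongazed)

where R_gazed is the sum of joint ranks of the gazed values (rank 1 =
smallest).  AUC ranges 0..1 with 0.5 = chance and 1 = perfect separation.

Decompositions: per-participant pooling (values pooled across images),
per-image pooling (across participants), a shuffled-image control in which
each image is scored with the map of a *different* image (derangement),
eight nonoverlapping 500 ms time intervals with interval-matched nongazed
pools, and ten participant-specific velocity-magnitude quantiles.

Nongazed pools are drawn once per (participant, image, partition, seed) and
reused across predictor families, so paired comparisons between families
share the same null sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .geometry import GazeRecording
from .kinematics import instantaneous_velocity
from .maps import PredictorMap

__all__ = [
    "AUCResult",
    "auc_from_values",
    "sample_gazed_values",
    "sample_nongazed_values",
    "auc_per_participant",
    "auc_per_image",
    "shuffled_control",
    "time_binned_auc",
    "velocity_binned_auc",
    "derangement",
]


@dataclass
class AUCResult:
    """One gazed/nongazed classification outcome."""

    auc: float
    U: float
    R_gazed: float
    n_gazed: int
    n_nongazed: int
    condition: str = "actual"            # actual | shuffled
    pooling: str = "per_participant"     # per_participant | per_image
    partition: str = "whole"             # whole | interval_k | velocity_qk
    provenance: str = ""
    participant_id: str = ""
    image_id: str = ""
    group: str = ""
    with_replacement: bool = False


def auc_from_values(gazed, nongazed, **meta) -> AUCResult:
    """Rank-based AUC of gazed vs nongazed predictor-map values.

    Joint midranks (ties averaged) are assigned across both samples, then
    the U statistic and AUC follow the formulas above.
    """
    gazed = np.asarray(gazed, dtype=float)
    nongazed = np.asarray(nongazed, dtype=float)
    if gazed.size == 0 or nongazed.size == 0:
        raise ValueError("gazed and nongazed value sets must be non-empty")
    ranks = rankdata(np.concatenate([gazed, nongazed]), method="average")
    n_g, n_ng = gazed.size, nongazed.size
    r_gazed = float(ranks[:n_g].sum())
    u = r_gazed - n_g * (n_g + 1) / 2.0
    return AUCResult(
        auc=u / (n_g * n_ng), U=u, R_gazed=r_gazed,
        n_gazed=n_g, n_nongazed=n_ng, **meta,
    )


def sample_gazed_values(pmap: PredictorMap, recording: GazeRecording) -> np.ndarray:
    """Map values at the recording's valid gaze locations (nearest pixel),
    in sample order.  Invalid samples contribute nothing."""
    x, y = recording.valid_xy()
    return pmap.value_at(x, y)


def sample_nongazed_values(
    pmap: PredictorMap,
    other_recordings: Sequence[GazeRecording],
    n_target: int,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, bool]:
    """Draw nongazed map values from gaze locations on *other* images.

    ``n_target`` locations are drawn uniformly without replacement from the
    pooled valid gaze locations of ``other_recordings``; if the pool is
    smaller than ``n_target`` the draw is with replacement and flagged.
    Returns ``(values, with_replacement)``.
    """
    xs, ys = [], []
    for rec in other_recordings:
        x, y = rec.valid_xy()
        xs.append(x)
        ys.append(y)
    if not xs or sum(len(x) for x in xs) == 0:
        raise ValueError("empty nongazed location pool")
    px = np.concatenate(xs)
    py = np.concatenate(ys)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    replace = px.size < n_target
    idx = rng.choice(px.size, size=n_target, replace=replace)
    return pmap.value_at(px[idx], py[idx]), bool(replace)


# ---------------------------------------------------------------------------
# Pooled dataset representation
# ---------------------------------------------------------------------------

@dataclass
class _ParticipantPool:
    participant_id: str
    group: str
    x: np.ndarray          # valid-sample pixel x, pooled over recordings
    y: np.ndarray
    image_idx: np.ndarray  # index into the dataset's sorted image-id list
    tbin: np.ndarray       # 0-based 500 ms interval of each sample
    vbin: np.ndarray       # velocity-quantile label (0 = unlabelled)
    image_ids: list[str]   # images this participant explored (sorted ids)


def _pool_participants(
    recordings: Sequence[GazeRecording],
    image_index: Mapping[str, int],
    bin_width_s: float = 0.5,
    velocity_bins: int = 0,
) -> dict[str, _ParticipantPool]:
    by_pid: dict[str, list[GazeRecording]] = {}
    for rec in recordings:
        by_pid.setdefault(rec.participant_id, []).append(rec)

    pools: dict[str, _ParticipantPool] = {}
    for pid, recs in by_pid.items():
        xs, ys, imgs, tbins, mags, defined = [], [], [], [], [], []
        for rec in recs:
            mask = rec.valid
            xs.append(rec.x[mask])
            ys.append(rec.y[mask])
            imgs.append(np.full(mask.sum(), image_index[rec.image_id], dtype=int))
            rel_t = rec.t - rec.t[0]
            tbins.append((rel_t[mask] / bin_width_s).astype(int))
            if velocity_bins:
                trace = instantaneous_velocity(rec)
                mags.append(trace.magnitude[mask])
                defined.append(trace.defined[mask])
        x = np.concatenate(xs)
        vbin = np.zeros(x.size, dtype=int)
        if velocity_bins:
            mag = np.concatenate(mags)
            dfn = np.concatenate(defined)
            idx = np.flatnonzero(dfn)
            m = idx.size
            if m < velocity_bins:
                raise ValueError(
                    f"participant {pid}: {m} defined velocity samples, "
                    f"need at least {velocity_bins}"
                )
            order = np.argsort(mag[idx], kind="stable")
            vbin[idx[order]] = np.arange(m) * velocity_bins // m + 1
        pools[pid] = _ParticipantPool(
            participant_id=pid,
            group=recs[0].group,
            x=x, y=np.concatenate(ys),
            image_idx=np.concatenate(imgs),
            tbin=np.concatenate(tbins),
            vbin=vbin,
            image_ids=sorted({r.image_id for r in recs}),
        )
    return pools


def _draw_rng(seed: int, p_idx: int, img_idx: int, partition_code: int) -> np.random.Generator:
    # one reproducible stream per (participant, image, partition, seed) so
    # the same nongazed draw is reused across predictor families
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(p_idx, img_idx, partition_code))
    return np.random.default_rng(ss)


def _participant_image_values(
    pool: _ParticipantPool,
    pmap: PredictorMap,
    img_idx: int,
    p_idx: int,
    seed: int,
    partition_code: int,
    sample_mask: np.ndarray | None = None,
    pool_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, bool] | None:
    """Gazed and nongazed values for one participant on one image.

    ``sample_mask`` restricts the gazed samples (e.g. to a time interval or
    velocity bin); ``pool_mask`` restricts the nongazed candidate pool.
    Returns None when either side is empty (missing entry, not zero).
    """
    gaze_sel = pool.image_idx == img_idx
    if sample_mask is not None:
        gaze_sel &= sample_mask
    n_gazed = int(gaze_sel.sum())
    if n_gazed == 0:
        return None
    pool_sel = pool.image_idx != img_idx
    if pool_mask is not None:
        pool_sel &= pool_mask
    pool_idx = np.flatnonzero(pool_sel)
    if pool_idx.size == 0:
        return None
    rng = _draw_rng(seed, p_idx, img_idx, partition_code)
    replace = pool_idx.size < n_gazed
    chosen = rng.choice(pool_idx, size=n_gazed, replace=replace)
    gazed = pmap.value_at(pool.x[gaze_sel], pool.y[gaze_sel])
    nongazed = pmap.value_at(pool.x[chosen], pool.y[chosen])
    return gazed, nongazed, bool(replace)


def _resolve_map(
    maps: Mapping[str, PredictorMap],
    image_id: str,
    assignment: Mapping[str, str] | None,
) -> PredictorMap:
    return maps[assignment[image_id] if assignment is not None else image_id]


def _dataset_index(recordings: Sequence[GazeRecording]) -> tuple[list[str], dict[str, int]]:
    image_ids = sorted({r.image_id for r in recordings})
    return image_ids, {img: i for i, img in enumerate(image_ids)}


def auc_per_participant(
    maps: Mapping[str, PredictorMap],
    recordings: Sequence[GazeRecording],
    seed: int,
    condition: str = "actual",
    assignment: Mapping[str, str] | None = None,
) -> list[AUCResult]:
    """One AUC per participant, with gazed/nongazed values pooled across the
    participant's images (each image scored against its own map).

    Participants with fewer than two images are skipped with a warning (the
    nongazed pool would be undefined).
    """
    image_ids, image_index = _dataset_index(recordings)
    pools = _pool_participants(recordings, image_index)
    results = []
    for p_idx, pid in enumerate(sorted(pools)):
        pool = pools[pid]
        if len(pool.image_ids) < 2:
            warnings.warn(f"participant {pid} has <2 images; skipped")
            continue
        gazed_all, nongazed_all = [], []
        any_replace = False
        provenance = ""
        for image_id in pool.image_ids:
            pmap = _resolve_map(maps, image_id, assignment)
            provenance = pmap.provenance
            out = _participant_image_values(
                pool, pmap, image_index[image_id], p_idx, seed, partition_code=0
            )
            if out is None:
                continue
            g, ng, rep = out
            gazed_all.append(g)
            nongazed_all.append(ng)
            any_replace |= rep
        results.append(auc_from_values(
            np.concatenate(gazed_all), np.concatenate(nongazed_all),
            condition=condition, pooling="per_participant", partition="whole",
            provenance=provenance, participant_id=pid, group=pool.group,
            with_replacement=any_replace,
        ))
    return results


def auc_per_image(
    maps: Mapping[str, PredictorMap],
    recordings: Sequence[GazeRecording],
    seed: int,
    condition: str = "actual",
    assignment: Mapping[str, str] | None = None,
) -> list[AUCResult]:
    """One AUC per image, with values pooled across participants.

    Mirror of :func:`auc_per_participant` with the pooling axes swapped;
    nongazed draws share the (participant, image, partition, seed) streams.
    """
    image_ids, image_index = _dataset_index(recordings)
    pools = _pool_participants(recordings, image_index)
    sorted_pids = sorted(pools)
    results = []
    for image_id in image_ids:
        pmap = _resolve_map(maps, image_id, assignment)
        gazed_all, nongazed_all = [], []
        any_replace = False
        for p_idx, pid in enumerate(sorted_pids):
            pool = pools[pid]
            if len(pool.image_ids) < 2 or image_id not in pool.image_ids:
                continue
            out = _participant_image_values(
                pool, pmap, image_index[image_id], p_idx, seed, partition_code=0
            )
            if out is None:
                continue
            g, ng, rep = out
            gazed_all.append(g)
            nongazed_all.append(ng)
            any_replace |= rep
        if not gazed_all:
            continue
        results.append(auc_from_values(
            np.concatenate(gazed_all), np.concatenate(nongazed_all),
            condition=condition, pooling="per_image", partition="whole",
            provenance=pmap.provenance, image_id=image_id,
            with_replacement=any_replace,
        ))
    return results


def derangement(items: Sequence[str], rng: np.random.Generator) -> dict[str, str]:
    """A random fixed-point-free permutation (Sattolo's algorithm yields a
    uniform single cycle, hence no item maps to itself)."""
    items = list(items)
    if len(items) < 2:
        raise ValueError("need at least 2 items for a derangement")
    perm = list(range(len(items)))
    for i in range(len(perm) - 1, 0, -1):
        j = int(rng.integers(0, i))
        perm[i], perm[j] = perm[j], perm[i]
    return {items[i]: items[perm[i]] for i in range(len(items))}


def shuffled_control(
    maps: Mapping[str, PredictorMap],
    recordings: Sequence[GazeRecording],
    seed: int,
) -> list[AUCResult]:
    """Shuffled-image control: every image is scored with the predictor map
    of another image (seed-controlled derangement), per participant."""
    image_ids, _ = _dataset_index(recordings)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(999,)))
    assignment = derangement(image_ids, rng)
    return auc_per_participant(maps, recordings, seed,
                               condition="shuffled", assignment=assignment)


def time_binned_auc(
    maps: Mapping[str, PredictorMap],
    recordings: Sequence[GazeRecording],
    seed: int,
    n_bins: int = 8,
    bin_width_s: float = 0.5,
    condition: str = "actual",
    assignment: Mapping[str, str] | None = None,
) -> list[AUCResult]:
    """AUC per participant x 500 ms interval.

    Gazed values are restricted to samples within each interval; the
    nongazed pool is likewise restricted to the matching interval of the
    participant's other images (interval-matched null).  Intervals with no
    valid samples yield no entry.
    """
    image_ids, image_index = _dataset_index(recordings)
    pools = _pool_participants(recordings, image_index, bin_width_s=bin_width_s)
    results = []
    for p_idx, pid in enumerate(sorted(pools)):
        pool = pools[pid]
        if len(pool.image_ids) < 2:
            warnings.warn(f"participant {pid} has <2 images; skipped")
            continue
        for k in range(n_bins):
            in_bin = pool.tbin == k
            gazed_all, nongazed_all = [], []
            any_replace = False
            provenance = ""
            for image_id in pool.image_ids:
                pmap = _resolve_map(maps, image_id, assignment)
                provenance = pmap.provenance
                out = _participant_image_values(
                    pool, pmap, image_index[image_id], p_idx, seed,
                    partition_code=1 + k, sample_mask=in_bin, pool_mask=in_bin,
                )
                if out is None:
                    continue
                g, ng, rep = out
                gazed_all.append(g)
                nongazed_all.append(ng)
                any_replace |= rep
            if not gazed_all:
                continue
            results.append(auc_from_values(
                np.concatenate(gazed_all), np.concatenate(nongazed_all),
                condition=condition, pooling="per_participant",
                partition=f"interval_{k + 1}", provenance=provenance,
                participant_id=pid, group=pool.group,
                with_replacement=any_replace,
            ))
    return results


def velocity_binned_auc(
    maps: Mapping[str, PredictorMap],
    recordings: Sequence[GazeRecording],
    seed: int,
    n_bins: int = 10,
    condition: str = "actual",
    assignment: Mapping[str, str] | None = None,
) -> list[AUCResult]:
    """AUC per participant x velocity-magnitude quantile (1 = slowest).

    Quantiles are participant-specific, computed from the pooled defined
    velocity magnitudes across all of that participant's recordings.  Gazed
    values are restricted to samples in each quantile; the nongazed pool is
    the whole-trial pool of the other images.
    """
    image_ids, image_index = _dataset_index(recordings)
    pools = _pool_participants(recordings, image_index, velocity_bins=n_bins)
    results = []
    for p_idx, pid in enumerate(sorted(pools)):
        pool = pools[pid]
        if len(pool.image_ids) < 2:
            warnings.warn(f"participant {pid} has <2 images; skipped")
            continue
        for q in range(1, n_bins + 1):
            in_bin = pool.vbin == q
            gazed_all, nongazed_all = [], []
            any_replace = False
            provenance = ""
            for image_id in pool.image_ids:
                pmap = _resolve_map(maps, image_id, assignment)
                provenance = pmap.provenance
                out = _participant_image_values(
                    pool, pmap, image_index[image_id], p_idx, seed,
                    partition_code=100 + q, sample_mask=in_bin,
                )
                if out is None:
                    continue
                g, ng, rep = out
                gazed_all.append(g)
                nongazed_all.append(ng)
                any_replace |= rep
            if not gazed_all:
                continue
            results.append(auc_from_values(
                np.concatenate(gazed_all), np.concatenate(nongazed_all),
                condition=condition, pooling="per_participant",
                partition=f"velocity_q{q}", provenance=provenance,
                participant_id=pid, group=pool.group,
                with_replacement=any_replace,
            ))
    return results
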