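"""End-to-end orchestration: filter -> velocity -> entropy -> maps -> AUC ->
repetition -> group statistics, with a config file and a report bundle.

Every output table carries the seed and a hash of the resolved config, so a
rerun with the same config and seed reproduces the report bit-for-bit.
Stage interchange is plain-text tabular (TSV), never opaque binary state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import auc as auc_mod
from . import entropy as entropy_mod
from . import kinematics, maps, repetition, stats
from .geometry import (
    GeometrySpec, read_gaze_dataset, read_trial_pairs, validity_filter,
    write_gaze_dataset, write_trial_pairs,
)
from .synthetic import CohortSpec, SessionData, simulate_session

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline", "load_config"]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the unit."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "freegaze_out"
    seed: int = 0
    # input: either simulate a cohort or read an existing dataset
    simulate: bool = True
    cohort: dict[str, Any] = field(default_factory=dict)
    pair_mix: tuple[int, int, int] = (7, 7, 14)
    gaze_path: str | None = None
    trials_path: str | None = None
    maps_dir: str | None = None
    # analysis options
    grid_cells: int = 20
    fwhm_deg: float = 2.0
    lowpass_cutoffs_deg: tuple[float, ...] = (0.5, 1.0, 2.0)
    partitions: tuple[str, ...] = ("whole", "shuffled")
    empirical_maps: bool = False
    min_valid_fraction: float = 0.5

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where its report lands
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("pair_mix", "lowpass_cutoffs_deg", "partitions"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("input")
def _obtain_dataset(config: RunConfig, geometry: GeometrySpec):
    if config.simulate:
        cohort = CohortSpec(seed=config.seed, **config.cohort)
        session = simulate_session(cohort, pair_mix=config.pair_mix,
                                   render_images=True)
        return session.recordings, session.pairs, session
    if not config.gaze_path or not Path(config.gaze_path).exists():
        raise FileNotFoundError(f"gaze table not found: {config.gaze_path!r}")
    recs = read_gaze_dataset(config.gaze_path, geometry)
    pairs = read_trial_pairs(config.trials_path) if config.trials_path else []
    return recs, pairs, None


@_stage("maps")
def _build_maps(config: RunConfig, recordings, session: SessionData | None,
                geometry: GeometrySpec):
    families: dict[str, dict[str, maps.PredictorMap]] = {}
    if session is not None:
        families["truth"] = session.truth.maps
        if config.empirical_maps:
            by_image: dict[str, list] = {}
            for rec in recordings:
                if rec.group == "SC":
                    by_image.setdefault(rec.image_id, []).append(rec)
            families["empirical"] = {
                img: maps.empirical_map(recs, geometry, fwhm_deg=config.fwhm_deg,
                                        image_id=img)
                for img, recs in by_image.items()
            }
        if session.images and session.images[0].pixels.std() > 0:
            families["contrast"] = {
                img.image_id: maps.contrast_map(img, geometry,
                                                fwhm_deg=config.fwhm_deg)
                for img in session.images
            }
    elif config.maps_dir:
        map_dir = Path(config.maps_dir)
        if not map_dir.is_dir():
            raise FileNotFoundError(f"maps dir not found: {map_dir}")
        family = {}
        for f in sorted(map_dir.iterdir()):
            if f.suffix in {".txt", ".png", ".pgm"}:
                family[f.stem] = maps.load_external_map(f, geometry)
        families["external"] = family
    if not families:
        raise ValueError("no predictor maps available")
    return families


def _auc_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "participant": r.participant_id, "group": r.group, "image": r.image_id,
        "condition": r.condition, "pooling": r.pooling, "partition": r.partition,
        "provenance": r.provenance, "auc": r.auc, "U": r.U,
        "n_gazed": r.n_gazed, "n_nongazed": r.n_nongazed,
    } for r in results])


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the full analysis; writes TSV tables plus a human-readable
    summary under ``config.out_dir`` and returns the tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = GeometrySpec()
    cfg_hash = config.config_hash()
    log: list[str] = [f"config_hash: {cfg_hash}", f"seed: {config.seed}"]

    recordings, pairs, session = _obtain_dataset(config, geometry)
    log.append(f"input: {len(recordings)} recordings, {len(pairs)} trial pairs")

    try:
        kept, discarded, validity_report = validity_filter(
            recordings, config.min_valid_fraction)
    except Exception as exc:
        raise PipelineStageError("validity_filter", str(exc)) from exc
    log.append(f"validity_filter: kept {len(kept)}, discarded {len(discarded)}")

    # velocity
    try:
        vel_rows = []
        for rec in kept:
            trace = kinematics.instantaneous_velocity(rec)
            dist = kinematics.velocity_distribution(trace)
            vel_rows.append({
                "participant": rec.participant_id, "group": rec.group,
                "image": rec.image_id, "trial": rec.trial_index,
                "presentation": rec.presentation,
                "median_velocity": dist.median_magnitude,
                "n_defined": int(trace.defined.sum()),
            })
        velocity_table = pd.DataFrame(vel_rows)
    except Exception as exc:
        raise PipelineStageError("velocity", str(exc)) from exc

    # entropy
    try:
        grid = entropy_mod.GridSpec(config.grid_cells, config.grid_cells)
        ent_results = [entropy_mod.entropy_from_recording(rec, grid) for rec in kept]
        entropy_table = pd.DataFrame([{
            "participant": e.participant_id, "group": e.group,
            "image": e.image_id, "trial": e.trial_index,
            "presentation": e.presentation, "N": e.N,
            "coverage": e.coverage, "H_bits": e.H,
            "grid": f"{grid.n_cells_x}x{grid.n_cells_y}",
        } for e in ent_results])
    except Exception as exc:
        raise PipelineStageError("entropy", str(exc)) from exc

    families = _build_maps(config, kept, session, geometry)
    log.append(f"maps: families {sorted(families)}")

    # AUC
    try:
        auc_results = []
        for fam, fam_maps in families.items():
            if "whole" in config.partitions:
                auc_results += auc_mod.auc_per_participant(fam_maps, kept, config.seed)
            if "shuffled" in config.partitions:
                auc_results += auc_mod.shuffled_control(fam_maps, kept, config.seed)
            if "time" in config.partitions:
                auc_results += auc_mod.time_binned_auc(fam_maps, kept, config.seed)
            if "velocity" in config.partitions:
                auc_results += auc_mod.velocity_binned_auc(fam_maps, kept, config.seed)
        auc_table = _auc_frame(auc_results)
    except Exception as exc:
        raise PipelineStageError("auc", str(exc)) from exc

    # repetition
    repetition_table = pd.DataFrame()
    if pairs:
        try:
            repetition_table = repetition.build_repetition_table(ent_results, pairs)
        except Exception as exc:
            raise PipelineStageError("repetition", str(exc)) from exc

    # group statistics
    contrast_rows = []
    try:
        ent_per_participant = entropy_table.groupby(
            ["participant", "group"])["H_bits"].mean().reset_index()
        if ent_per_participant["group"].nunique() >= 2 and \
                ent_per_participant.groupby("group").size().min() >= 2:
            for c in stats.robust_group_contrasts(
                    ent_per_participant["H_bits"], ent_per_participant["group"]):
                contrast_rows.append({
                    "measure": "entropy", "contrast": c.contrast,
                    "estimate": c.estimate, "se": c.se, "statistic": c.statistic,
                    "pvalue": c.pvalue, "corrected_alpha": c.corrected_alpha,
                })
    except Exception as exc:
        raise PipelineStageError("group_stats", str(exc)) from exc
    contrasts_table = pd.DataFrame(contrast_rows)

    tables = {
        "validity_report": validity_report,
        "velocity": velocity_table,
        "entropy": entropy_table,
        "auc": auc_table,
        "repetition": repetition_table,
        "contrasts": contrasts_table,
    }
    for name, df in tables.items():
        df = df.copy()
        df["config_hash"] = cfg_hash
        df["seed"] = config.seed
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    if session is not None:
        write_gaze_dataset(kept, out / "gaze.tsv")
        write_trial_pairs(pairs, out / "trials.tsv")

    summary = [*log]
    if not auc_table.empty:
        for (fam, cond), sub in auc_table.groupby(["provenance", "condition"]):
            whole = sub[sub["partition"] == "whole"]
            if not whole.empty:
                summary.append(
                    f"auc[{fam}, {cond}]: mean {whole['auc'].mean():.3f} "
                    f"over {len(whole)} units")
    if not entropy_table.empty:
        for group, sub in entropy_table.groupby("group"):
            summary.append(f"entropy[{group}]: mean {sub['H_bits'].mean():.3f} bits")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return tables
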