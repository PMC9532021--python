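"""Data model for gaze recordings, stimuli and screen geometry, plus readers
and writers for the plain-text interchange formats.

Coordinate convention: 0-based pixel indices, origin at the image's top-left
corner, x rightward, y downward (raster convention).  Gaze positions are
stored in image pixels; samples that fall outside the image are retained and
flagged invalid rather than dropped, so missing-data accounting stays exact.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeometrySpec",
    "GazeSample",
    "GazeRecording",
    "TrialPair",
    "ImageStimulus",
    "GazeParseError",
    "GazeStructureError",
    "read_gaze_dataset",
    "write_gaze_dataset",
    "read_trial_pairs",
    "write_trial_pairs",
    "validity_filter",
    "missing_fraction",
]

GROUPS = ("CC", "SC", "DC", "NC")

PAIR_TYPES = ("same_image", "same_category", "different_category")

#: Object categories of the stimulus set.
CATEGORIES = (
    "animals", "chairs", "fruits", "guitars", "houses", "plants", "telephones",
)


class GazeParseError(ValueError):
    """A gaze or trial table could not be parsed."""


class GazeStructureError(ValueError):
    """A parsed table violates structural constraints (timing, duration)."""


@dataclass(frozen=True)
class GeometrySpec:
    """Screen and stimulus geometry of the recording setup.

    Parameters
    ----------
    sampling_rate : float
        Eye-tracker sampling rate in samples/s (default 500 Hz).
    pixels_per_degree : float
        Pixel pitch of the stimulus in px/° of visual angle (default 40.6).
    image_size_px : tuple of int
        Stimulus size (width, height) in pixels.
    image_extent_deg : tuple of float
        Stimulus extent (width, height) in visual degrees.
    screen_size_px : tuple of int
        Full monitor resolution; the image is centred on the screen.
    """

    sampling_rate: float = 500.0
    pixels_per_degree: float = 40.6
    image_size_px: tuple[int, int] = (800, 800)
    image_extent_deg: tuple[float, float] = (19.6, 19.6)
    screen_size_px: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.pixels_per_degree <= 0:
            raise ValueError("sampling_rate and pixels_per_degree must be positive")
        for pair in (self.image_size_px, self.image_extent_deg, self.screen_size_px):
            if len(pair) != 2 or any(v <= 0 for v in pair):
                raise ValueError(f"invalid geometry tuple: {pair!r}")
        for size_px, ext_deg in zip(self.image_size_px, self.image_extent_deg):
            implied = size_px / self.pixels_per_degree
            if abs(implied - ext_deg) / ext_deg > 0.05:
                raise ValueError(
                    "image_size_px / pixels_per_degree inconsistent with "
                    f"image_extent_deg: {implied:.3f} vs {ext_deg:.3f}"
                )

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.sampling_rate

    @property
    def image_center_px(self) -> tuple[float, float]:
        w, h = self.image_size_px
        return (w / 2.0, h / 2.0)

    def deg_to_px(self, deg: float) -> float:
        return deg * self.pixels_per_degree

    def px_to_deg(self, px: float) -> float:
        return px / self.pixels_per_degree


class GazeSample(NamedTuple):
    """One timestamped gaze position; ``valid`` is false when the gaze fell
    off the image or the tracker lost the pupil."""

    t: float
    x: float
    y: float
    valid: bool


@dataclass(eq=False)
class GazeRecording:
    """One participant x image exploration.

    Samples are stored columnar (``t`` seconds, ``x``/``y`` image pixels,
    ``valid`` flags).  Timestamps must be strictly increasing with constant
    step 1/sampling_rate; the nominal trial duration is 4 s (2000 samples at
    500 Hz), enforced by the dataset reader (short recordings can still be
    constructed directly for analysis of partial data).
    """

    participant_id: str
    group: str
    image_id: str
    trial_index: int
    block: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    geometry: GeometrySpec
    #: 1-based presentation order of the image within its trial.
    presentation: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("sample columns must have equal length")
        if n == 0:
            raise ValueError("empty recording")
        if n > 1:
            steps = np.diff(self.t)
            dt = self.geometry.dt
            if np.any(steps <= 0) or np.any(np.abs(steps - dt) > 0.1 * dt):
                raise GazeStructureError(
                    "timestamps must be strictly increasing with constant "
                    f"step {dt:.6f} s"
                )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Nominal duration in seconds (sample count / sampling rate)."""
        return len(self.t) / self.geometry.sampling_rate

    @property
    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(t, x, y, bool(v))
            for t, x, y, v in zip(self.t, self.x, self.y, self.valid)
        ]

    def revalidate_bounds(self) -> None:
        """Clear validity for samples lying outside the image raster."""
        w, h = self.geometry.image_size_px
        inside = (self.x >= 0) & (self.x < w) & (self.y >= 0) & (self.y < h)
        self.valid &= inside

    def valid_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y of valid samples only."""
        return self.x[self.valid], self.y[self.valid]

    def copy(self) -> "GazeRecording":
        return replace(
            self, t=self.t.copy(), x=self.x.copy(), y=self.y.copy(),
            valid=self.valid.copy(),
        )


@dataclass(frozen=True)
class TrialPair:
    """Design metadata for one trial (two sequentially presented images)."""

    participant_id: str
    block: int
    trial_index: int
    pair_type: str
    first_image_id: str
    second_image_id: str
    named_first_correct: bool
    named_second_correct: bool

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair_type {self.pair_type!r}")
        same = self.first_image_id == self.second_image_id
        if self.pair_type == "same_image" and not same:
            raise ValueError("same_image pair with two distinct images")
        if self.pair_type != "same_image" and same:
            raise ValueError(f"{self.pair_type} pair repeats one image")


@dataclass
class ImageStimulus:
    """A grayscale stimulus: square intensity matrix with values in [0, 1]."""

    image_id: str
    category: str
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("stimulus must be a square 2-D matrix")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0.0 or hi > 1.0 + 1e-12:
            raise ValueError(f"intensities outside [0, 1]: [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# Tabular interchange
# ---------------------------------------------------------------------------

GAZE_COLUMNS = [
    "participant_id", "group", "block", "trial_index", "image_id",
    "t_ms", "x_px", "y_px", "valid",
]

TRIAL_COLUMNS = [
    "participant_id", "block", "trial_index", "pair_type",
    "first_image_id", "second_image_id",
    "named_first_correct", "named_second_correct",
]


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise GazeParseError(f"{what} is missing column(s): {', '.join(missing)}")


def read_gaze_dataset(
    path: str | Path | io.IOBase,
    geometry: GeometrySpec,
    *,
    sep: str = "\t",
    duration_tolerance_s: tuple[float, float] = (3.9, 4.1),
) -> list[GazeRecording]:
    """Read a gaze table into one :class:`GazeRecording` per exploration.

    The table holds one sample per row (columns ``participant_id, group,
    block, trial_index, image_id, t_ms, x_px, y_px, valid``).  Within a trial
    the two presentations of the same image (repeated-image trials) are split
    wherever ``t_ms`` resets.  Off-image coordinates are retained with
    ``valid=0``.  Recordings outside the accepted duration window are
    rejected.
    """
    try:
        df = pd.read_csv(path, sep=sep, dtype={"participant_id": str, "image_id": str},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GazeParseError(f"cannot parse gaze table: {exc}") from exc
    _check_columns(df, GAZE_COLUMNS, "gaze table")
    for col in ("t_ms", "x_px", "y_px", "valid"):
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0]) + 2  # 1-based incl. header
            raise GazeParseError(f"malformed value in column {col!r} at line {row}")

    recordings: list[GazeRecording] = []
    lo, hi = duration_tolerance_s
    for (pid, block, trial), sub in df.groupby(
        ["participant_id", "block", "trial_index"], sort=False
    ):
        # one trial holds up to two presentations in row order; split where
        # the image changes or the timestamp resets (identical-image repeats)
        t_ms = sub["t_ms"].to_numpy(dtype=float)
        image_change = (sub["image_id"].to_numpy()[1:]
                        != sub["image_id"].to_numpy()[:-1])
        breaks = np.flatnonzero(image_change | (np.diff(t_ms) < 0)) + 1
        for order, chunk in enumerate(np.split(np.arange(len(sub)), breaks), start=1):
            seg = sub.iloc[chunk]
            rec = GazeRecording(
                participant_id=str(pid),
                group=str(seg["group"].iloc[0]),
                image_id=str(seg["image_id"].iloc[0]),
                trial_index=int(trial),
                block=int(block),
                t=seg["t_ms"].to_numpy(dtype=float) / 1000.0,
                x=seg["x_px"].to_numpy(dtype=float),
                y=seg["y_px"].to_numpy(dtype=float),
                valid=seg["valid"].to_numpy() != 0,
                geometry=geometry,
                presentation=order,
            )
            rec.revalidate_bounds()
            if not (lo <= rec.duration <= hi):
                raise GazeStructureError(
                    f"recording {pid}/{rec.image_id} (trial {trial}) lasts "
                    f"{rec.duration:.3f} s; accepted window is [{lo}, {hi}] s"
                )
            recordings.append(rec)
    return recordings


def write_gaze_dataset(
    recordings: Iterable[GazeRecording], path: str | Path, *, sep: str = "\t"
) -> None:
    """Write recordings in the tabular dialect read by :func:`read_gaze_dataset`."""
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "participant_id": rec.participant_id,
            "group": rec.group,
            "block": rec.block,
            "trial_index": rec.trial_index,
            "image_id": rec.image_id,
            "t_ms": np.round(rec.t * 1000.0).astype(int),
            "x_px": rec.x,
            "y_px": rec.y,
            "valid": rec.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False,
                                                float_format="%.17g")


def read_trial_pairs(path: str | Path | io.IOBase, *, sep: str = "\t") -> list[TrialPair]:
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # pragma: no cover
        raise GazeParseError(f"cannot parse trial table: {exc}") from exc
    _check_columns(df, TRIAL_COLUMNS, "trial table")
    pairs = []
    for _, row in df.iterrows():
        pairs.append(TrialPair(
            participant_id=row["participant_id"],
            block=int(row["block"]),
            trial_index=int(row["trial_index"]),
            pair_type=row["pair_type"],
            first_image_id=row["first_image_id"],
            second_image_id=row["second_image_id"],
            named_first_correct=row["named_first_correct"] in ("1", "True", "true"),
            named_second_correct=row["named_second_correct"] in ("1", "True", "true"),
        ))
    return pairs


def write_trial_pairs(pairs: Iterable[TrialPair], path: str | Path, *, sep: str = "\t") -> None:
    rows = [{
        "participant_id": p.participant_id,
        "block": p.block,
        "trial_index": p.trial_index,
        "pair_type": p.pair_type,
        "first_image_id": p.first_image_id,
        "second_image_id": p.second_image_id,
        "named_first_correct": int(p.named_first_correct),
        "named_second_correct": int(p.named_second_correct),
    } for p in pairs]
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Validity screening
# ---------------------------------------------------------------------------

def missing_fraction(recording: GazeRecording) -> float:
    """Fraction of samples flagged invalid (gaze off-image or pupil lost)."""
    return float(np.mean(~recording.valid))


def validity_filter(
    recordings: Sequence[GazeRecording],
    min_valid_fraction: float = 0.5,
) -> tuple[list[GazeRecording], list[GazeRecording], pd.DataFrame]:
    """Partition recordings by the minimum-valid-data inclusion rule.

    A recording is kept iff its fraction of valid samples is at least
    ``min_valid_fraction`` (default: at least 50% valid samples).  Returns
    ``(kept, discarded, report)`` where the report counts discarded
    explorations per group.
    """
    if len(recordings) == 0:
        raise ValueError("no recordings to filter")
    kept, discarded = [], []
    for rec in recordings:
        frac_valid = 1.0 - missing_fraction(rec)
        (kept if frac_valid >= min_valid_fraction else discarded).append(rec)
    rows = []
    for group in sorted({r.group for r in recordings}):
        n_in = sum(r.group == group for r in recordings)
        n_out = sum(r.group == group for r in discarded)
        rows.append({"group": group, "n_recordings": n_in,
                     "n_discarded": n_out, "n_kept": n_in - n_out})
    report = pd.DataFrame(rows, columns=["group", "n_recordings", "n_discarded", "n_kept"])
    return kept, discarded, report
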