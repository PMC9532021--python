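"""Predictor maps for visual exploration.

Three families of nonnegative, sum-normalized per-pixel maps predict where
gaze lands on an image:

* **empirical** — the pooled gaze density of a reference (normally sighted)
  group for that image, smoothed with a unit-sum Gaussian kernel of 2° FWHM;
  with leave-one-out exclusion when predicting a member of the reference
  group itself;
* **contrast** — a low-level map from local luminance contrast (Gaussian-
  weighted local standard deviation of intensity), standing in for
  intensity-contrast-feature saliency models;
* **external** — maps computed elsewhere (e.g. deep-network saliency) and
  ingested from image or text-grid files.

Low-pass image variants blur the stimulus with a Gaussian whose modulation
transfer falls to 0.67 at the cutoff spatial frequency, emulating reduced
sensitivity to high spatial frequencies.

All convolutions use reflect padding so no probability mass leaks across the
image border.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .geometry import GazeRecording, GeometrySpec, ImageStimulus

__all__ = [
    "PredictorMap",
    "FWHM_TO_SIGMA",
    "empirical_map",
    "contrast_map",
    "load_external_map",
    "save_map",
    "lowpass_image",
    "lowpass_sigma_deg",
]

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: Amplitude attenuation of the low-pass filter at the cutoff frequency.
LOWPASS_REDUCTION = 0.67


class EmptyMapError(ValueError):
    """No contributing gaze samples remain for an empirical map."""


@dataclass
class PredictorMap:
    """A nonnegative per-pixel map, normalized to sum 1."""

    values: np.ndarray
    provenance: str
    fwhm_deg: float = 0.0
    lowpass_cutoff_deg: float | None = None
    image_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map must be 2-D")
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("map values must be finite and nonnegative")
        total = self.values.sum()
        if total <= 0:
            raise ValueError("map has no mass")
        if abs(total - 1.0) > 1e-9:
            self.values = self.values / total

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def value_at(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Nearest-pixel map lookup at continuous pixel coordinates."""
        h, w = self.values.shape
        ix = np.clip(np.rint(np.asarray(x)).astype(int), 0, w - 1)
        iy = np.clip(np.rint(np.asarray(y)).astype(int), 0, h - 1)
        return self.values[iy, ix]


def _smoothing_sigma_px(fwhm_deg: float, geometry: GeometrySpec) -> float:
    return fwhm_deg / FWHM_TO_SIGMA * geometry.pixels_per_degree


def empirical_map(
    recordings: Sequence[GazeRecording],
    geometry: GeometrySpec,
    exclude_participant: str | None = None,
    fwhm_deg: float = 2.0,
    image_id: str = "",
) -> PredictorMap:
    """Empirical gaze-density map for one image from a reference group.

    Pixel-level valid-gaze counts are pooled across the contributing
    participants (excluding ``exclude_participant`` for leave-one-out
    prediction), smoothed with a unit-sum Gaussian of ``fwhm_deg`` FWHM, and
    normalized to sum 1.
    """
    w, h = geometry.image_size_px
    counts = np.zeros((h, w), dtype=float)
    contributed = False
    for rec in recordings:
        if exclude_participant is not None and rec.participant_id == exclude_participant:
            continue
        x, y = rec.valid_xy()
        if x.size == 0:
            continue
        ix = np.clip(np.rint(x).astype(int), 0, w - 1)
        iy = np.clip(np.rint(y).astype(int), 0, h - 1)
        np.add.at(counts, (iy, ix), 1.0)
        contributed = True
    if not contributed or counts.sum() == 0:
        raise EmptyMapError(
            "no contributing gaze samples"
            + (f" after excluding {exclude_participant!r}" if exclude_participant else "")
        )
    smoothed = gaussian_filter(counts, sigma=_smoothing_sigma_px(fwhm_deg, geometry),
                               mode="reflect")
    provenance = "empirical_loo" if exclude_participant is not None else "empirical_full"
    return PredictorMap(values=smoothed, provenance=provenance,
                        fwhm_deg=fwhm_deg, image_id=image_id)


def contrast_map(
    image: ImageStimulus,
    geometry: GeometrySpec,
    window_deg: float = 1.0,
    fwhm_deg: float = 2.0,
) -> PredictorMap:
    """Low-level saliency from local luminance contrast.

    Per-pixel contrast is the Gaussian-weighted local standard deviation of
    intensity (window sigma = ``window_deg`` in pixels), then smoothed with
    the standard FWHM kernel and sum-normalized.  A constant image has zero
    contrast everywhere; the map falls back to uniform and is flagged in its
    provenance.
    """
    h, w = image.pixels.shape
    if (w, h) != tuple(geometry.image_size_px):
        raise ValueError("image size does not match geometry")
    sigma_w = window_deg * geometry.pixels_per_degree
    mean = gaussian_filter(image.pixels, sigma=sigma_w, mode="reflect")
    mean_sq = gaussian_filter(image.pixels ** 2, sigma=sigma_w, mode="reflect")
    local_sd = np.sqrt(np.clip(mean_sq - mean ** 2, 0.0, None))
    if local_sd.max() <= 1e-12:
        uniform = np.full_like(image.pixels, 1.0)
        return PredictorMap(values=uniform, provenance="contrast_uniform_fallback",
                            fwhm_deg=fwhm_deg, image_id=image.image_id)
    smoothed = gaussian_filter(local_sd, sigma=_smoothing_sigma_px(fwhm_deg, geometry),
                               mode="reflect")
    return PredictorMap(values=smoothed, provenance="contrast",
                        fwhm_deg=fwhm_deg, image_id=image.image_id)


def load_external_map(path: str | Path, geometry: GeometrySpec) -> PredictorMap:
    """Load an externally computed map (grayscale image or numeric text grid).

    The grid must match the geometry's image size; values must be
    nonnegative.  The result is sum-normalized with provenance ``external``.
    """
    path = Path(path)
    if path.suffix.lower() in {".txt", ".tsv", ".csv", ".dat"}:
        delim = "," if path.suffix.lower() == ".csv" else None
        values = np.loadtxt(path, delimiter=delim)
    else:
        with Image.open(path) as img:
            values = np.asarray(img, dtype=float)
    w, h = geometry.image_size_px
    if values.shape != (h, w):
        raise ValueError(
            f"external map shape {values.shape} does not match geometry {(h, w)}"
        )
    if np.any(values < 0):
        raise ValueError("external map contains negative values")
    return PredictorMap(values=values, provenance="external", image_id=path.stem)


def save_map(pmap: PredictorMap, path: str | Path, *, format: str = "txt") -> None:
    """Persist a map: exact text grid (``txt``) or 16-bit grayscale PNG
    (``png16``, max-scaled) with a key-value sidecar holding provenance."""
    path = Path(path)
    if format == "txt":
        np.savetxt(path, pmap.values, fmt="%.17g")
    elif format == "png16":
        scaled = np.round(pmap.values / pmap.values.max() * 65535).astype(np.uint16)
        Image.fromarray(scaled, mode="I;16").save(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    sidecar = path.with_suffix(path.suffix + ".meta")
    lines = [
        f"provenance: {pmap.provenance}",
        f"fwhm_deg: {pmap.fwhm_deg}",
        f"lowpass_cutoff_deg: {pmap.lowpass_cutoff_deg}",
        f"image_id: {pmap.image_id}",
    ]
    sidecar.write_text("\n".join(lines) + "\n")


def lowpass_sigma_deg(cutoff_deg: float, reduction: float = LOWPASS_REDUCTION) -> float:
    """Gaussian blur sigma (in degrees) whose modulation transfer function
    equals ``reduction`` at spatial frequency 1/cutoff_deg cycles/°.

    MTF(f) = exp(-2 pi^2 sigma^2 f^2)  =>  sigma = cutoff * sqrt(ln(1/r)) / (pi sqrt 2).
    """
    if cutoff_deg <= 0:
        raise ValueError("cutoff must be positive")
    return cutoff_deg * np.sqrt(np.log(1.0 / reduction)) / (np.pi * np.sqrt(2.0))


def lowpass_image(
    image: ImageStimulus, cutoff_deg: float, geometry: GeometrySpec
) -> ImageStimulus:
    """Low-pass-filter a stimulus (attenuation to 0.67 at the cutoff)."""
    sigma_px = lowpass_sigma_deg(cutoff_deg) * geometry.pixels_per_degree
    blurred = gaussian_filter(image.pixels, sigma=sigma_px, mode="reflect")
    return ImageStimulus(
        image_id=f"{image.image_id}_lp{cutoff_deg:g}",
        category=image.category,
        pixels=np.clip(blurred, 0.0, 1.0),
    )
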