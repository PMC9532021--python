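"""Instantaneous gaze velocity and velocity-based partitions.

Fixation/saccade segmentation is deliberately avoided: with nystagmus there
is no velocity threshold that separates fixations from saccades, so every
gaze sample enters the analysis.  Gaze stability is instead quantified by an
instantaneous velocity operator, a smoothed (multi-sample) variant of the
2-point central difference:

    Velocity(n) = SR * (g(n+4) + g(n+3) + g(n+2)
                        - g(n-2) - g(n-3) - g(n-4)) / (18 * PPD)

applied separately to the horizontal and vertical components.  SR is the
sampling rate (samples/s), PPD converts pixels to visual degrees and the
constant 18 is the sum of the index spans (4-(-4)) + (3-(-3)) + (2-(-2)).
For a linear trajectory of slope a px/sample the operator returns exactly
a*SR/PPD °/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GazeRecording

__all__ = [
    "VelocityTrace",
    "VelocityDistribution",
    "instantaneous_velocity",
    "velocity_distribution",
    "velocity_quantile_partition",
]

# Forward/backward sample offsets of the velocity operator and its
# normalizing span (4-(-4)) + (3-(-3)) + (2-(-2)) = 18.
_FORWARD_OFFSETS = (2, 3, 4)
_SPAN = 18
_HALF_WINDOW = 4


@dataclass
class VelocityTrace:
    """Per-sample instantaneous gaze velocity in °/s.

    Entries are NaN where undefined: the first/last 4 samples, and any sample
    whose 9-sample neighbourhood touches an invalid gaze sample.
    """

    horizontal: np.ndarray
    vertical: np.ndarray
    magnitude: np.ndarray
    defined: np.ndarray

    def __len__(self) -> int:
        return len(self.defined)

    @property
    def defined_magnitude(self) -> np.ndarray:
        return self.magnitude[self.defined]


def _axis_velocity(g: np.ndarray, sr: float, ppd: float) -> np.ndarray:
    n = len(g)
    out = np.full(n, np.nan)
    core = slice(_HALF_WINDOW, n - _HALF_WINDOW)
    acc = np.zeros(n - 2 * _HALF_WINDOW)
    for k in _FORWARD_OFFSETS:
        acc += g[_HALF_WINDOW + k : n - _HALF_WINDOW + k]
        acc -= g[_HALF_WINDOW - k : n - _HALF_WINDOW - k]
    out[core] = sr * acc / (_SPAN * ppd)
    return out


def instantaneous_velocity(recording: GazeRecording) -> VelocityTrace:
    """Apply the velocity operator to a recording.

    Undefined samples (window truncated by the trace edge or touching an
    invalid sample) are flagged and set to NaN, never silently zeroed.
    """
    n = len(recording)
    if n < 2 * _HALF_WINDOW + 1:
        raise ValueError(f"recording has {n} samples; need at least 9")
    geom = recording.geometry
    h = _axis_velocity(recording.x, geom.sampling_rate, geom.pixels_per_degree)
    v = _axis_velocity(recording.y, geom.sampling_rate, geom.pixels_per_degree)

    # a sample is defined iff all samples n-4 .. n+4 are valid
    ok = recording.valid.astype(float)
    window_ok = np.ones(n, dtype=bool)
    window_ok[:_HALF_WINDOW] = False
    window_ok[n - _HALF_WINDOW:] = False
    csum = np.concatenate([[0.0], np.cumsum(ok)])
    core = np.arange(_HALF_WINDOW, n - _HALF_WINDOW)
    n_valid = csum[core + _HALF_WINDOW + 1] - csum[core - _HALF_WINDOW]
    window_ok[core] &= n_valid == (2 * _HALF_WINDOW + 1)

    h[~window_ok] = np.nan
    v[~window_ok] = np.nan
    mag = np.hypot(h, v)
    return VelocityTrace(horizontal=h, vertical=v, magnitude=mag, defined=window_ok)


@dataclass
class VelocityDistribution:
    """Binned velocity densities (1-D magnitude and 2-D component) plus the
    median magnitude.  Densities sum to 1."""

    bin_size: float
    magnitude_edges: np.ndarray
    magnitude_density: np.ndarray
    component_edges: np.ndarray
    component_density: np.ndarray  # [horizontal, vertical]
    median_magnitude: float


def velocity_distribution(trace: VelocityTrace, bin_size: float = 16.0) -> VelocityDistribution:
    """Histogram the velocity trace (default bin size 16 °/s)."""
    mag = trace.defined_magnitude
    if mag.size == 0:
        raise ValueError("velocity trace has no defined samples")
    h = trace.horizontal[trace.defined]
    v = trace.vertical[trace.defined]

    m_hi = max(bin_size, float(np.ceil(mag.max() / bin_size + 1e-12)) * bin_size)
    m_edges = np.arange(0.0, m_hi + bin_size / 2, bin_size)
    m_counts, _ = np.histogram(mag, bins=m_edges)
    m_density = m_counts / m_counts.sum()

    c_max = max(bin_size, float(np.max(np.abs(np.concatenate([h, v])))))
    n_half = int(np.ceil(c_max / bin_size + 1e-12))
    c_edges = np.arange(-n_half, n_half + 1) * bin_size
    c_counts, _, _ = np.histogram2d(h, v, bins=[c_edges, c_edges])
    c_density = c_counts / c_counts.sum()

    return VelocityDistribution(
        bin_size=bin_size,
        magnitude_edges=m_edges,
        magnitude_density=m_density,
        component_edges=c_edges,
        component_density=c_density,
        median_magnitude=float(np.median(mag)),
    )


def velocity_quantile_partition(trace: VelocityTrace, n_bins: int = 10) -> np.ndarray:
    """Partition defined samples into ``n_bins`` near-equal-size groups by
    velocity magnitude.

    Returns an integer label per sample: 1..n_bins for defined samples
    (1 = slowest decile), 0 for undefined samples.  Ties are broken by stable
    sample order, so bin sizes differ by at most one.
    """
    idx = np.flatnonzero(trace.defined)
    m = idx.size
    if m < n_bins:
        raise ValueError(f"{m} defined samples; need at least n_bins={n_bins}")
    order = np.argsort(trace.magnitude[idx], kind="stable")
    labels = np.zeros(len(trace.defined), dtype=int)
    positions = np.arange(m)
    labels[idx[order]] = positions * n_bins // m + 1
    return labels
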