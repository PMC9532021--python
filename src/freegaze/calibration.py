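"""Five-point polynomial gaze calibration.

Because standard online calibration fails with nystagmus, calibration uses
manually selected low-velocity gaze windows at five screen targets: the
center, 15° right/left, and 8.5° above/below.  The median raw gaze position
of each target's windows is fitted with a full quadratic polynomial per
output axis (6 coefficients per axis, ridge-regularized so five points do
not leave the fit rank-deficient), mapping raw tracker coordinates to image
pixels.  Calibration error is quantified at the central target only, as the
distance in degrees between the calibrated median of a validation window
and the image center.

Window selection is taken as given input (it is a manual, judgment-based
step); the synthetic generator produces windows directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .geometry import GazeRecording, GeometrySpec

__all__ = [
    "CANONICAL_TARGETS_DEG",
    "CalibrationTargetSet",
    "CalibrationModel",
    "fit_calibration",
    "apply_calibration",
    "central_error",
]

#: The five calibration target positions in degrees relative to the image
#: center (x rightward, y downward).
CANONICAL_TARGETS_DEG: dict[str, tuple[float, float]] = {
    "center": (0.0, 0.0),
    "right": (15.0, 0.0),
    "left": (-15.0, 0.0),
    "below": (0.0, 8.5),
    "above": (0.0, -8.5),
}

_MIN_WINDOW_SAMPLES = 10


@dataclass
class CalibrationTargetSet:
    """Selected low-velocity raw-gaze windows at the five targets.

    ``windows`` maps each target label to an (n, 2) array of raw (u, v)
    tracker coordinates; each target needs at least one window of >= 10
    samples (multiple windows may be concatenated by the caller).
    """

    windows: Mapping[str, np.ndarray]
    targets_deg: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(CANONICAL_TARGETS_DEG)
    )

    def __post_init__(self) -> None:
        if set(self.windows) != set(self.targets_deg):
            raise ValueError(
                f"windows for targets {sorted(self.windows)} do not match "
                f"the target set {sorted(self.targets_deg)}"
            )
        for label, w in self.windows.items():
            arr = np.asarray(w, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < _MIN_WINDOW_SAMPLES:
                raise ValueError(
                    f"target {label!r}: need an (n>={_MIN_WINDOW_SAMPLES}, 2) window"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"target {label!r}: non-finite samples")


class SingularFitError(ValueError):
    """Calibration geometry is degenerate (rank-deficient fit)."""


@dataclass
class CalibrationModel:
    """Quadratic map from raw (u, v) to image-pixel (x, y).

    Features are evaluated on centered/scaled raw coordinates for numerical
    stability; ``coef_x``/``coef_y`` hold the 6 coefficients per axis over
    [1, u', v', u'v', u'^2, v'^2].
    """

    coef_x: np.ndarray
    coef_y: np.ndarray
    center_uv: np.ndarray
    scale_uv: np.ndarray
    residuals_px: dict[str, float]
    geometry: GeometrySpec

    def predict(self, u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = _features(np.column_stack([np.asarray(u, float), np.asarray(v, float)]),
                      self.center_uv, self.scale_uv)
        return A @ self.coef_x, A @ self.coef_y


def _features(uv: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    s = (uv - center) / scale
    u, v = s[:, 0], s[:, 1]
    return np.column_stack([np.ones_like(u), u, v, u * v, u ** 2, v ** 2])


def target_positions_px(
    targets_deg: Mapping[str, tuple[float, float]], geometry: GeometrySpec
) -> dict[str, tuple[float, float]]:
    """Target positions in image-pixel coordinates (may lie off-image for the
    eccentric targets; coordinates are not clipped)."""
    cx, cy = geometry.image_center_px
    ppd = geometry.pixels_per_degree
    return {
        label: (cx + dx * ppd, cy + dy * ppd)
        for label, (dx, dy) in targets_deg.items()
    }


def fit_calibration(
    targets: CalibrationTargetSet,
    geometry: GeometrySpec,
    ridge: float = 1e-12,
) -> CalibrationModel:
    """Least-squares quadratic fit of per-target raw medians to target pixels.

    Medians are computed per target first; the six polynomial coefficients
    per axis are then fitted to the five medians with a tiny ridge penalty on
    centered/scaled features (the quadratic is otherwise rank-deficient on
    five points; the penalty selects the minimum-norm interpolant without
    perceptibly biasing the fit).
    """
    labels = sorted(targets.windows)
    medians = np.array([
        np.median(np.asarray(targets.windows[lab], float), axis=0) for lab in labels
    ])
    px_targets = target_positions_px(targets.targets_deg, geometry)
    bx = np.array([px_targets[lab][0] for lab in labels])
    by = np.array([px_targets[lab][1] for lab in labels])

    center = medians.mean(axis=0)
    scale = np.maximum(medians.std(axis=0), 1.0)
    A = _features(medians, center, scale)
    if np.linalg.matrix_rank(A, tol=1e-9) < 3:
        # fewer than 3 independent directions: even an affine map is unidentifiable
        raise SingularFitError("calibration target medians are collinear")

    # ridge via row augmentation keeps the solve well-conditioned
    aug = np.vstack([A, np.sqrt(ridge) * np.eye(A.shape[1])])
    zeros = np.zeros(A.shape[1])
    coef_x = np.linalg.lstsq(aug, np.concatenate([bx, zeros]), rcond=None)[0]
    coef_y = np.linalg.lstsq(aug, np.concatenate([by, zeros]), rcond=None)[0]

    fit_x, fit_y = A @ coef_x, A @ coef_y
    residuals = {
        lab: float(np.hypot(fit_x[i] - bx[i], fit_y[i] - by[i]))
        for i, lab in enumerate(labels)
    }
    return CalibrationModel(
        coef_x=coef_x, coef_y=coef_y, center_uv=center, scale_uv=scale,
        residuals_px=residuals, geometry=geometry,
    )


def apply_calibration(model: CalibrationModel, recording: GazeRecording) -> GazeRecording:
    """Map a recording's raw coordinates through the calibration model.

    Returns a new recording with calibrated pixel coordinates; validity is
    re-evaluated against the image bounds (a point mapped off-image loses
    its valid flag; a previously invalid sample never regains it).
    """
    out = recording.copy()
    out.x, out.y = model.predict(recording.x, recording.y)
    out.revalidate_bounds()
    return out


def central_error(
    model: CalibrationModel,
    validation_window: np.ndarray,
    geometry: GeometrySpec,
) -> float:
    """Calibration error (degrees) at the central target.

    Euclidean distance between the calibrated median of the validation
    window and the image center, divided by pixels-per-degree.
    """
    window = np.asarray(validation_window, dtype=float)
    if window.ndim != 2 or window.shape[1] != 2 or window.shape[0] == 0:
        raise ValueError("validation window must be a non-empty (n, 2) array")
    med = np.median(window, axis=0)
    x, y = model.predict(med[:1], med[1:])
    cx, cy = geometry.image_center_px
    return float(np.hypot(x[0] - cx, y[0] - cy) / geometry.pixels_per_degree)
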