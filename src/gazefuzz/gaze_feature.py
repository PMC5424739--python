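"""Feature 2 -- gaze position and its change over a short dwell window.

Gaze is estimated with the classic pupil-center corneal-reflection
technique: the pupil center is compensated by the glint center (vector
difference, which cancels common head translation), and a 4-point
bilinear calibration maps the compensated position to monitor pixels:

    Gx = a*x + b*y + c*x*y + d
    Gy = e*x + f*y + g*x*y + h

The eight coefficients are solved exactly from the four corner
correspondences. Feature 2 is the summed Euclidean gaze change
sum_{i=S}^{S+W-1} dz_i over a W-frame dwell window starting at the
fixation anchor S; it is small when the user holds a selection gaze.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateCalibrationError,
    GazeUnavailableError,
    IncompleteDwellWindowError,
)

__all__ = [
    "CalibrationSet",
    "CalibrationModel",
    "GazeTrace",
    "compensate",
    "fit_calibration",
    "map_gaze",
    "gaze_delta",
    "dwell_change",
    "minimum_target_separation_cm",
    "frame_period_ms",
    "window_duration_ms",
]

DWELL_WINDOW = 10  # frames, same as the Feature-1 template window


@dataclass(frozen=True)
class CalibrationSet:
    """Four glint-compensated pupil positions and their monitor corner targets."""

    eye_points: np.ndarray  # (4, 2)
    monitor_points: np.ndarray  # (4, 2)

    def __post_init__(self) -> None:
        eye = np.asarray(self.eye_points, dtype=float)
        mon = np.asarray(self.monitor_points, dtype=float)
        if eye.shape != (4, 2) or mon.shape != (4, 2):
            raise ValueError("calibration needs exactly 4 eye and 4 monitor points")
        object.__setattr__(self, "eye_points", eye)
        object.__setattr__(self, "monitor_points", mon)


@dataclass(frozen=True)
class CalibrationModel:
    """The 8 bilinear coefficients (a, b, c, d, e, f, g, h)."""

    coeffs: np.ndarray

    def map(self, point: Sequence[float]) -> tuple[float, float]:
        x, y = float(point[0]), float(point[1])
        a, b, c, d, e, f, g, h = self.coeffs
        return (a * x + b * y + c * x * y + d, e * x + f * y + g * x * y + h)


@dataclass
class GazeTrace:
    """Per-frame monitor-space gaze positions with validity flags."""

    frame_indices: np.ndarray
    positions: np.ndarray  # (n, 2), NaN where invalid
    valid: np.ndarray  # bool per frame

    def deltas(self) -> np.ndarray:
        """Per-frame gaze change dz_i (NaN for the first frame or missing gaze)."""
        dz = np.full(len(self.frame_indices), np.nan)
        p = self.positions
        ok = self.valid
        for i in range(1, len(dz)):
            if ok[i] and ok[i - 1]:
                dz[i] = gaze_delta(p[i], p[i - 1])
        return dz


def compensate(
    pupil_center: Sequence[float], glint_center: Sequence[float]
) -> tuple[float, float]:
    """Glint-compensated pupil position: pupil - glint (head-shift invariant)."""
    return (
        float(pupil_center[0]) - float(glint_center[0]),
        float(pupil_center[1]) - float(glint_center[1]),
    )


def fit_calibration(cal: CalibrationSet) -> CalibrationModel:
    """Solve the two 4x4 bilinear systems through the four correspondences.

    Raises :class:`DegenerateCalibrationError` when the eye points are
    (near-)collinear and the design matrix is singular.
    """
    x, y = cal.eye_points[:, 0], cal.eye_points[:, 1]
    design = np.column_stack([x, y, x * y, np.ones(4)])
    if abs(np.linalg.det(design)) < 1e-12 * max(1.0, float(np.abs(design).max()) ** 4):
        raise DegenerateCalibrationError("degenerate calibration: singular 4x4 system")
    abcd = np.linalg.solve(design, cal.monitor_points[:, 0])
    efgh = np.linalg.solve(design, cal.monitor_points[:, 1])
    return CalibrationModel(coeffs=np.concatenate([abcd, efgh]))


def map_gaze(
    model_left: CalibrationModel | None,
    model_right: CalibrationModel | None,
    p_left: Sequence[float] | None,
    p_right: Sequence[float] | None,
) -> tuple[float, float]:
    """Monitor gaze point: per-eye bilinear map, averaged when both eyes are valid."""
    points = []
    if model_left is not None and p_left is not None:
        points.append(model_left.map(p_left))
    if model_right is not None and p_right is not None:
        points.append(model_right.map(p_right))
    if not points:
        raise GazeUnavailableError("gaze unavailable for frame")
    arr = np.asarray(points, dtype=float)
    return (float(arr[:, 0].mean()), float(arr[:, 1].mean()))


def gaze_delta(p_now: Sequence[float], p_prev: Sequence[float]) -> float:
    """Euclidean gaze change dz between consecutive frames."""
    return math.hypot(
        float(p_now[0]) - float(p_prev[0]), float(p_now[1]) - float(p_prev[1])
    )


def dwell_change(trace: GazeTrace, start: int, window: int = DWELL_WINDOW) -> float:
    """Raw Feature 2: sum of dz over ``window`` frames from ``start``.

    ``start`` indexes into the trace arrays. Raises
    :class:`IncompleteDwellWindowError` if any dz in the window is
    missing (invalid gaze on a frame or its predecessor).
    """
    dz = trace.deltas()
    if start < 0 or start + window > len(dz):
        raise IncompleteDwellWindowError("incomplete dwell window: out of range")
    chunk = dz[start : start + window]
    if np.any(np.isnan(chunk)):
        raise IncompleteDwellWindowError("incomplete dwell window: missing gaze")
    return float(chunk.sum())


def minimum_target_separation_cm(z_distance_cm: float, accuracy_deg: float = 1.0) -> float:
    """Minimum on-screen separation of two selectable targets.

    With gaze accuracy of about +/- ``accuracy_deg`` degrees at viewing
    distance ``z_distance_cm``, targets must be at least
    z * tan(2 * accuracy) apart (e.g. 70 cm at +/-1 degree -> 2.44 cm).
    """
    return z_distance_cm * math.tan(math.radians(2.0 * accuracy_deg))


def frame_period_ms(fps: float) -> float:
    """Capture period per frame in milliseconds (30 fps -> 33.3 ms)."""
    return 1000.0 / fps


def window_duration_ms(window: int, fps: float = 30.0) -> float:
    """Duration of an analysis window in ms (10 frames at 30 fps -> ~333 ms)."""
    return window * frame_period_ms(fps)
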