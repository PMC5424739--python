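"""Feature 1 -- pupil accommodation by template matching.

Pupil size is the pixel count inside the segmented pupil boundary. A
3-tap moving average suppresses frame-to-frame noise, a 10-frame window
(~333 ms at 30 fps) is min-max normalized, and the feature is the
minimum sum-of-squared-differences (SSD) against a small bank of
constriction templates. Intentional fixations show a transient pupil
constriction, so a low score is evidence of target selection.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .errors import NoFixationError, WindowMismatchError

__all__ = [
    "PupilSeries",
    "TemplateGraph",
    "MatchResult",
    "smooth_series",
    "normalize_minmax",
    "template_match_score",
    "locate_window_start",
    "default_template_bank",
    "load_template_bank",
]

WINDOW_SIZE = 10
STILLNESS_THRESHOLD = 5.0  # monitor px / frame


@dataclass(frozen=True)
class PupilSeries:
    """Pupil sizes (pixel counts) on the valid frames of a session."""

    frame_indices: np.ndarray
    sizes: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_indices, dtype=int)
        sz = np.asarray(self.sizes, dtype=float)
        if idx.shape != sz.shape:
            raise ValueError("frame_indices and sizes must have equal length")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("frame_indices must be strictly increasing")
        if np.any(sz <= 0):
            raise ValueError("pupil sizes must be positive pixel counts")
        object.__setattr__(self, "frame_indices", idx)
        object.__setattr__(self, "sizes", sz)


@dataclass(frozen=True)
class TemplateGraph:
    """One normalized constriction profile of length ``WINDOW_SIZE``."""

    values: np.ndarray
    template_id: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isclose(v.min(), 0.0) or not np.isclose(v.max(), 1.0):
            raise ValueError("template must be min-max normalized to [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class MatchResult:
    """Best-template SSD for one candidate window."""

    score: float
    best_template: int
    window_start: int


def smooth_series(sizes: Sequence[float]) -> np.ndarray:
    """3-tap uniform moving average; truncated, renormalized end windows."""
    v = np.asarray(sizes, dtype=float)
    if v.size == 0:
        raise ValueError("series must be non-empty")
    csum = np.concatenate([[0.0], np.cumsum(v)])
    idx = np.arange(v.size)
    lo = np.maximum(idx - 1, 0)
    hi = np.minimum(idx + 2, v.size)
    return (csum[hi] - csum[lo]) / (hi - lo)


def normalize_minmax(window: Sequence[float]) -> np.ndarray:
    """Scale a window to [0, 1]; a constant window maps to all zeros."""
    w = np.asarray(window, dtype=float)
    lo, hi = w.min(), w.max()
    if hi == lo:
        return np.zeros_like(w)
    return (w - lo) / (hi - lo)


def _dip_profile(dip_index: int, length: int = WINDOW_SIZE, recovery: float = 0.6) -> np.ndarray:
    """Constrict-then-partially-recover profile: 1 -> 0 at ``dip_index`` -> recovery."""
    v = np.empty(length)
    v[: dip_index + 1] = np.linspace(1.0, 0.0, dip_index + 1)
    v[dip_index:] = np.linspace(0.0, recovery, length - dip_index)
    return v


def default_template_bank(length: int = WINDOW_SIZE) -> list[TemplateGraph]:
    """Three constriction templates: fast, middle and slow dip.

    Minima sit at samples 3, 5 and 7 (1-based) of the window; each
    profile falls linearly from 1 to 0 and recovers to 0.6.
    """
    dips_1based = (3, 5, 7)
    dips = [round((d - 1) * (length - 1) / (WINDOW_SIZE - 1)) for d in dips_1based]
    return [TemplateGraph(_dip_profile(d, length), i + 1) for i, d in enumerate(dips)]


def load_template_bank(path=None) -> list[TemplateGraph]:
    """Load a template bank from CSV (one row per template); defaults to the packaged bank."""
    if path is None:
        path = resources.files("gazefuzz").joinpath("data/templates.csv")
    with open(str(path), newline="") as fh:
        rows = [row for row in csv.reader(fh) if row]
    return [TemplateGraph(np.array([float(x) for x in row]), i + 1) for i, row in enumerate(rows)]


def template_match_score(
    window: Sequence[float], bank: Sequence[TemplateGraph], window_start: int = 0
) -> MatchResult:
    """Minimum SSD of the normalized window over the template bank.

    Ties go to the lowest template id. Raises
    :class:`WindowMismatchError` on a length mismatch.
    """
    w = np.asarray(window, dtype=float)
    if not bank:
        raise ValueError("template bank must be non-empty")
    best_score, best_id = np.inf, -1
    for tpl in bank:
        if tpl.values.shape != w.shape:
            raise WindowMismatchError("window/template length mismatch")
        ssd = float(np.sum((w - tpl.values) ** 2))
        if ssd < best_score:
            best_score, best_id = ssd, tpl.template_id
    return MatchResult(score=best_score, best_template=best_id, window_start=window_start)


def locate_window_start(
    gaze_deltas: Sequence[float],
    window: int = WINDOW_SIZE,
    stillness_threshold: float = STILLNESS_THRESHOLD,
    frame_indices: Sequence[int] | None = None,
) -> int:
    """First frame of the longest low-motion (fixation) run in the trace.

    ``gaze_deltas`` holds per-frame gaze changes Δz; a fixation candidate
    is a maximal run of Δz below ``stillness_threshold`` of at least
    ``window`` frames. The start of the longest such run (earliest on
    ties) anchors both the Feature-1 template window and the Feature-2
    dwell window. Raises :class:`NoFixationError` when no run is long
    enough.
    """
    dz = np.asarray(gaze_deltas, dtype=float)
    if dz.size < window:
        raise NoFixationError("no fixation candidate: trace shorter than window")
    still = dz < stillness_threshold
    best_start, best_len = -1, 0
    run_start = None
    for i, flag in enumerate(np.append(still, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            run_len = i - run_start
            if run_len > best_len:
                best_start, best_len = run_start, run_len
            run_start = None
    if best_len < window:
        raise NoFixationError("no fixation candidate")
    if frame_indices is not None:
        return int(np.asarray(frame_indices)[best_start])
    return best_start
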