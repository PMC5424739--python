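"""End-to-end glue: frames -> detections -> per-event features -> fuzzy scores.

Two entry granularities exist. The image path runs the segmentation
detector on eye frames and converts detections into pupil-size series
and gaze traces. The signal path (used by the synthetic session and
the noise-robustness experiment) starts directly from those series.
Either way, each candidate event yields one feature triple
(f1 = template-match SSD, f2 = dwell gaze change, f3 = Gabor texture),
which is normalized, fused by the fuzzy system and thresholded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoFixationError, ROIOffScreenError
from .evaluation import LabeledScore
from .fuzzy import (
    FeatureVector,
    MembershipParams,
    RampPair,
    fit_membership_entropy,
    fuzzy_score,
    normalize_features,
)
from .gaze_feature import CalibrationModel, GazeTrace, dwell_change
from .pupil_feature import (
    STILLNESS_THRESHOLD,
    TemplateGraph,
    default_template_bank,
    locate_window_start,
    normalize_minmax,
    smooth_series,
    template_match_score,
)
from .segmentation import Detection, EyeFrame, SegmentationConfig, detect_pupil_and_glint
from .synthetic import SyntheticSession
from .texture_feature import FilterBank, ROISpec, build_bank, texture_score

__all__ = [
    "EventFeatures",
    "detect_session_frames",
    "extract_event_features",
    "feature_ranges",
    "fit_session_membership",
    "score_session",
    "detections_to_csv",
]


@dataclass
class EventFeatures:
    """Raw feature triple for one candidate event (or the no-fixation flag)."""

    event: int
    label: int
    window_start: int | None
    f1_raw: float | None
    f2_raw: float | None
    f3_raw: float | None
    best_template: int | None

    @property
    def has_window(self) -> bool:
        return self.window_start is not None


def detect_session_frames(
    frames: Sequence[EyeFrame], config: SegmentationConfig | None = None
) -> list[Detection]:
    """Run the pupil/glint detector over a frame sequence."""
    return [detect_pupil_and_glint(f, config) for f in frames]


def detections_to_csv(frames: Sequence[EyeFrame], detections: Sequence[Detection]) -> pd.DataFrame:
    """Per-frame detection table (the segmentation module's CSV contract)."""
    rows = []
    for frame, det in zip(frames, detections):
        rows.append(
            dict(
                frame_index=frame.frame_index,
                eye=frame.eye_side,
                pupil_x=det.pupil_center[0] if det.pupil_center else np.nan,
                pupil_y=det.pupil_center[1] if det.pupil_center else np.nan,
                pupil_area=det.pupil_area if det.pupil_area is not None else np.nan,
                glint_x=det.glint_center[0] if det.glint_center else np.nan,
                glint_y=det.glint_center[1] if det.glint_center else np.nan,
                valid=det.valid,
            )
        )
    return pd.DataFrame(rows)


def extract_event_features(
    session: SyntheticSession,
    bank: Sequence[TemplateGraph] | None = None,
    gabor_bank: FilterBank | None = None,
    stillness_threshold: float = STILLNESS_THRESHOLD,
    roi_half: int = 50,
) -> list[EventFeatures]:
    """Per-event raw features from a signal-level session.

    For each event span, the fixation anchor S is located on the gaze
    deltas; events without a qualifying fixation run carry ``None``
    features (they will score 0 downstream). The Feature-1 window is
    the smoothed, min-max-normalized pupil-size window at S; Feature 2
    the dwell gaze change; Feature 3 the Gabor texture of the monitor
    at the window's mean gaze point.
    """
    bank = bank if bank is not None else default_template_bank(session.window)
    gabor_bank = gabor_bank or build_bank()
    smoothed = smooth_series(session.pupil_sizes)
    trace = GazeTrace(
        frame_indices=np.arange(session.n_frames),
        positions=session.gaze,
        valid=np.ones(session.n_frames, dtype=bool),
    )
    dz_all = trace.deltas()
    out = []
    W = session.window
    for k, (start, end, label) in enumerate(session.events):
        dz = dz_all[start:end]
        dz = np.where(np.isnan(dz), np.inf, dz)  # first frame of the session
        try:
            s_local = locate_window_start(dz, window=W, stillness_threshold=stillness_threshold)
        except NoFixationError:
            out.append(EventFeatures(k, label, None, None, None, None, None))
            continue
        s = start + s_local
        if s + W > session.n_frames:
            out.append(EventFeatures(k, label, None, None, None, None, None))
            continue
        window = normalize_minmax(smoothed[s : s + W])
        match = template_match_score(window, bank, window_start=s)
        f2 = dwell_change(trace, s, W)
        center = session.gaze[s : s + W].mean(axis=0)
        roi = ROISpec(center=(float(center[0]), float(center[1])), half_width=roi_half, half_height=roi_half)
        try:
            f3 = texture_score(session.monitor, roi, gabor_bank)
        except ROIOffScreenError:
            f3 = 0.0
        out.append(EventFeatures(k, label, s, match.score, f2, f3, match.best_template))
    return out


def feature_ranges(records: Sequence[EventFeatures]) -> dict[str, tuple[float, float]]:
    """Training min/max per raw feature over events with a valid window."""
    ranges = {}
    for name, attr in (("f1", "f1_raw"), ("f2", "f2_raw"), ("f3", "f3_raw")):
        vals = [getattr(r, attr) for r in records if r.has_window]
        if not vals:
            raise ValueError("no valid windows to derive feature ranges from")
        lo, hi = float(min(vals)), float(max(vals))
        if hi <= lo:
            hi = lo + 1e-9
        ranges[name] = (lo, hi)
    return ranges


def _class_histograms(values: np.ndarray, labels: np.ndarray, n_bins: int = 101):
    idx = np.clip(np.round(values * (n_bins - 1)).astype(int), 0, n_bins - 1)
    m_high = np.bincount(idx[labels == 1], minlength=n_bins).astype(float)
    m_low = np.bincount(idx[labels == 0], minlength=n_bins).astype(float)
    return m_high, m_low


def fit_session_membership(
    records: Sequence[EventFeatures],
    ranges: Mapping[str, tuple[float, float]],
    grid_step: float = 0.01,
) -> MembershipParams:
    """Entropy-fit the three ramp pairs from a labeled feature table.

    Events without a fixation window are excluded (they never reach the
    fuzzy stage). Falls back to symmetric mid-range ramps for a feature
    whose classes leave the entropy surface degenerate.
    """
    usable = [r for r in records if r.has_window]
    fvs = [normalize_features(r.f1_raw, r.f2_raw, r.f3_raw, ranges) for r in usable]
    labels = np.array([r.label for r in usable])
    ramps = []
    for name in ("f1", "f2", "f3"):
        vals = np.array([getattr(fv, name) for fv in fvs])
        m_high, m_low = _class_histograms(vals, labels)
        if m_high.sum() == 0 or m_low.sum() == 0:
            ramps.append(RampPair(0.25, 0.75, 0.25, 0.75))
            continue
        ramps.append(fit_membership_entropy(m_high, m_low, grid_step=grid_step))
    return MembershipParams(*ramps)


#: Broad symmetric default ramps: full membership below 0.25 / above 0.75,
#: linear in between. Used when no fitted or user-supplied params are given.
DEFAULT_MEMBERSHIP = MembershipParams(
    RampPair(0.25, 0.75, 0.25, 0.75),
    RampPair(0.25, 0.75, 0.25, 0.75),
    RampPair(0.25, 0.75, 0.25, 0.75),
)


def score_session(
    session: SyntheticSession,
    params: MembershipParams | Literal["fit"] | None = None,
    ranges: Mapping[str, tuple[float, float]] | None = None,
    mode: Literal["MIN", "MAX"] = "MIN",
    method: Literal["FOM", "MOM", "LOM", "COG", "BOA"] = "COG",
    stillness_threshold: float = STILLNESS_THRESHOLD,
) -> list[LabeledScore]:
    """Fuzzy output score per event with its ground-truth label.

    ``ranges`` defaults to self-calibration on this session; pass the
    clean session's ranges to hold the trained system fixed across
    noise conditions. ``params`` defaults to the broad symmetric ramps
    of :data:`DEFAULT_MEMBERSHIP`; pass ``"fit"`` to entropy-fit the
    membership functions from this session's labeled features. Events
    without a fixation window score 0 (no selection evidence).
    """
    records = extract_event_features(session, stillness_threshold=stillness_threshold)
    usable = [r for r in records if r.has_window]
    if ranges is None:
        ranges = feature_ranges(usable) if usable else None
    if params == "fit":
        params = fit_session_membership(records, ranges) if usable and ranges else None
    if params is None:
        params = DEFAULT_MEMBERSHIP
    out = []
    for r in records:
        if not r.has_window or ranges is None or params is None:
            out.append(LabeledScore(0.0, r.label))
            continue
        fv = normalize_features(r.f1_raw, r.f2_raw, r.f3_raw, ranges)
        out.append(LabeledScore(fuzzy_score(fv, params, mode=mode, method=method), r.label))
    return out
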