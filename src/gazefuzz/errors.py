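"""Exception hierarchy for the gazefuzz pipeline."""


class GazefuzzError(Exception):
    """Base class for all package-specific errors."""


class DegenerateHistogramError(GazefuzzError):
    """Automatic thresholding requested on an image with a flat histogram."""


class NoCircleError(GazefuzzError):
    """Circular Hough accumulator produced no peak above the vote floor."""


class SegmentationCollapseError(GazefuzzError):
    """Level-set region vanished or flooded its whole adaptive mask."""


class NoFixationError(GazefuzzError):
    """No sufficiently long low-motion run in the gaze trace."""


class WindowMismatchError(GazefuzzError):
    """Window and template lengths differ."""


class DegenerateCalibrationError(GazefuzzError):
    """The 4-point bilinear calibration system is singular."""


class GazeUnavailableError(GazefuzzError):
    """Neither eye produced a valid detection for the frame."""


class IncompleteDwellWindowError(GazefuzzError):
    """The dwell window covers frames without gaze estimates."""


class ROIOffScreenError(GazefuzzError):
    """Texture ROI is empty after clipping to the monitor image."""


class DegenerateFeatureRangeError(GazefuzzError):
    """Feature normalization range has max == min."""


class NonOverlappingRampsError(GazefuzzError):
    """Entropy fit found no ramp with non-zero class mass anywhere on the grid."""


class DegenerateEvaluationError(GazefuzzError):
    """Evaluation set contains only one class."""
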