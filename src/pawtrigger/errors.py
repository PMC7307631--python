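"""Exception hierarchy.

Every user-facing error names the offending field or frame so that a
misconfigured session fails loudly before any hardware (real or mock) is
touched.
"""


class PawTriggerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PawTriggerError):
    """A configuration value violates an invariant (names field + constraint)."""


class InputError(PawTriggerError):
    """Malformed replay input (length mismatch, non-monotone timestamps, ...)."""


class RenderError(PawTriggerError):
    """A keypoint fell outside the frame during rendering (names the frame)."""


class CalibrationError(PawTriggerError):
    """Invalid spatial calibration (non-positive mm-per-pixel scale)."""


class AlignmentError(PawTriggerError):
    """LED onsets cannot be aligned with logged trigger events."""


class ScheduleError(PawTriggerError):
    """Duplicate or inconsistent experiment schedule entries."""


class TruncatedTrialError(PawTriggerError):
    """Replay source exhausted before the buffer period completed."""


class InsufficientDataError(PawTriggerError):
    """A statistic was requested with too few observations."""
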