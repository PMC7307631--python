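"""Feedback-latency quantification, two ways, plus sampling/calibration utilities.

Time-stamp latency is internal: dispatch time minus the arrival time of the
frame carrying the criterion movement, straight from the trial log.
Ground-truth latency is external: the video itself is searched for the
feedback LED turning on, by thresholding the mean intensity of a region of
interest around the LED at ``baseline mean + 3 SD``; the latency is the
time from the movement frame's start to the first threshold crossing.
Frames inside an initial skip window (default 800 frames, where drops
cluster at trial start) are never searched.  Agreement of the two measures
on the same trials validates the software's own timestamps, assessed with
a paired t test across trials.

Also here: the Nyquist limit of a processed frame rate (half the rate — the
fastest movement frequency the stream can represent) and the pixel→mm
spatial calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import AlignmentError, CalibrationError, InputError, InsufficientDataError
from .runner import TrialRecord

__all__ = [
    "LedTrace",
    "LatencyResult",
    "roi_mean_trace",
    "timestamp_latency",
    "detect_flashes",
    "ground_truth_latency",
    "compare_latency_methods",
    "PairedTResult",
    "nyquist_limit",
    "px_to_mm",
]

_EPS_SD = 1e-6  # floor for a degenerate zero-variance baseline


@dataclass
class LedTrace:
    """Per-frame mean intensity of the LED ROI, with baseline statistics.

    ``baseline_mean``/``baseline_sd`` default to being estimated from the
    trace itself over frames after ``skip_frames``, optionally excluding
    guard windows around known trigger times (so the flashes being detected
    do not contaminate their own baseline).
    """

    intensity: np.ndarray
    timestamps_ms: np.ndarray
    roi: tuple[int, int, int, int] = (232, 0, 24, 24)
    skip_frames: int = 800
    baseline_mean: float | None = None
    baseline_sd: float | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if len(self.intensity) != len(self.timestamps_ms):
            raise InputError("intensity and timestamps differ in length")
        if self.skip_frames < 0:
            raise InputError("skip_frames must be >= 0")

    def fit_baseline(
        self,
        guard_times_ms: Sequence[float] = (),
        guard_ms: float = 400.0,
    ) -> None:
        """Estimate baseline mean/SD from post-skip frames outside guards."""
        mask = np.zeros(len(self.intensity), dtype=bool)
        mask[self.skip_frames :] = True
        for g in guard_times_ms:
            mask &= ~(
                (self.timestamps_ms >= g - 50.0)
                & (self.timestamps_ms <= g + guard_ms)
            )
        vals = self.intensity[mask]
        if vals.size == 0:
            raise InputError("no baseline frames left after skip/guard masking")
        self.baseline_mean = float(np.mean(vals))
        self.baseline_sd = float(np.std(vals))


@dataclass
class LatencyResult:
    """Per-trigger latencies with summary statistics."""

    latencies_ms: list[float]
    method: str  # "timestamp" | "ground_truth"
    unmatched: int = 0
    flagged_negative: int = 0

    @property
    def n(self) -> int:
        return len(self.latencies_ms)

    @property
    def mean(self) -> float:
        return float(np.mean(self.latencies_ms)) if self.latencies_ms else float("nan")

    @property
    def sd(self) -> float:
        return (
            float(np.std(self.latencies_ms, ddof=1))
            if len(self.latencies_ms) > 1
            else 0.0
        )


def roi_mean_trace(
    frames: np.ndarray, roi: tuple[int, int, int, int]
) -> np.ndarray:
    """Mean intensity of the (x, y, w, h) ROI in every frame."""
    x, y, w, h = roi
    return np.asarray(frames, dtype=float)[:, y : y + h, x : x + w].mean(axis=(1, 2))


def timestamp_latency(trial: TrialRecord) -> LatencyResult | None:
    """Per-event dispatch − movement-frame-arrival latency from the trial log.

    Returns None for a zero-event trial (the empty-result signal; such
    trials are excluded from latency summaries).
    """
    if not trial.events:
        return None
    lats = [
        e.dispatch_time - e.frame_time
        for e in trial.events
        if e.dispatch_time is not None
    ]
    return LatencyResult(latencies_ms=[float(v) for v in lats], method="timestamp")


def detect_flashes(
    trace: LedTrace, k_sd: float = 3.0, min_width_frames: int = 2
) -> list[int]:
    """Find LED flash onsets: first post-skip frames crossing mean + k·SD.

    The detector re-arms only after the intensity falls back below the
    threshold, so a sustained pulse yields exactly one onset.  A crossing
    must persist for ``min_width_frames`` consecutive frames to count:
    a k-SD threshold on a noisy baseline produces isolated single-frame
    false crossings at a small but nonzero rate, while a real LED pulse
    (hundreds of ms) spans many frames, so debouncing removes the former
    without touching the latter.  Frames at or before ``skip_frames`` are
    never reported.  A zero-variance baseline is floored at a tiny epsilon
    SD (with a warning) rather than producing a degenerate threshold.
    """
    if len(trace.intensity) <= trace.skip_frames:
        raise InputError(
            f"trace length {len(trace.intensity)} not longer than "
            f"skip_frames {trace.skip_frames}"
        )
    if trace.baseline_mean is None or trace.baseline_sd is None:
        trace.fit_baseline()
    sd = trace.baseline_sd
    if sd == 0.0:
        import warnings

        warnings.warn("zero-variance LED baseline; using epsilon SD floor")
        sd = _EPS_SD
    threshold = trace.baseline_mean + k_sd * sd

    onsets: list[int] = []
    # A flash already in progress at the skip boundary began before frame
    # skip_frames and is never reported; start disarmed in that case.
    armed = not (
        trace.skip_frames > 0
        and trace.intensity[trace.skip_frames - 1] > threshold
    )
    above = trace.intensity > threshold
    n = len(above)
    for i in range(trace.skip_frames, n):
        if above[i] and armed:
            width = 1
            while i + width < n and above[i + width]:
                width += 1
            if width >= min_width_frames or i + width == n:
                onsets.append(i)
            armed = False
        elif not above[i]:
            armed = True
    return onsets


def ground_truth_latency(
    onsets: Sequence[int],
    events: Sequence,
    timestamps_ms: Sequence[float],
    window_ms: float = 1000.0,
) -> LatencyResult:
    """Match each trigger to its nearest following LED onset; latency per event.

    ``events`` may be TriggerEvents or raw movement-frame times (ms).
    Events with no onset within ``window_ms`` are flagged unmatched; having
    more onsets than events is an alignment error (phantom flashes).
    """
    t = np.asarray(timestamps_ms, dtype=float)
    onset_times = sorted(float(t[i]) for i in onsets)
    event_times = [
        float(getattr(e, "frame_time", e)) for e in events
    ]
    if len(onset_times) > len(event_times):
        raise AlignmentError(
            f"{len(onset_times)} LED onsets but only {len(event_times)} logged "
            "events; check trigger log / ROI"
        )
    lats: list[float] = []
    unmatched = 0
    negative = 0
    used = 0
    for et in sorted(event_times):
        while used < len(onset_times) and onset_times[used] < et:
            used += 1
        if used < len(onset_times) and onset_times[used] - et <= window_ms:
            lat = onset_times[used] - et
            used += 1
            if lat < 0:
                negative += 1
            else:
                lats.append(lat)
        else:
            unmatched += 1
    return LatencyResult(
        latencies_ms=lats,
        method="ground_truth",
        unmatched=unmatched,
        flagged_negative=negative,
    )


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_difference: float
    zero_variance: bool = False


def compare_latency_methods(
    paired_means: Sequence[tuple[float, float]]
) -> PairedTResult:
    """Paired t test on per-trial (timestamp, ground-truth) mean latencies.

    Identical pairs (all differences zero) are reported as the
    zero-variance case with an undefined statistic rather than an error.
    """
    if len(paired_means) < 2:
        raise InsufficientDataError(
            f"paired t needs >= 2 trials, got {len(paired_means)}"
        )
    a = np.array([p[0] for p in paired_means], dtype=float)
    b = np.array([p[1] for p in paired_means], dtype=float)
    diffs = a - b
    if np.allclose(np.std(diffs, ddof=1), 0.0):
        return PairedTResult(
            t=float("nan"),
            df=len(diffs) - 1,
            p=1.0,
            mean_difference=float(np.mean(diffs)),
            zero_variance=True,
        )
    res = stats.ttest_rel(a, b)
    return PairedTResult(
        t=float(res.statistic),
        df=len(diffs) - 1,
        p=float(res.pvalue),
        mean_difference=float(np.mean(diffs)),
    )


def nyquist_limit(output_rate_hz: float) -> float:
    """Highest movement frequency representable at a processed frame rate.

    By the Nyquist–Shannon sampling theorem the stream must run at at least
    twice the frequency of the fastest movement sampled, so the limit is
    half the rate, reported to two decimals.
    """
    if not math.isfinite(output_rate_hz) or output_rate_hz < 0:
        raise InputError(f"frame rate must be finite >= 0, got {output_rate_hz}")
    return round(output_rate_hz / 2.0, 2)


def px_to_mm(displacement_px: float, mm_per_px: float) -> float:
    """Convert a pixel displacement to millimetres with a scene calibration.

    The scale comes from measuring a known scene dimension (e.g. the width
    of the tube floor) in both millimetres and pixels; it is a required
    input, not a constant of the method.
    """
    if not (math.isfinite(mm_per_px) and mm_per_px > 0):
        raise CalibrationError(f"mm-per-pixel scale must be > 0, got {mm_per_px}")
    return displacement_px * mm_per_px
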