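"""Ground-truthed synthetic sessions: scripted paw motion, rendered frames, LED.

A :class:`MotionScript` describes a head-fixed forepaw session the way the
rig would see it: vertical left- or right-paw reaches of chosen amplitude
and speed, grooming-like intervals where both paws co-move, per-frame
tracking jitter, random frame drops, and timestamp jitter.  From a script,
:func:`generate_pose_trace` produces the 8-digit keypoint trace the pose
backend would emit plus a :class:`GroundTruth` record of everything the
downstream pipeline is supposed to recover (dropped frames, expected
trigger frames, LED flash onsets once scheduled).  :func:`render_frames`
turns a trace into 8-bit video with high-contrast digit markers and a
feedback LED rendered in a fixed corner ROI, closing the loop for the
marker-centroid oracle backend and the LED-contrast latency analysis.

Everything is deterministic under a fixed seed; identical script + seed
give bit-identical output.

Reaches are smooth half-cosine ramps (up then back down), so the
displacement seen across one frame pair depends on the frame rate: a slow
reach sampled fast may never cross the per-pair threshold, the discrete
analogue of the sampling-adequacy argument the latency module quantifies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CriterionConfig
from .errors import ConfigurationError, RenderError
from .pose import DIGIT_LABELS

__all__ = [
    "ReachEvent",
    "MotionScript",
    "GroundTruth",
    "PoseTrace",
    "generate_pose_trace",
    "render_frames",
    "default_led_roi",
    "roi_center",
    "random_script",
    "learning_experiment_schedule",
    "write_pose_csv",
    "read_pose_csv",
    "write_frames_tiff",
    "read_frames_tiff",
]

# Nominal digit layout (px, 256x256 frame): four digits per paw, spaced so
# rendered markers never merge; y grows downward, so a reach decreases y.
_LEFT_X = np.array([70.0, 82.0, 94.0, 106.0])
_RIGHT_X = np.array([150.0, 162.0, 174.0, 186.0])
_BASE_Y = 190.0


@dataclass(frozen=True)
class ReachEvent:
    """One scripted vertical reach: half-cosine up then down.

    ``rise`` is the time (s) from rest to peak; the return takes another
    ``rise`` seconds, so the whole excursion lasts ``2 * rise``.
    """

    onset: float
    paw: str
    amplitude: float
    rise: float = 0.1

    def __post_init__(self) -> None:
        if self.paw not in ("left", "right", "both"):
            raise ConfigurationError(
                f"reach paw must be left|right|both, got {self.paw!r}"
            )
        if not (math.isfinite(self.onset) and self.onset >= 0):
            raise ConfigurationError(f"reach onset must be finite >= 0, got {self.onset}")
        if not (math.isfinite(self.amplitude) and self.amplitude >= 0):
            raise ConfigurationError(
                f"reach amplitude must be finite >= 0, got {self.amplitude}"
            )
        if not (math.isfinite(self.rise) and self.rise > 0):
            raise ConfigurationError(f"reach rise must be finite > 0, got {self.rise}")


@dataclass(frozen=True)
class MotionScript:
    """Full description of a synthetic session.

    Defaults mirror the nominal rig conditions: 130 s trials streamed at
    200 Hz, with roughly two thirds of frames dropped in acquisition (which
    brings the processed rate near 66 Hz) and ~4 ms timestamp jitter.
    Reach amplitudes are free parameters of the bench, not measured values.
    """

    duration: float = 130.0
    frame_rate: float = 200.0
    reach_events: tuple[ReachEvent, ...] = ()
    baseline_jitter_sd: float = 0.5
    grooming_intervals: tuple[tuple[float, float], ...] = ()
    grooming_amplitude: float = 40.0
    grooming_rate: float = 2.0
    grooming_rise: float = 0.05
    drop_probability: float = 0.67
    timestamp_jitter_sd: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.duration) and self.duration > 0):
            raise ConfigurationError(f"duration must be finite > 0, got {self.duration}")
        if not (math.isfinite(self.frame_rate) and self.frame_rate > 0):
            raise ConfigurationError(
                f"frame_rate must be finite > 0, got {self.frame_rate}"
            )
        if not 0.0 <= self.drop_probability <= 1.0:
            raise ConfigurationError(
                f"drop_probability must be in [0, 1], got {self.drop_probability}"
            )
        for name in ("baseline_jitter_sd", "timestamp_jitter_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigurationError(f"{name} must be finite >= 0, got {v}")
        for ev in self.reach_events:
            if not 0 <= ev.onset < self.duration:
                raise ConfigurationError(
                    f"reach onset {ev.onset} outside [0, {self.duration})"
                )
        for a, b in self.grooming_intervals:
            if not 0 <= a < b <= self.duration:
                raise ConfigurationError(
                    f"grooming interval ({a}, {b}) invalid for duration {self.duration}"
                )

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    """Everything the pipeline should recover from a synthetic session."""

    digit_positions: np.ndarray  # (n_total, 8, 2) float, all frames incl. dropped
    timestamps_ms: np.ndarray  # (n_total,) non-decreasing
    dropped_frame_indices: list[int]
    expected_trigger_frames: list[int]  # second-frame index of each expected trigger
    led_flash_onsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.expected_trigger_frames
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ConfigurationError(
                "expected_trigger_frames must be strictly increasing"
            )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_frames": int(len(self.digit_positions)),
                    "dropped_frame_indices": list(map(int, self.dropped_frame_indices)),
                    "expected_trigger_frames": list(
                        map(int, self.expected_trigger_frames)
                    ),
                    "led_flash_onsets": list(map(int, self.led_flash_onsets)),
                    "timestamps_ms": [float(t) for t in self.timestamps_ms],
                },
                indent=1,
            )
        )


@dataclass
class PoseTrace:
    """Keypoint trace over the surviving (non-dropped) frames of a session."""

    frame_indices: np.ndarray  # (n,) original frame numbers, strictly increasing
    timestamps_ms: np.ndarray  # (n,)
    positions: np.ndarray  # (n, 8, 2)
    confidences: np.ndarray  # (n, 8)
    frame_rate: float
    n_total: int
    dropped_frame_indices: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame_indices)

    def mean_paw_y(self) -> np.ndarray:
        """(n, 2) array of per-frame mean y for (left, right) paws."""
        return np.stack(
            [
                self.positions[:, :4, 1].mean(axis=1),
                self.positions[:, 4:, 1].mean(axis=1),
            ],
            axis=1,
        )


def _reach_offset(t: np.ndarray, ev: ReachEvent) -> np.ndarray:
    """Vertical offset (negative = upward) of one half-cosine reach at times t."""
    out = np.zeros_like(t)
    up = (t >= ev.onset) & (t < ev.onset + ev.rise)
    down = (t >= ev.onset + ev.rise) & (t < ev.onset + 2 * ev.rise)
    out[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - ev.onset) / ev.rise))
    out[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - ev.onset - ev.rise) / ev.rise))
    return -ev.amplitude * out


def _expected_triggers(
    mean_y: np.ndarray,
    kept_times: np.ndarray,
    kept_indices: np.ndarray,
    criterion: CriterionConfig,
) -> list[int]:
    """Minimal scan of the trigger rules over non-overlapping surviving pairs.

    Kept deliberately simple and separate from the engine: it is the
    generator's own account of which frames should trigger, used to
    cross-check both the online engine and the offline oracle.
    """
    out: list[int] = []
    last_time: float | None = None
    n_pairs = len(mean_y) // 2
    for p in range(n_pairs):
        i, j = 2 * p, 2 * p + 1
        dy_l = abs(mean_y[j, 0] - mean_y[i, 0])
        dy_r = abs(mean_y[j, 1] - mean_y[i, 1])
        t = float(kept_times[j])
        right_ok = dy_r <= criterion.max_right if criterion.right_bound_inclusive else dy_r < criterion.max_right
        if (
            criterion.min_left <= dy_l <= criterion.max_left
            and right_ok
            and (last_time is None or t - last_time > criterion.refractory)
        ):
            out.append(int(kept_indices[j]))
            last_time = t
    return out


def generate_pose_trace(
    script: MotionScript,
    criterion: CriterionConfig | None = None,
) -> tuple[PoseTrace, GroundTruth]:
    """Generate the keypoint trace and ground truth for a scripted session.

    The trace covers only surviving frames (drops removed); the ground
    truth records every frame, which frames were dropped, and the frame
    indices on which the default trigger criterion should fire given the
    non-overlapping pairing of surviving frames.
    """
    criterion = criterion or CriterionConfig()
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    t = np.arange(n) / script.frame_rate

    # Coherent per-paw vertical offsets from scripted reaches.
    offset = np.zeros((n, 2))  # (left, right)
    for ev in script.reach_events:
        o = _reach_offset(t, ev)
        if ev.paw in ("left", "both"):
            offset[:, 0] += o
        if ev.paw in ("right", "both"):
            offset[:, 1] += o
    # Grooming: fast, correlated co-reaches of both paws.
    for a, b in script.grooming_intervals:
        onset = a
        while onset + 2 * script.grooming_rise <= b:
            ev = ReachEvent(onset, "both", script.grooming_amplitude, script.grooming_rise)
            o = _reach_offset(t, ev)
            offset[:, 0] += o
            offset[:, 1] += o
            onset += 1.0 / script.grooming_rate

    positions = np.empty((n, 8, 2))
    positions[:, :4, 0] = _LEFT_X
    positions[:, 4:, 0] = _RIGHT_X
    positions[:, :4, 1] = _BASE_Y + offset[:, 0:1]
    positions[:, 4:, 1] = _BASE_Y + offset[:, 1:2]
    if script.baseline_jitter_sd > 0:
        positions += rng.normal(0, script.baseline_jitter_sd, positions.shape)
    np.clip(positions, 4.0, 251.0, out=positions)

    timestamps = 1000.0 * t
    if script.timestamp_jitter_sd > 0:
        timestamps = timestamps + rng.normal(0, script.timestamp_jitter_sd, n)
        timestamps = np.maximum.accumulate(timestamps)
        timestamps -= timestamps[0]

    dropped = (
        np.flatnonzero(rng.random(n) < script.drop_probability)
        if script.drop_probability > 0
        else np.array([], dtype=int)
    )
    kept = np.setdiff1d(np.arange(n), dropped)

    trace = PoseTrace(
        frame_indices=kept,
        timestamps_ms=timestamps[kept],
        positions=positions[kept],
        confidences=np.ones((len(kept), 8)),
        frame_rate=script.frame_rate,
        n_total=n,
        dropped_frame_indices=[int(i) for i in dropped],
    )
    mean_y = trace.mean_paw_y()
    gt = GroundTruth(
        digit_positions=positions,
        timestamps_ms=timestamps,
        dropped_frame_indices=[int(i) for i in dropped],
        expected_trigger_frames=_expected_triggers(
            mean_y, trace.timestamps_ms, kept, criterion
        ),
    )
    return trace, gt


def default_led_roi(resolution: tuple[int, int] = (256, 256)) -> tuple[int, int, int, int]:
    """Fixed LED ROI: the top-right 24 x 24 px corner, as (x, y, w, h)."""
    h, w = resolution
    return (w - 24, 0, 24, 24)


def roi_center(roi: tuple[int, int, int, int]) -> tuple[float, float]:
    x, y, w, h = roi
    return (x + w / 2.0, y + h / 2.0)


def render_frames(
    positions: np.ndarray,
    led_schedule: Sequence[tuple[int, int]] = (),
    resolution: tuple[int, int] = (256, 256),
    led_roi: tuple[int, int, int, int] | None = None,
    background: int = 16,
    marker_value: int = 255,
    marker_radius: float = 2.0,
    led_value: int = 255,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Render a pose trace into an 8-bit frame stack.

    Each frame shows the 8 digit tips as bright discs on a flat background,
    plus a bright disc centered in the LED ROI on frames covered by the
    schedule (a list of ``(onset_frame, n_frames)`` pulses).  Optional
    Gaussian pixel noise is added last and clipped to [0, 255].
    """
    positions = np.asarray(positions, dtype=float)
    h, w = int(resolution[0]), int(resolution[1])
    if h < 64 or w < 64:
        raise ConfigurationError(f"resolution must be >= 64x64, got {resolution}")
    n = len(positions)
    roi = led_roi if led_roi is not None else default_led_roi((h, w))

    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = roi_center(roi)
    led_disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= (min(roi[2], roi[3]) / 3.0) ** 2

    flash_on = np.zeros(n, dtype=bool)
    for onset, length in led_schedule:
        flash_on[max(0, int(onset)) : int(onset) + int(length)] = True

    rng = np.random.default_rng(seed)
    frames = np.empty((n, h, w), dtype=np.uint8)
    r2 = marker_radius**2
    for i in range(n):
        img = np.full((h, w), background, dtype=float)
        for k in range(8):
            x, y = positions[i, k]
            if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
                raise RenderError(
                    f"frame {i}: keypoint {DIGIT_LABELS[k]} at ({x:.1f}, {y:.1f}) "
                    f"outside {w}x{h} frame"
                )
            x0, x1 = int(max(0, x - marker_radius - 1)), int(min(w, x + marker_radius + 2))
            y0, y1 = int(max(0, y - marker_radius - 1)), int(min(h, y + marker_radius + 2))
            sub_y, sub_x = np.mgrid[y0:y1, x0:x1]
            disc = (sub_x - x) ** 2 + (sub_y - y) ** 2 <= r2
            img[y0:y1, x0:x1][disc] = marker_value
        if flash_on[i]:
            img[led_disc] = led_value
        if noise_sd > 0:
            img += rng.normal(0, noise_sd, (h, w))
        frames[i] = np.clip(img, 0, 255).astype(np.uint8)
    return frames


def random_script(
    rng: np.random.Generator,
    duration_range: tuple[float, float] = (20.0, 40.0),
    frame_rate_choices: Sequence[float] = (50.0, 100.0),
    reach_rate_range: tuple[float, float] = (0.2, 1.0),
    amplitude_range: tuple[float, float] = (10.0, 80.0),
    rise_range: tuple[float, float] = (0.05, 0.15),
    right_paw_fraction: float = 0.3,
    grooming_probability: float = 0.5,
    drop_probability_range: tuple[float, float] = (0.0, 0.3),
    timestamp_jitter_range: tuple[float, float] = (0.0, 4.0),
) -> MotionScript:
    """Draw a randomized session script for fuzz/equivalence testing.

    Varies duration, frame rate, reach rate/amplitude/speed on both paws,
    grooming, frame drops, and timestamp jitter; every draw comes from the
    supplied generator so a seeded caller gets reproducible scripts.
    """
    duration = float(rng.uniform(*duration_range))
    frame_rate = float(rng.choice(list(frame_rate_choices)))
    n_reaches = rng.poisson(rng.uniform(*reach_rate_range) * duration)
    events = []
    for _ in range(n_reaches):
        events.append(
            ReachEvent(
                onset=float(rng.uniform(0, duration - 0.5)),
                paw="right" if rng.random() < right_paw_fraction else "left",
                amplitude=float(rng.uniform(*amplitude_range)),
                rise=float(rng.uniform(*rise_range)),
            )
        )
    grooming: list[tuple[float, float]] = []
    if rng.random() < grooming_probability and duration > 8:
        start = float(rng.uniform(0, duration - 5))
        grooming.append((start, start + float(rng.uniform(2, 4))))
    return MotionScript(
        duration=duration,
        frame_rate=frame_rate,
        reach_events=tuple(sorted(events, key=lambda e: e.onset)),
        baseline_jitter_sd=float(rng.uniform(0, 1.0)),
        grooming_intervals=tuple(grooming),
        drop_probability=float(rng.uniform(*drop_probability_range)),
        timestamp_jitter_sd=float(rng.uniform(*timestamp_jitter_range)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def learning_experiment_schedule(
    n_mice: int = 7,
    n_days: int = 5,
    trials_per_mode: int = 21,
    trial_duration: float = 20.0,
    frame_rate: float = 50.0,
    baseline_rate: float = 0.4,
    training_rates: Sequence[float] | None = None,
    amplitude: float = 40.0,
    rise: float = 0.1,
    seed: int = 0,
) -> list[dict]:
    """Script a multi-day learning experiment: rising training reach rate, flat baseline.

    Emulates the structure of a conditioning study in which animals make
    progressively more criterion reaches on training trials across days
    while baseline trials stay flat.  ``training_rates`` gives the mean
    reach rate (reaches/s) per day; the default rises from the baseline
    rate on day 1 and saturates after day 3.  Returns a flat list of trial
    dicts (mouse, day, trial, mode, script) with alternating modes.
    """
    if training_rates is None:
        ramp = np.linspace(baseline_rate, 3.0 * baseline_rate, min(3, n_days))
        training_rates = list(ramp) + [3.0 * baseline_rate] * (n_days - len(ramp))
    if len(training_rates) != n_days:
        raise ConfigurationError(
            f"training_rates must have one rate per day ({n_days}), got {len(training_rates)}"
        )
    rng = np.random.default_rng(seed)
    schedule: list[dict] = []
    for m in range(n_mice):
        for day in range(1, n_days + 1):
            for trial in range(trials_per_mode):
                for k, mode in enumerate(("baseline", "training")):
                    rate = baseline_rate if mode == "baseline" else training_rates[day - 1]
                    n_reaches = max(1, int(rng.poisson(rate * trial_duration)))
                    # spaced beyond the refractory so each reach can trigger
                    onsets = np.sort(
                        rng.uniform(0.5, trial_duration - 0.5, n_reaches)
                    )
                    events = tuple(
                        ReachEvent(float(o), "left", amplitude, rise) for o in onsets
                    )
                    schedule.append(
                        {
                            "mouse": f"m{m + 1}",
                            "day": day,
                            "trial": 2 * trial + k,
                            "mode": mode,
                            "script": MotionScript(
                                duration=trial_duration,
                                frame_rate=frame_rate,
                                reach_events=events,
                                baseline_jitter_sd=0.5,
                                drop_probability=0.05,
                                timestamp_jitter_sd=1.0,
                                seed=int(rng.integers(0, 2**31 - 1)),
                            ),
                        }
                    )
    return schedule


# ---------------------------------------------------------------------------
# I/O: DeepLabCut-dialect pose CSV, TIFF stacks, JSON sidecars


def write_pose_csv(trace: PoseTrace, path: str | Path, scorer: str = "synthetic") -> None:
    """Write a pose trace as CSV with the three-row scorer/bodyparts/coords header."""
    cols = pd.MultiIndex.from_product(
        [[scorer], list(DIGIT_LABELS), ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    data = np.concatenate(
        [trace.positions, trace.confidences[:, :, None]], axis=2
    ).reshape(len(trace), 24)
    df = pd.DataFrame(data, index=trace.frame_indices, columns=cols)
    df.index.name = "frame"
    df.to_csv(path)


def read_pose_csv(path: str | Path, frame_rate: float = 200.0) -> PoseTrace:
    """Read a pose CSV written by :func:`write_pose_csv` (or any equivalent dialect)."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    bodyparts = list(dict.fromkeys(df.columns.get_level_values(1)))
    n = len(df)
    positions = np.empty((n, 8, 2))
    confidences = np.empty((n, 8))
    scorer = df.columns.get_level_values(0)[0]
    for k, bp in enumerate(bodyparts[:8]):
        positions[:, k, 0] = df[(scorer, bp, "x")].to_numpy()
        positions[:, k, 1] = df[(scorer, bp, "y")].to_numpy()
        confidences[:, k] = df[(scorer, bp, "likelihood")].to_numpy()
    indices = df.index.to_numpy().astype(int)
    return PoseTrace(
        frame_indices=indices,
        timestamps_ms=1000.0 * indices / frame_rate,
        positions=positions,
        confidences=confidences,
        frame_rate=frame_rate,
        n_total=int(indices[-1]) + 1 if n else 0,
    )


def write_frames_tiff(frames: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), frames, photometric="minisblack")


def read_frames_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
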