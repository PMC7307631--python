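"""Trial and experiment orchestration.

A trial streams frames for ``buffer + recording`` seconds (nominally
10 + 120 s): during the buffer the full analysis runs but nothing is
persisted and no feedback is delivered; after the buffer and a short
settling wait, every frame pair is evaluated, triggers are dispatched, and
the labelled pair log is persisted.  An experiment is a schedule of
alternating baseline/training trials across mice and days whose records
feed the behavior statistics.

Quality control mirrors standard practice for this kind of rig: trials
with a mean time-stamp latency above a cutoff (default 500 ms, i.e. a
malfunctioning feedback path) or training trials with zero above-criterion
events can be excluded before summaries; exclusion is declarative and
logged, never silent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import CriterionConfig, SessionConfig
from .engine import TriggerEngine, TriggerEvent
from .errors import ScheduleError, TruncatedTrialError
from .feedback import Dispatcher, FeedbackEvent, MockDevice, set_cue
from .pose import PoseBackend, ReplayBackend
from .stream import DropLedger, PairStream, ReplaySource
from .synthetic import MotionScript, PoseTrace, generate_pose_trace

__all__ = [
    "TrialRecord",
    "run_trial",
    "run_trial_from_trace",
    "run_experiment",
    "apply_qc",
    "save_trials",
    "load_trials",
]


@dataclass
class TrialRecord:
    """Complete, self-consistent record of one trial."""

    mouse_id: str
    day: int
    mode: str
    trial: int = 0
    session: SessionConfig = field(default_factory=SessionConfig)
    criterion: CriterionConfig = field(default_factory=CriterionConfig)
    processed: int = 0
    dropped: int = 0
    mean_output_rate_hz: float = 0.0
    events: list[TriggerEvent] = field(default_factory=list)
    feedback: list[FeedbackEvent] = field(default_factory=list)
    feedback_misses: int = 0
    truncated: bool = False
    excluded: bool = False
    exclusion_reason: str = ""

    @property
    def trigger_count(self) -> int:
        return len(self.events)

    def mean_timestamp_latency(self) -> float:
        """Mean dispatch − frame-arrival latency (ms) over this trial's events."""
        lats = [
            e.dispatch_time - e.frame_time
            for e in self.events
            if e.dispatch_time is not None
        ]
        return float(np.mean(lats)) if lats else float("nan")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["session"]["resolution"] = list(self.session.resolution)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialRecord":
        d = dict(d)
        sess = dict(d.pop("session"))
        sess["resolution"] = tuple(sess["resolution"])
        d["session"] = SessionConfig(**sess)
        d["criterion"] = CriterionConfig(**d.pop("criterion"))
        d["events"] = [TriggerEvent(**e) for e in d.pop("events")]
        d["feedback"] = [FeedbackEvent(**f) for f in d.pop("feedback")]
        return cls(**d)


def run_trial(
    source: ReplaySource,
    backend: PoseBackend,
    session: SessionConfig,
    criterion: CriterionConfig | None = None,
    mode: str = "baseline",
    device: MockDevice | None = None,
    mouse_id: str = "m1",
    day: int = 1,
    trial: int = 0,
) -> TrialRecord:
    """Run one full trial over a frame source.

    Buffer-period pairs are analyzed but can neither trigger nor persist;
    after ``buffer + post_buffer_wait`` every pair is armed.  Each trigger
    dispatches feedback through the (virtual-clock) dispatcher, so
    ``dispatch_time = decision_time + device latency`` deterministically.
    """
    criterion = criterion or CriterionConfig()
    device = device if device is not None else MockDevice()
    engine = TriggerEngine(criterion)
    dispatcher = Dispatcher(device, mode, criterion, clock="virtual")
    ledger = DropLedger()
    pairs = PairStream(source, ledger)

    buffer_end = 1000.0 * session.buffer_duration
    armed_from = buffer_end + session.post_buffer_wait
    trial_end = 1000.0 * session.trial_length
    set_cue(mode, device, 0.0, trial_end)

    events: list[TriggerEvent] = []
    last_time = 0.0
    for pair_index, pair in enumerate(pairs):
        first = backend.estimate(pair.first)
        second = backend.estimate(pair.second)
        t = pair.second.acquisition_time
        last_time = max(last_time, t)
        armed = t >= armed_from
        _, decision = engine.process(first, second, pair_index, t, armed=armed)
        if decision.triggered:
            decision_time = t + session.processing_delay_ms
            dispatcher.dispatch(decision_time)
            events.append(
                TriggerEvent(
                    pair_index=pair_index,
                    frame_index=pair.second.index,
                    frame_time=t,
                    decision_time=decision_time,
                    dispatch_time=decision_time + device.latency_ms,
                    dy_left=engine.decisions[-1][0].dy_left,
                    dy_right=engine.decisions[-1][0].dy_right,
                    confidence=engine.decisions[-1][0].confidence,
                )
            )
    dispatcher.close()

    if last_time < buffer_end:
        raise TruncatedTrialError(
            f"source exhausted at {last_time:.0f} ms, before the "
            f"{buffer_end:.0f} ms buffer completed"
        )
    truncated = last_time < 0.95 * trial_end

    recording_ms = max(last_time - armed_from, 1e-9)
    rec_times = [t for t in ledger.processed_times if t >= armed_from]
    rate = 1000.0 * len(rec_times) / recording_ms

    return TrialRecord(
        mouse_id=mouse_id,
        day=day,
        mode=mode,
        trial=trial,
        session=session,
        criterion=criterion,
        processed=ledger.processed,
        dropped=ledger.dropped,
        mean_output_rate_hz=float(rate),
        events=events,
        feedback=list(dispatcher.events),
        feedback_misses=dispatcher.misses,
        truncated=truncated,
    )


def run_trial_from_trace(
    trace: PoseTrace,
    session: SessionConfig,
    criterion: CriterionConfig | None = None,
    mode: str = "baseline",
    device: MockDevice | None = None,
    **ids,
) -> TrialRecord:
    """Run a trial by replaying a stored pose trace (no video needed)."""
    dropped_times = {
        int(i): float(np.interp(i, trace.frame_indices, trace.timestamps_ms))
        for i in trace.dropped_frame_indices
    }
    source = ReplaySource(
        None,
        trace.timestamps_ms,
        indices=trace.frame_indices,
        placeholder_indices=trace.dropped_frame_indices,
        placeholder_times=dropped_times,
    )
    backend = ReplayBackend(
        trace.positions, trace.confidences, trace.frame_indices
    )
    return run_trial(
        source, backend, session, criterion, mode, device, **ids
    )


def run_experiment(
    schedule: Sequence[dict],
    session: SessionConfig,
    criterion: CriterionConfig | None = None,
) -> list[TrialRecord]:
    """Run every scheduled trial of a (synthetic) multi-day experiment.

    Each schedule entry carries ``mouse``, ``day``, ``trial``, ``mode`` and
    either a ``script`` (:class:`MotionScript`) or a pre-generated
    ``trace``.  Duplicate (mouse, day, trial) keys are a schedule error.
    """
    if not schedule:
        raise ScheduleError("schedule is empty")
    seen: set[tuple] = set()
    records: list[TrialRecord] = []
    for entry in schedule:
        key = (entry["mouse"], entry["day"], entry["trial"])
        if key in seen:
            raise ScheduleError(f"duplicate schedule entry {key}")
        seen.add(key)
        trace = entry.get("trace")
        if trace is None:
            script: MotionScript = entry["script"]
            trace, _ = generate_pose_trace(script, criterion)
        records.append(
            run_trial_from_trace(
                trace,
                session,
                criterion,
                mode=entry["mode"],
                mouse_id=entry["mouse"],
                day=entry["day"],
                trial=entry["trial"],
            )
        )
    return records


def apply_qc(
    records: Sequence[TrialRecord],
    max_mean_latency_ms: float = 500.0,
    exclude_zero_event_training: bool = True,
) -> list[TrialRecord]:
    """Flag excluded trials; returns the records with exclusion fields set.

    Applied before summary statistics, matching the convention that
    malfunctioning trials (grossly delayed feedback) and uninformative
    training trials (no above-criterion movement at all) do not enter
    summaries.
    """
    out = []
    for r in records:
        r = dataclasses.replace(r)
        lat = r.mean_timestamp_latency()
        if np.isfinite(lat) and lat > max_mean_latency_ms:
            r.excluded, r.exclusion_reason = True, "mean_latency"
        elif exclude_zero_event_training and r.mode == "training" and not r.events:
            r.excluded, r.exclusion_reason = True, "zero_events"
        out.append(r)
    return out


def save_trials(records: Sequence[TrialRecord], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([r.to_dict() for r in records], indent=None)
    )


def load_trials(path: str | Path) -> list[TrialRecord]:
    return [TrialRecord.from_dict(d) for d in json.loads(Path(path).read_text())]
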