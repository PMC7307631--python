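"""Feedback output: mock GPIO device, pulse scheduling, asynchronous dispatch.

Feedback on a trigger is a 200 ms red LED pulse, accompanied on training
trials by a 150 ms water-valve pulse (both onsets simultaneous).  Training
trials are additionally cued by a green LED held on for the whole trial.
The device abstraction is a single ``set_channel(name, level)`` call so any
real GPIO board can be adapted; the shipped :class:`MockDevice` records a
millisecond-stamped timeline of channel transitions instead of toggling
hardware.

Two clock modes exist.  ``virtual`` (replay analytics) is deterministic:
the dispatch timestamp is the trigger time plus the device's modelled
latency.  ``wall`` exercises the real concurrency contract: dispatch and
persistence each run on their own queue-fed worker thread so neither can
block the evaluation path, and timestamps are wall-clock.
"""

from __future__ import annotations

import queue
import threading
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .config import CriterionConfig
from .errors import InputError

__all__ = [
    "FeedbackEvent",
    "GPIODevice",
    "MockDevice",
    "Dispatcher",
    "set_cue",
    "AsyncWorker",
    "write_device_timeline",
]

CHANNELS = ("red_led", "water", "green_cue")


@dataclass(frozen=True)
class FeedbackEvent:
    """One delivered feedback: channels pulsed and their timing."""

    trigger_time: float
    dispatch_time: float
    channels: tuple[str, ...]
    pulse_lengths: dict[str, float]

    def __post_init__(self) -> None:
        if self.dispatch_time < self.trigger_time:
            raise InputError("dispatch_time must be >= trigger_time")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise InputError(f"unknown feedback channel(s): {sorted(unknown)}")


class GPIODevice:
    """Output-device contract: a named channel driven high or low."""

    def set_channel(self, name: str, level: bool) -> None:  # pragma: no cover
        raise NotImplementedError


class MockDevice(GPIODevice):
    """Records channel transitions instead of driving hardware.

    ``latency_ms`` models the command-to-device leg; in wall mode it is an
    actual sleep before the transition is recorded, in virtual mode it is
    added arithmetically.  ``fail`` makes every call raise, to exercise the
    feedback-miss path.
    """

    def __init__(self, latency_ms: float = 0.0, fail: bool = False) -> None:
        self.latency_ms = float(latency_ms)
        self.fail = fail
        self.transitions: list[tuple[str, float, bool]] = []
        self._lock = threading.Lock()

    def set_channel(self, name: str, level: bool, at_ms: float | None = None) -> None:
        if self.fail:
            raise IOError(f"mock device failure on channel {name}")
        if at_ms is None:  # wall mode: latency is real time
            if self.latency_ms > 0:
                time.sleep(self.latency_ms / 1000.0)
            at_ms = time.monotonic() * 1000.0
        with self._lock:
            self.transitions.append((name, float(at_ms), level))

    def pulses(self, channel: str) -> list[tuple[float, float]]:
        """(t_on, t_off) pairs for one channel, from the transition record."""
        ts = sorted(
            [(t, lvl) for ch, t, lvl in self.transitions if ch == channel],
            key=lambda x: x[0],
        )
        out: list[tuple[float, float]] = []
        t_on: float | None = None
        for t, lvl in ts:
            if lvl and t_on is None:
                t_on = t
            elif not lvl and t_on is not None:
                out.append((t_on, t))
                t_on = None
        return out


class AsyncWorker:
    """A queue-fed worker thread: submit items, a sink consumes them.

    Used for both labelled-frame persistence and feedback dispatch so that
    a slow sink (disk, device) never blocks the frame-evaluation loop.
    """

    def __init__(self, sink: Callable, name: str = "worker") -> None:
        self._queue: queue.Queue = queue.Queue()
        self._sink = sink
        self.errors: list[Exception] = []
        self._thread = threading.Thread(target=self._run, name=name, daemon=True)
        self._thread.start()

    def _run(self) -> None:
        while True:
            item = self._queue.get()
            if item is None:
                self._queue.task_done()
                return
            try:
                self._sink(item)
            except Exception as exc:  # sink failures are counted, not fatal
                self.errors.append(exc)
            finally:
                self._queue.task_done()

    def submit(self, item) -> None:
        self._queue.put(item)

    def close(self) -> None:
        self._queue.put(None)
        self._queue.join()
        self._thread.join(timeout=5.0)


class Dispatcher:
    """Schedules feedback pulses on trigger decisions.

    ``mode`` selects the channel set: baseline pulses the red LED only;
    training adds the water valve (simultaneous onsets).  Device failures
    are logged as feedback misses and the session continues.
    """

    def __init__(
        self,
        device: MockDevice,
        mode: str,
        config: CriterionConfig | None = None,
        clock: str = "virtual",
    ) -> None:
        if mode not in ("baseline", "training"):
            raise InputError(f"mode must be baseline|training, got {mode!r}")
        if clock not in ("virtual", "wall"):
            raise InputError(f"clock must be virtual|wall, got {clock!r}")
        self.device = device
        self.mode = mode
        self.config = config or CriterionConfig()
        self.clock = clock
        self.events: list[FeedbackEvent] = []
        self.misses: int = 0
        self._worker = (
            AsyncWorker(self._deliver, name="dispatch") if clock == "wall" else None
        )
        self._lock = threading.Lock()

    def _channel_plan(self) -> dict[str, float]:
        plan = {"red_led": self.config.led_pulse}
        if self.mode == "training":
            plan["water"] = self.config.water_pulse
        return plan

    def _deliver(self, trigger_time: float) -> None:
        plan = self._channel_plan()
        try:
            if self.clock == "virtual":
                dispatch_time = trigger_time + self.device.latency_ms
                for ch, pulse in plan.items():
                    self.device.set_channel(ch, True, at_ms=dispatch_time)
                    self.device.set_channel(ch, False, at_ms=dispatch_time + pulse)
            else:
                before = time.monotonic() * 1000.0
                for ch in plan:
                    self.device.set_channel(ch, True)
                dispatch_time = max(time.monotonic() * 1000.0, trigger_time)
                for ch, pulse in plan.items():
                    self.device.set_channel(ch, False, at_ms=dispatch_time + pulse)
                del before
        except IOError:
            with self._lock:
                self.misses += 1
            return
        with self._lock:
            self.events.append(
                FeedbackEvent(
                    trigger_time=trigger_time,
                    dispatch_time=dispatch_time,
                    channels=tuple(plan),
                    pulse_lengths=plan,
                )
            )

    def dispatch(self, trigger_time: float) -> None:
        """Schedule feedback for a trigger; returns immediately in wall mode."""
        if self._worker is not None:
            self._worker.submit(trigger_time)
        else:
            self._deliver(trigger_time)

    def close(self) -> None:
        if self._worker is not None:
            self._worker.close()


def set_cue(
    mode: str,
    device: MockDevice,
    trial_start_ms: float,
    trial_end_ms: float,
) -> bool:
    """Hold the green cue LED on for the whole trial on training trials.

    Returns whether the cue is on.  Baseline trials never illuminate it.
    """
    if mode == "training":
        device.set_channel("green_cue", True, at_ms=trial_start_ms)
        device.set_channel("green_cue", False, at_ms=trial_end_ms)
        return True
    return False


def write_device_timeline(device: MockDevice, path: str | Path) -> None:
    """Export the device timeline as CSV (channel, t_on_ms, t_off_ms)."""
    rows = [
        {"channel": ch, "t_on_ms": on, "t_off_ms": off}
        for ch in CHANNELS
        for on, off in device.pulses(ch)
    ]
    pd.DataFrame(rows, columns=["channel", "t_on_ms", "t_off_ms"]).to_csv(
        path, index=False
    )


def feedback_events_from(dispatchers: Sequence[Dispatcher]) -> list[FeedbackEvent]:
    out: list[FeedbackEvent] = []
    for d in dispatchers:
        out.extend(d.events)
    return sorted(out, key=lambda e: e.trigger_time)
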