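"""Selective trigger criterion: paired-frame displacement, gates, refractory.

The reinforced movement is a vertical excursion of the left forepaw between
one frame and the next.  For each non-overlapping frame pair the engine
computes the absolute change in the mean vertical position of each paw's
four digit tips and fires when all gates pass:

* ``min_left <= |dy_left| <= max_left`` — large enough to be a real reach,
  small enough not to be a tracking jump across the screen (both bounds
  inclusive);
* ``|dy_right| <= max_right`` — contralateral veto enforcing selectivity
  for the left paw (inclusive by default; configurable);
* aggregated keypoint confidence strictly above ``confidence_min``;
* more than ``refractory`` ms since the previous trigger.  The refractory
  gate is evaluated last and suppresses unconditionally; a suppressed
  above-criterion pair does *not* reset the refractory clock.

Every rejection carries a reason code, which the offline oracle uses for
equivalence diagnostics.  :func:`offline_oracle` replays the identical
rules by a plain sequential scan over a complete trace and is the ground
truth the streaming engine is tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CriterionConfig
from .errors import InputError
from .pose import PoseEstimate, mean_paw_position

__all__ = [
    "Reason",
    "Decision",
    "PawDisplacement",
    "EngineState",
    "TriggerEvent",
    "paw_displacement",
    "evaluate_criterion",
    "update_refractory",
    "TriggerEngine",
    "offline_oracle",
    "write_event_log",
    "read_event_log",
]


class Reason(str, Enum):
    """Why a frame pair did not trigger."""

    BELOW_MIN = "below_min"
    ABOVE_MAX = "above_max"
    CONTRALATERAL = "contralateral"
    LOW_CONFIDENCE = "low_confidence"
    REFRACTORY = "refractory"


@dataclass(frozen=True)
class Decision:
    triggered: bool
    reason: Reason | None = None

    def __bool__(self) -> bool:
        return self.triggered


TRIGGER = Decision(True)


@dataclass(frozen=True)
class PawDisplacement:
    """Absolute per-pair vertical displacement of each paw (px)."""

    pair_index: int
    dy_left: float
    dy_right: float
    confidence: float
    second_frame_time: float

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.dy_left)
            and math.isfinite(self.dy_right)
            and self.dy_left >= 0
            and self.dy_right >= 0
        ):
            raise InputError(
                f"pair {self.pair_index}: dy values must be finite and >= 0"
            )


@dataclass(frozen=True)
class EngineState:
    """Refractory bookkeeping: time of last trigger and running count."""

    last_trigger_time: float | None = None
    trigger_count: int = 0


@dataclass(frozen=True)
class TriggerEvent:
    """One emitted trigger with its full timing record."""

    pair_index: int
    frame_index: int  # index of the pair's second frame (movement arrival)
    frame_time: float  # ms, acquisition of the second frame
    decision_time: float  # ms, criterion evaluation
    dispatch_time: float | None  # ms, feedback command issue (None pre-dispatch)
    dy_left: float
    dy_right: float
    confidence: float


def paw_displacement(
    first: PoseEstimate,
    second: PoseEstimate,
    pair_index: int = 0,
    second_frame_time: float = 0.0,
    config: CriterionConfig | None = None,
) -> PawDisplacement:
    """Displacement of the mean paw position between the two frames of a pair.

    ``dy = |ȳ(second) − ȳ(first)|`` per paw, so upward and downward
    movements are treated alike.
    """
    config = config or CriterionConfig()
    dy_l = abs(mean_paw_position(second, "left")[1] - mean_paw_position(first, "left")[1])
    dy_r = abs(mean_paw_position(second, "right")[1] - mean_paw_position(first, "right")[1])
    if config.confidence_frames == "both":
        conf = min(
            first.confidence(config.confidence_agg),
            second.confidence(config.confidence_agg),
        )
    else:
        conf = second.confidence(config.confidence_agg)
    return PawDisplacement(pair_index, dy_l, dy_r, conf, second_frame_time)


def evaluate_criterion(
    d: PawDisplacement, config: CriterionConfig, state: EngineState
) -> Decision:
    """Apply all trigger gates to one displacement; refractory is checked last."""
    if d.dy_left < config.min_left:
        return Decision(False, Reason.BELOW_MIN)
    if d.dy_left > config.max_left:
        return Decision(False, Reason.ABOVE_MAX)
    right_ok = (
        d.dy_right <= config.max_right
        if config.right_bound_inclusive
        else d.dy_right < config.max_right
    )
    if not right_ok:
        return Decision(False, Reason.CONTRALATERAL)
    if not d.confidence > config.confidence_min:
        return Decision(False, Reason.LOW_CONFIDENCE)
    if (
        state.last_trigger_time is not None
        and not d.second_frame_time - state.last_trigger_time > config.refractory
    ):
        return Decision(False, Reason.REFRACTORY)
    return TRIGGER


def update_refractory(
    state: EngineState, decision: Decision, time_ms: float
) -> EngineState:
    """Advance the refractory state: triggers reset the clock, rejections don't."""
    if decision.triggered:
        return EngineState(
            last_trigger_time=time_ms, trigger_count=state.trigger_count + 1
        )
    return state


class TriggerEngine:
    """Streaming evaluation of the criterion over successive frame pairs."""

    def __init__(self, config: CriterionConfig | None = None) -> None:
        self.config = config or CriterionConfig()
        self.state = EngineState()
        self.decisions: list[tuple[PawDisplacement, Decision]] = []

    def process(
        self,
        first: PoseEstimate,
        second: PoseEstimate,
        pair_index: int,
        second_frame_time: float,
        armed: bool = True,
    ) -> tuple[PawDisplacement, Decision]:
        """Evaluate one pair.  ``armed=False`` (buffer period) evaluates the
        gates but forces NO_TRIGGER and leaves the refractory state untouched."""
        d = paw_displacement(first, second, pair_index, second_frame_time, self.config)
        decision = evaluate_criterion(d, self.config, self.state)
        if not armed:
            decision = Decision(False, decision.reason)
        else:
            self.state = update_refractory(self.state, decision, second_frame_time)
        self.decisions.append((d, decision))
        return d, decision

    @property
    def trigger_count(self) -> int:
        return self.state.trigger_count


def offline_oracle(
    positions: np.ndarray,
    timestamps_ms: Sequence[float],
    config: CriterionConfig | None = None,
    confidences: np.ndarray | None = None,
    frame_indices: Sequence[int] | None = None,
    armed_from_ms: float = 0.0,
) -> list[TriggerEvent]:
    """Brute-force replay of the trigger rules over a complete pose trace.

    Scans the same non-overlapping pairing — frames (0,1), (2,3), ... of the
    received sequence — applying each gate in order and tracking the
    refractory clock, with no shared code path through the streaming engine
    beyond the config object.  Pairs whose second frame falls before
    ``armed_from_ms`` are evaluated but cannot trigger (the buffer rule).

    Parameters are plain arrays: ``positions`` (n, 8, 2) with the first four
    columns the left paw's digits, ``confidences`` (n,) or (n, 8).
    """
    config = config or CriterionConfig()
    positions = np.asarray(positions, dtype=float)
    t = np.asarray(timestamps_ms, dtype=float)
    n = len(positions)
    if confidences is None:
        conf_frame = np.ones(n)
    else:
        confidences = np.asarray(confidences, dtype=float)
        if confidences.ndim == 2:
            conf_frame = (
                confidences.mean(axis=1)
                if config.confidence_agg == "mean"
                else confidences.min(axis=1)
            )
        else:
            conf_frame = confidences
    idx = (
        np.asarray(frame_indices, dtype=int)
        if frame_indices is not None
        else np.arange(n)
    )

    left_y = positions[:, :4, 1].mean(axis=1)
    right_y = positions[:, 4:, 1].mean(axis=1)

    events: list[TriggerEvent] = []
    last: float | None = None
    for p in range(n // 2):
        i, j = 2 * p, 2 * p + 1
        dy_l = abs(left_y[j] - left_y[i])
        dy_r = abs(right_y[j] - right_y[i])
        conf = (
            min(conf_frame[i], conf_frame[j])
            if config.confidence_frames == "both"
            else conf_frame[j]
        )
        tj = float(t[j])
        if dy_l < config.min_left or dy_l > config.max_left:
            continue
        if config.right_bound_inclusive:
            if dy_r > config.max_right:
                continue
        elif dy_r >= config.max_right:
            continue
        if not conf > config.confidence_min:
            continue
        if tj < armed_from_ms:
            continue
        if last is not None and not tj - last > config.refractory:
            continue
        events.append(
            TriggerEvent(
                pair_index=p,
                frame_index=int(idx[j]),
                frame_time=tj,
                decision_time=tj,
                dispatch_time=None,
                dy_left=float(dy_l),
                dy_right=float(dy_r),
                confidence=float(conf),
            )
        )
        last = tj
    return events


_LOG_COLUMNS = [
    "pair_index",
    "frame_index",
    "frame_time_ms",
    "decision_time_ms",
    "dispatch_time_ms",
    "decision",
    "reason",
    "dy_left",
    "dy_right",
    "confidence",
]


def write_event_log(
    path: str | Path,
    displacements: Sequence[PawDisplacement],
    decisions: Sequence[Decision],
    events: Sequence[TriggerEvent],
) -> None:
    """Persist the per-pair decision log as CSV."""
    by_pair = {e.pair_index: e for e in events}
    rows = []
    for d, dec in zip(displacements, decisions):
        ev = by_pair.get(d.pair_index)
        rows.append(
            {
                "pair_index": d.pair_index,
                "frame_index": ev.frame_index if ev else -1,
                "frame_time_ms": d.second_frame_time,
                "decision_time_ms": ev.decision_time if ev else d.second_frame_time,
                "dispatch_time_ms": ev.dispatch_time if ev else np.nan,
                "decision": "TRIGGER" if dec.triggered else "NO_TRIGGER",
                "reason": dec.reason.value if dec.reason else "",
                "dy_left": d.dy_left,
                "dy_right": d.dy_right,
                "confidence": d.confidence,
            }
        )
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False)


def read_event_log(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def events_equal(a: Sequence[TriggerEvent], b: Sequence[TriggerEvent]) -> bool:
    """Exact agreement of two event lists on pair indices and frame indices."""
    return [(e.pair_index, e.frame_index) for e in a] == [
        (e.pair_index, e.frame_index) for e in b
    ]


def replace_dispatch(event: TriggerEvent, dispatch_time: float) -> TriggerEvent:
    return replace(event, dispatch_time=dispatch_time)
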