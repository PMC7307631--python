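"""Frame acquisition abstraction: replay sources, pairing, drops, buffer.

The acquisition model is deliberately simple: frames arrive with a
monotonic millisecond timestamp, dropped frames appear as explicit
placeholder records, and all movement decisions operate on *non-overlapping
pairs* of consecutively received frames — (1st, 2nd), (3rd, 4th), ... —
so movement between the last frame of one pair and the first of the next
is never evaluated.  A pair whose two frames were not adjacent in the
original camera stream (because a drop fell between them) is flagged
``non_adjacent`` but still evaluated: the criterion compares whatever two
frames actually arrived back to back.

Each trial opens with a buffer period during which frames are analyzed but
neither persisted nor allowed to trigger feedback, followed by a short
settling wait; only then does the recording window begin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .config import SessionConfig
from .errors import InputError

__all__ = [
    "FrameRecord",
    "FramePair",
    "ReplaySource",
    "PairStream",
    "DropLedger",
    "open_replay_source",
    "run_buffer",
    "BufferReport",
]


@dataclass(frozen=True)
class FrameRecord:
    """One acquired frame: index, monotonic timestamp (ms), image, drop flag.

    ``image`` may be None when replaying a pose trace without video.
    """

    index: int
    acquisition_time: float
    image: np.ndarray | None = None
    is_placeholder: bool = False


@dataclass(frozen=True)
class FramePair:
    """The two-frame unit every trigger decision operates on."""

    first: FrameRecord
    second: FrameRecord

    def __post_init__(self) -> None:
        if self.second.index <= self.first.index:
            raise InputError(
                f"pair indices must increase: {self.first.index} -> {self.second.index}"
            )
        if self.first.is_placeholder or self.second.is_placeholder:
            raise InputError("pairs must not contain placeholder frames")

    @property
    def non_adjacent(self) -> bool:
        """True when a dropped frame fell between the two members."""
        return self.second.index != self.first.index + 1


class ReplaySource:
    """Replays a frame sequence with timestamps as an acquisition source.

    Exhaustion is signalled by ``StopIteration`` from :meth:`__next__` /
    a ``None`` from :meth:`next_frame`, never by an exception.
    """

    def __init__(
        self,
        frames: Sequence[np.ndarray] | None,
        timestamps: Sequence[float],
        indices: Sequence[int] | None = None,
        placeholder_indices: Iterable[int] = (),
        placeholder_times: dict[int, float] | None = None,
    ) -> None:
        timestamps = np.asarray(timestamps, dtype=float)
        if frames is not None and len(frames) != len(timestamps):
            raise InputError(
                f"frames ({len(frames)}) and timestamps ({len(timestamps)}) differ in length"
            )
        if np.any(np.diff(timestamps) < 0):
            raise InputError("timestamps must be non-decreasing")
        indices = (
            np.asarray(indices, dtype=int)
            if indices is not None
            else np.arange(len(timestamps))
        )
        if len(indices) != len(timestamps):
            raise InputError("indices and timestamps differ in length")
        placeholder_times = placeholder_times or {}

        records = [
            FrameRecord(
                int(indices[i]),
                float(timestamps[i]),
                None if frames is None else frames[i],
            )
            for i in range(len(timestamps))
        ]
        for pi in placeholder_indices:
            records.append(
                FrameRecord(
                    int(pi),
                    float(placeholder_times.get(int(pi), np.nan)),
                    None,
                    is_placeholder=True,
                )
            )
        records.sort(key=lambda r: r.index)
        # placeholders without a known time inherit the previous frame's time
        fixed: list[FrameRecord] = []
        last_t = 0.0
        for r in records:
            if r.is_placeholder and not np.isfinite(r.acquisition_time):
                r = FrameRecord(r.index, last_t, None, True)
            last_t = r.acquisition_time
            fixed.append(r)
        self._records = fixed
        self._pos = 0

    def __iter__(self) -> Iterator[FrameRecord]:
        return self

    def __next__(self) -> FrameRecord:
        if self._pos >= len(self._records):
            raise StopIteration
        rec = self._records[self._pos]
        self._pos += 1
        return rec

    def next_frame(self) -> FrameRecord | None:
        try:
            return next(self)
        except StopIteration:
            return None


def open_replay_source(
    frames: Sequence[np.ndarray] | None,
    timestamps: Sequence[float],
    **kwargs,
) -> ReplaySource:
    """Open a replay source over a recorded frame sequence.

    Thin constructor wrapper; validates that frames and timestamps agree in
    length and that timestamps are monotone.
    """
    if frames is None and len(timestamps) == 0:
        return ReplaySource(None, [], **kwargs)
    return ReplaySource(frames, timestamps, **kwargs)


@dataclass
class DropLedger:
    """Running account of emitted, processed, and dropped frames."""

    emitted: int = 0
    processed: int = 0
    dropped: int = 0
    drop_indices: list[int] = field(default_factory=list)
    processed_times: list[float] = field(default_factory=list)

    def record(self, frame: FrameRecord) -> None:
        self.emitted += 1
        if frame.is_placeholder:
            self.dropped += 1
            self.drop_indices.append(frame.index)
        else:
            self.processed += 1
            self.processed_times.append(frame.acquisition_time)

    def throughput_trace(
        self, start_ms: float | None = None, end_ms: float | None = None
    ) -> np.ndarray:
        """Processed-frame counts in 1 s bins over [start, end)."""
        if not self.processed_times:
            return np.zeros(0, dtype=int)
        t = np.asarray(self.processed_times)
        lo = t.min() if start_ms is None else start_ms
        hi = t.max() + 1e-9 if end_ms is None else end_ms
        n_bins = max(1, int(np.ceil((hi - lo) / 1000.0)))
        edges = lo + 1000.0 * np.arange(n_bins + 1)
        counts, _ = np.histogram(t[(t >= lo) & (t < hi)], bins=edges)
        return counts

    def summary(self) -> dict:
        return {
            "emitted": self.emitted,
            "processed": self.processed,
            "dropped": self.dropped,
        }


class PairStream:
    """Consume a frame source into non-overlapping pairs, skipping placeholders.

    Placeholders are logged to the ledger and never enter a pair; an
    unpaired trailing frame at exhaustion is discarded.
    """

    def __init__(self, source: Iterable[FrameRecord], ledger: DropLedger | None = None):
        self._source = iter(source)
        self.ledger = ledger if ledger is not None else DropLedger()

    def _next_real(self) -> FrameRecord | None:
        for frame in self._source:
            self.ledger.record(frame)
            if not frame.is_placeholder:
                return frame
        return None

    def next_pair(self) -> FramePair | None:
        first = self._next_real()
        if first is None:
            return None
        second = self._next_real()
        if second is None:
            return None
        return FramePair(first, second)

    def __iter__(self) -> Iterator[FramePair]:
        while True:
            pair = self.next_pair()
            if pair is None:
                return
            yield pair


@dataclass
class BufferReport:
    """Outcome of the buffer phase of a trial."""

    buffered_frames: int
    buffer_end_ms: float
    persistence_start_ms: float


def run_buffer(
    timestamps_ms: Sequence[float], config: SessionConfig
) -> BufferReport:
    """Classify the buffer window of a trial from its frame timestamps.

    Frames with time < ``buffer_duration`` are buffered (analyzed,
    non-persistent, non-triggering); persistence begins only after a
    further ``post_buffer_wait`` settling pause.
    """
    t = np.asarray(timestamps_ms, dtype=float)
    buffer_end = 1000.0 * config.buffer_duration
    return BufferReport(
        buffered_frames=int(np.sum(t < buffer_end)),
        buffer_end_ms=buffer_end,
        persistence_start_ms=buffer_end + config.post_buffer_wait,
    )
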