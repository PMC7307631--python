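"""Configuration schema: trigger criterion, session timing, validation, YAML I/O.

Defaults are the constants of the head-fixed forepaw-conditioning rig this
package models: a left-paw vertical displacement between 5 and 100 px
(inclusive) across one frame pair earns feedback, provided the right paw
moved no more than 10 px, the pose confidence exceeds 0.20, and at least
300 ms have elapsed since the previous trigger.  Feedback is a 200 ms red
LED pulse, plus a 150 ms water pulse on training trials.  Each trial streams
for 130 s: a 10 s warm-up buffer (analyzed, never persisted or rewarded), a
100 ms settling wait, then 120 s of recorded movement and feedback data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError

__all__ = [
    "CriterionConfig",
    "SessionConfig",
    "RunManifest",
    "load_config",
    "save_config",
]


def _require(cond: bool, field_name: str, constraint: str) -> None:
    if not cond:
        raise ConfigurationError(f"{field_name}: {constraint}")


@dataclass(frozen=True)
class CriterionConfig:
    """Trigger-criterion thresholds and feedback pulse timing.

    Parameters
    ----------
    min_left, max_left : float
        Inclusive bounds (px) on the left paw's absolute vertical
        displacement across a frame pair.  The upper bound rejects
        tracking jumps across the screen.
    max_right : float
        Contralateral veto (px): triggers are suppressed when the right
        paw's displacement exceeds this.  ``right_bound_inclusive``
        controls whether exactly ``max_right`` px still passes.
    confidence_min : float
        Pose-confidence gate; the aggregated keypoint confidence must be
        strictly greater than this.
    refractory : float
        Dead time (ms) after each trigger during which no trigger is
        emitted regardless of movement; strictly more than ``refractory``
        ms must elapse before the engine re-arms.
    led_pulse, water_pulse : float
        Feedback pulse lengths (ms) for the red LED and the water valve.
    confidence_agg : {"mean", "min"}
        How the 8 keypoint confidences of a frame are aggregated.
    confidence_frames : {"second", "both"}
        Whether the gate inspects only the pair's second frame or the
        minimum over both frames.
    """

    min_left: float = 5.0
    max_left: float = 100.0
    max_right: float = 10.0
    confidence_min: float = 0.20
    refractory: float = 300.0
    led_pulse: float = 200.0
    water_pulse: float = 150.0
    right_bound_inclusive: bool = True
    confidence_agg: str = "mean"
    confidence_frames: str = "second"

    def __post_init__(self) -> None:
        _require(self.min_left > 0, "min_left", "must be > 0")
        _require(self.min_left <= self.max_left, "min_left", "must be <= max_left")
        _require(self.max_right > 0, "max_right", "must be > 0")
        _require(
            0 <= self.confidence_min < 1, "confidence_min", "must be in [0, 1)"
        )
        for name in ("refractory", "led_pulse", "water_pulse"):
            _require(getattr(self, name) > 0, name, "must be > 0")
        _require(
            self.confidence_agg in ("mean", "min"),
            "confidence_agg",
            "must be 'mean' or 'min'",
        )
        _require(
            self.confidence_frames in ("second", "both"),
            "confidence_frames",
            "must be 'second' or 'both'",
        )


@dataclass(frozen=True)
class SessionConfig:
    """Trial timing and geometry.

    ``buffer_duration + recording_duration`` is the nominal trial length
    (130 s by default).  ``post_buffer_wait`` is the settling pause after
    the buffer before persistence begins; it minimizes dropped frames at
    the recording boundary.
    """

    buffer_duration: float = 10.0
    post_buffer_wait: float = 100.0
    recording_duration: float = 120.0
    input_frame_rate: float = 200.0
    resolution: tuple[int, int] = (256, 256)
    processing_delay_ms: float = 0.0

    def __post_init__(self) -> None:
        _require(self.buffer_duration >= 0, "buffer_duration", "must be >= 0")
        _require(self.post_buffer_wait >= 0, "post_buffer_wait", "must be >= 0")
        _require(self.recording_duration > 0, "recording_duration", "must be > 0")
        _require(self.input_frame_rate > 0, "input_frame_rate", "must be > 0")
        _require(
            len(self.resolution) == 2
            and all(int(r) >= 64 for r in self.resolution),
            "resolution",
            "must be (height, width) with both >= 64",
        )
        _require(
            self.processing_delay_ms >= 0, "processing_delay_ms", "must be >= 0"
        )

    @property
    def trial_length(self) -> float:
        """Total trial length in seconds (buffer + recording)."""
        return self.buffer_duration + self.recording_duration


_SECTIONS = {"criterion": CriterionConfig, "session": SessionConfig}


def _build(cls: type, data: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"{section}: unknown key(s) {sorted(unknown)}; known: {sorted(known)}"
        )
    if "resolution" in data and isinstance(data["resolution"], list):
        data = {**data, "resolution": tuple(data["resolution"])}
    return cls(**data)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML config file.

    Recognized top-level sections: ``criterion``, ``session``, and a free
    ``analysis`` mapping (bootstrap resamples, seeds, ROI, ...).  Unknown
    keys anywhere inside ``criterion``/``session`` are rejected.

    Returns a dict with instantiated ``CriterionConfig`` / ``SessionConfig``
    objects plus the raw ``analysis`` mapping.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"analysis"}
    if unknown:
        raise ConfigurationError(f"unknown top-level section(s): {sorted(unknown)}")
    out: dict[str, Any] = {
        name: _build(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    out["analysis"] = raw.get("analysis", {}) or {}
    return out


def save_config(config: dict[str, Any], path: str | Path) -> None:
    """Write a config dict (as returned by :func:`load_config`) to YAML."""
    raw: dict[str, Any] = {}
    for name in _SECTIONS:
        obj = config.get(name)
        if obj is not None:
            d = dataclasses.asdict(obj)
            if "resolution" in d:
                d["resolution"] = list(d["resolution"])
            raw[name] = d
    if config.get("analysis"):
        raw["analysis"] = config["analysis"]
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))


@dataclass
class RunManifest:
    """Reproducibility metadata attached to every persisted output."""

    config_hash: str
    seeds: dict[str, int]
    component: str
    inputs: dict[str, str] = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None

    @classmethod
    def create(
        cls,
        config: dict[str, Any],
        seeds: dict[str, int],
        component: str,
        inputs: dict[str, str] | None = None,
    ) -> "RunManifest":
        payload = {
            name: dataclasses.asdict(config[name])
            for name in _SECTIONS
            if config.get(name) is not None
        }
        payload["analysis"] = config.get("analysis", {})
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seeds=dict(seeds),
            component=component,
            inputs=dict(inputs or {}),
        )

    def close(self) -> "RunManifest":
        self.finished = time.time()
        return self

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
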