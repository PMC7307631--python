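"""Pose-estimator contract and backends.

A pose backend turns a video frame into 8 digit-tip keypoints (4 per
forepaw) with confidences.  The production system would plug a trained
keypoint network in here; this package ships two dependency-free backends:

* :class:`CentroidBackend` — an exact oracle for synthetic frames: it
  segments the rendered high-contrast markers and returns their
  intensity-weighted centroids.  On noiseless synthetic video it recovers
  the scripted digit positions to well under a pixel, which is what makes
  the whole closed loop testable without a trained model.
* :class:`ReplayBackend` — replays a stored pose trace by frame index
  (the offline path: analyze a session from its saved keypoint CSV).

Coordinates are pixels, origin top-left, y increasing downward; "vertical
movement" downstream means a change in y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import InputError

__all__ = [
    "DIGIT_LABELS",
    "LEFT_LABELS",
    "RIGHT_LABELS",
    "Keypoint",
    "PoseEstimate",
    "mean_paw_position",
    "PoseBackend",
    "CentroidBackend",
    "ReplayBackend",
]

#: Digit-tip labels: four per paw, numbered within each paw.
LEFT_LABELS = ("L1", "L2", "L3", "L4")
RIGHT_LABELS = ("R1", "R2", "R3", "R4")
DIGIT_LABELS = LEFT_LABELS + RIGHT_LABELS


@dataclass(frozen=True)
class Keypoint:
    """One digit-tip estimate: label, pixel coordinates, confidence in [0, 1]."""

    label: str
    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if self.label not in DIGIT_LABELS:
            raise InputError(f"unknown keypoint label {self.label!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InputError(f"non-finite coordinates for {self.label}")
        if not 0.0 <= self.confidence <= 1.0:
            raise InputError(
                f"confidence {self.confidence} for {self.label} outside [0, 1]"
            )


@dataclass(frozen=True)
class PoseEstimate:
    """A complete 8-keypoint pose for one frame."""

    frame_index: int
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        labels = [k.label for k in self.keypoints]
        if sorted(labels) != sorted(DIGIT_LABELS):
            raise InputError(
                f"pose for frame {self.frame_index} must contain exactly one "
                f"keypoint per label {DIGIT_LABELS}, got {labels}"
            )

    def by_label(self, label: str) -> Keypoint:
        for k in self.keypoints:
            if k.label == label:
                return k
        raise KeyError(label)  # unreachable given the invariant

    def paw(self, side: str) -> tuple[Keypoint, ...]:
        labels = LEFT_LABELS if side == "left" else RIGHT_LABELS
        return tuple(self.by_label(lb) for lb in labels)

    def confidence(self, agg: str = "mean") -> float:
        c = [k.confidence for k in self.keypoints]
        return float(np.mean(c)) if agg == "mean" else float(min(c))

    @classmethod
    def from_arrays(
        cls,
        frame_index: int,
        xy: np.ndarray,
        confidence: np.ndarray | float = 1.0,
    ) -> "PoseEstimate":
        """Build a pose from an (8, 2) coordinate array in label order."""
        xy = np.asarray(xy, dtype=float)
        conf = np.broadcast_to(np.asarray(confidence, dtype=float), (8,))
        kps = tuple(
            Keypoint(lb, float(xy[i, 0]), float(xy[i, 1]), float(conf[i]))
            for i, lb in enumerate(DIGIT_LABELS)
        )
        return cls(frame_index, kps)


def mean_paw_position(pose: PoseEstimate, paw: str) -> tuple[float, float]:
    """Arithmetic mean (x̄, ȳ) of the four digit tips of one paw.

    Averaging the digits gives a single per-paw position whose frame-to-frame
    change defines the movement the trigger criterion evaluates.  The mean is
    translation-equivariant and independent of digit order.
    """
    if paw not in ("left", "right"):
        raise InputError(f"paw must be 'left' or 'right', got {paw!r}")
    kps = pose.paw(paw)
    return (
        float(np.mean([k.x for k in kps])),
        float(np.mean([k.y for k in kps])),
    )


class PoseBackend:
    """Contract: ``estimate(frame) -> PoseEstimate``.

    ``frame`` is any object with ``index`` (int) and ``image`` (2-D uint8
    array or None).  Backends that exceed a caller-supplied deadline are
    reported as deadline misses by the caller, never killed.
    """

    def estimate(self, frame) -> PoseEstimate:  # pragma: no cover - interface
        raise NotImplementedError


class CentroidBackend(PoseBackend):
    """Marker-centroid oracle for synthetic frames.

    Segments pixels brighter than ``background + threshold`` into connected
    components (excluding the LED ROI, which would otherwise be read as a
    giant marker), takes each component's intensity-weighted centroid, and
    assigns labels by x-order: the four leftmost blobs are the left paw's
    digits L1..L4 (left to right), the rest R1..R4.  Exactly eight blobs
    give confidence 1.0; anything else returns the frame center for every
    digit with confidence 0.0 so downstream gates reject the frame.
    """

    def __init__(
        self,
        background: float = 16.0,
        threshold: float = 40.0,
        exclude_roi: tuple[int, int, int, int] | None = None,
    ) -> None:
        self.background = float(background)
        self.threshold = float(threshold)
        #: (x, y, w, h), half-open, 0-based; masked out before segmentation.
        self.exclude_roi = exclude_roi

    def estimate(self, frame) -> PoseEstimate:
        img = getattr(frame, "image", frame)
        if img is None or np.ndim(img) != 2:
            raise InputError(
                f"CentroidBackend needs a 2-D image for frame "
                f"{getattr(frame, 'index', '?')}"
            )
        img = np.asarray(img, dtype=float)
        work = img.copy()
        if self.exclude_roi is not None:
            x, y, w, h = self.exclude_roi
            work[y : y + h, x : x + w] = self.background
        mask = work > self.background + self.threshold
        labeled, n = ndimage.label(mask)
        h_img, w_img = img.shape
        if n != 8:
            center = np.tile([(w_img - 1) / 2.0, (h_img - 1) / 2.0], (8, 1))
            return PoseEstimate.from_arrays(
                getattr(frame, "index", -1), center, 0.0
            )
        weights = np.where(mask, work - self.background, 0.0)
        # center_of_mass returns (row, col) = (y, x)
        coms = ndimage.center_of_mass(weights, labeled, index=range(1, 9))
        xy = np.array([(c[1], c[0]) for c in coms])
        xy = xy[np.argsort(xy[:, 0])]  # label by x-order: 4 left, 4 right
        return PoseEstimate.from_arrays(getattr(frame, "index", -1), xy, 1.0)


class ReplayBackend(PoseBackend):
    """Replay a stored pose trace keyed by frame index."""

    def __init__(
        self,
        positions: np.ndarray,
        confidences: np.ndarray | None = None,
        frame_indices: Sequence[int] | None = None,
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 3 or positions.shape[1:] != (8, 2):
            raise InputError(
                f"positions must have shape (n, 8, 2), got {positions.shape}"
            )
        n = len(positions)
        if confidences is None:
            confidences = np.ones((n, 8))
        confidences = np.asarray(confidences, dtype=float)
        if confidences.shape == (n,):
            confidences = np.repeat(confidences[:, None], 8, axis=1)
        idx: Iterable[int] = frame_indices if frame_indices is not None else range(n)
        self._table = {
            int(i): (positions[row], confidences[row])
            for row, i in enumerate(idx)
        }

    def estimate(self, frame) -> PoseEstimate:
        index = int(getattr(frame, "index", frame))
        try:
            xy, conf = self._table[index]
        except KeyError:
            raise InputError(f"no stored pose for frame index {index}") from None
        return PoseEstimate.from_arrays(index, xy, conf)
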