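"""Axis-aligned boxes, detections and IoU primitives.

Coordinates are continuous pixel positions with origin at the top-left
corner, x increasing rightward and y increasing downward.  Boxes are real
rectangles: ``area = (x_max - x_min) * (y_max - y_min)`` with no pixel
inclusive/exclusive correction.  Zero-area boxes are rejected at
construction so degenerate geometry surfaces immediately rather than
propagating NaNs through a loss or a fusion decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Box",
    "Detection",
    "FrameResult",
    "iou",
    "iou_loss",
    "enclosing_box",
    "detections_to_jsonl",
    "detections_from_jsonl",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle with strictly positive area."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) has non-positive extent"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)


@dataclass(frozen=True)
class Detection:
    """A detected egg: box plus confidence in [0, 1]; single fixed class."""

    box: Box
    confidence: float
    label: str = "egg"

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class FrameResult:
    """Detections of one frame of an inspection cycle."""

    frame_index: int
    timestamp: float
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint, 1 when equal."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def iou_loss(a: Box, b: Box) -> float:
    """Complement of IoU: the base regression loss L_IoU = 1 - IoU."""
    return 1.0 - iou(a, b)


def enclosing_box(a: Box, b: Box) -> Box:
    """Smallest axis-aligned box containing both inputs."""
    return Box(
        min(a.x_min, b.x_min),
        min(a.y_min, b.y_min),
        max(a.x_max, b.x_max),
        max(a.y_max, b.y_max),
    )


def detections_to_jsonl(frames: Iterable[FrameResult]) -> str:
    """Serialise detections to JSON-lines: one object per detection."""
    lines = []
    for fr in frames:
        for det in fr.detections:
            lines.append(
                json.dumps(
                    {
                        "frame": fr.frame_index,
                        "x_min": det.box.x_min,
                        "y_min": det.box.y_min,
                        "x_max": det.box.x_max,
                        "y_max": det.box.y_max,
                        "confidence": det.confidence,
                    }
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def detections_from_jsonl(
    text: str, n_frames: int | None = None, timestamps: Sequence[float] | None = None
) -> list[FrameResult]:
    """Parse the JSON-lines sidecar back into per-frame results.

    Frames with no detections are still materialised when ``n_frames`` is
    given, so a downstream majority vote sees them as explicit "no" votes.
    """
    by_frame: dict[int, list[Detection]] = {}
    max_idx = -1
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        idx = int(obj["frame"])
        max_idx = max(max_idx, idx)
        box = Box(obj["x_min"], obj["y_min"], obj["x_max"], obj["y_max"])
        by_frame.setdefault(idx, []).append(Detection(box, float(obj["confidence"])))
    total = n_frames if n_frames is not None else max_idx + 1
    frames = []
    for i in range(total):
        ts = float(timestamps[i]) if timestamps is not None else float(i)
        frames.append(FrameResult(i, ts, by_frame.get(i, [])))
    return frames
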