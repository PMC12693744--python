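"""Pluggable egg-detection providers and a classical reference detector.

The production system feeds frames to a trained neural detector.  Here the
provider contract is the interface: any callable mapping an RGB image to a
:class:`~nestvision.geometry.FrameResult` can drive the inspection chain.
The bundled reference detector is a deterministic classical chain —
grayscale, OTSU binarisation, connected components, per-component
ellipse-likeness screening — sufficient for the synthetic desk-scale scenes
and for exercising fusion, positioning and record-keeping end to end.

A component is accepted as an egg when its pixel area lies in
[min_area, max_area], its min-area-rectangle axis ratio is at most
``axis_ratio_max`` and its fill ratio (pixel area over rectangle area) is
at least ``min_fill``.  A perfect ellipse fills its min-area rectangle at
pi/4 ~ 0.785, so min_fill defaults safely below that.  Confidence is
fill ratio times (short/long) axis ratio; detections under
``conf_threshold`` are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .barcode import binarize, histogram256, min_area_rect, otsu_threshold, to_grayscale
from .geometry import Box, Detection, FrameResult

__all__ = ["DetectorConfig", "detect_eggs", "run_provider"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectorConfig:
    conf_threshold: float = 0.25
    min_area: float = 250.0
    max_area: float = 60_000.0
    axis_ratio_max: float = 1.8
    min_fill: float = 0.70

    def __post_init__(self) -> None:
        if not 0.0 <= self.conf_threshold <= 1.0:
            raise ValueError("conf_threshold must lie in [0, 1]")
        if not 0.0 < self.min_area < self.max_area:
            raise ValueError("need 0 < min_area < max_area")
        if self.axis_ratio_max < 1.0:
            raise ValueError("axis_ratio_max must be >= 1")


def detect_eggs(
    image: np.ndarray,
    cfg: DetectorConfig = DetectorConfig(),
    frame_index: int = 0,
    timestamp: float = 0.0,
) -> FrameResult:
    """Classical reference detector; deterministic, empty result allowed."""
    arr = np.asarray(image)
    gray = to_grayscale(arr) if arr.ndim == 3 else arr.astype(np.uint8)
    try:
        t = otsu_threshold(histogram256(gray))
    except ValueError:  # constant image
        return FrameResult(frame_index, timestamp, [])
    fg = binarize(gray, t)
    lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    detections: list[Detection] = []
    for sl_idx, sl in enumerate(ndimage.find_objects(lab), start=1):
        comp = lab[sl] == sl_idx
        area = float(comp.sum())
        if not cfg.min_area <= area <= cfg.max_area:
            continue
        pts = np.argwhere(comp)
        region = min_area_rect(pts)
        if region is None or region.rect_area <= 0:
            continue
        ratio = region.aspect
        if ratio > cfg.axis_ratio_max:
            continue
        fill = min(area / region.rect_area, 1.0)
        if fill < cfg.min_fill:
            continue
        confidence = fill * (1.0 / ratio)
        if confidence < cfg.conf_threshold:
            continue
        r0, c0 = sl[0].start, sl[1].start
        rows, cols = np.nonzero(comp)
        box = Box(
            float(c0 + cols.min()),
            float(r0 + rows.min()),
            float(c0 + cols.max() + 1),
            float(r0 + rows.max() + 1),
        )
        detections.append(Detection(box, confidence))
    detections.sort(key=lambda d: (-d.confidence, d.box.x_min, d.box.y_min))
    return FrameResult(frame_index, timestamp, detections)


def run_provider(
    frames: Sequence[np.ndarray],
    provider: Callable[[np.ndarray], FrameResult],
    timestamps: Sequence[float] | None = None,
) -> list[FrameResult]:
    """Run any detector over a cycle's frames, containing its failures.

    Results carry frame indices 0..N-1 in input order.  A provider exception
    becomes an empty FrameResult plus a logged warning, so a failed frame is
    a "no" vote downstream instead of aborting the cycle.
    """
    results = []
    for i, img in enumerate(frames):
        ts = float(timestamps[i]) if timestamps is not None else float(i)
        try:
            res = provider(img)
            results.append(FrameResult(i, ts, list(res.detections)))
        except Exception:
            logger.warning("detection provider failed on frame %d; counting as no detections", i, exc_info=True)
            results.append(FrameResult(i, ts, []))
    return results
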