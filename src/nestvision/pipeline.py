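"""The full inspection chain: frames -> detections -> vote -> position -> record."""

from __future__ import annotations

from datetime import datetime
from typing import Callable, Sequence

import numpy as np

from .barcode import NoBarcodeError, read_position_code
from .codes import DEFAULT_PREFIX, extract_from_ean13
from .detector import DetectorConfig, detect_eggs, run_provider
from .fusion import FusionDecision, VotingPolicy, fuse_count
from .geometry import FrameResult
from .records import EggRecord, RecordStore

__all__ = ["PositioningError", "inspect_cycle", "end_to_end_fixture"]


class PositioningError(RuntimeError):
    """No frame of the cycle yielded a decodable cage barcode."""


def inspect_cycle(
    frames: Sequence[np.ndarray],
    store: RecordStore,
    det_cfg: DetectorConfig = DetectorConfig(),
    policy: VotingPolicy | None = None,
    prefix: str = DEFAULT_PREFIX,
    provider: Callable[[np.ndarray], FrameResult] | None = None,
    detections: Sequence[FrameResult] | None = None,
    time: datetime | None = None,
) -> tuple[EggRecord, FusionDecision, str]:
    """Run one inspection cycle and append its record.

    Detection runs through the provider contract (default: the classical
    reference detector), the per-egg majority vote fuses the frames, and the
    cage barcode is decoded from the first frame on which it succeeds.  If
    every frame fails to decode, no record is written and a
    :class:`PositioningError` is raised.
    """
    if policy is None:
        policy = VotingPolicy(n_frames=len(frames))
    if detections is None:
        if provider is None:
            provider = lambda img: detect_eggs(img, det_cfg)
        detections = run_provider(frames, provider)
    decision = fuse_count(list(detections), policy)

    uid = None
    for img in frames:
        try:
            uid = extract_from_ean13(read_position_code(img), prefix).uid
            break
        except (NoBarcodeError, ValueError):
            continue
    if uid is None:
        raise PositioningError("cage barcode could not be decoded from any frame")

    record = store.add_record(uid, decision.fused_count, time)
    return record, decision, uid


def end_to_end_fixture(cyc, store: RecordStore | None = None, **kwargs) -> EggRecord:
    """Render a synthetic cycle and push it through the whole chain."""
    from .scenes import CycleSpec, detector_config_for, render_cycle  # local: avoid cycle

    assert isinstance(cyc, CycleSpec)
    frames, truth, _ = render_cycle(cyc)
    if store is None:
        store = RecordStore()
    kwargs.setdefault("det_cfg", detector_config_for(cyc.scene))
    kwargs.setdefault("prefix", cyc.scene.prefix)
    record, _, _ = inspect_cycle(frames, store, **kwargs)
    return record
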