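"""Majority-voting fusion of repeated inspections of one nest.

A nest is photographed N times (default 3, ten seconds apart) so that
transient interference — a pigeon briefly covering the nest, an egg rolling
a few pixels, a blurred frame — affects individual frames independently.
Presence is declared when at least T of the N frames see an egg.  If a
single frame detects an occupied nest with probability P_d, the probability
the vote is correct is the binomial tail

    P_system = sum_{k=T}^{N} C(N, k) P_d^k (1 - P_d)^(N - k)

e.g. P_d = 0.8, N = 3, T = 2 gives 0.896.

Count fusion generalises the presence vote to per-egg granularity: the
detections of all frames are clustered by greedy nearest-center matching
(descending confidence, one member per frame per cluster) and every cluster
supported by at least T distinct frames counts as one egg.  A spurious
single-frame detection therefore never reaches the record, and an egg
missing from one frame of three still does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import FrameResult

__all__ = [
    "VotingPolicy",
    "ReliabilityInputs",
    "FusionDecision",
    "system_reliability",
    "fuse_presence",
    "fuse_count",
    "simulate_cycles",
]


@dataclass(frozen=True)
class VotingPolicy:
    """N frames per cycle, vote threshold T, and cross-frame match radius."""

    n_frames: int = 3
    threshold: int = 2
    sample_interval: float = 10.0
    match_radius: float = 40.0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 1 <= self.threshold <= self.n_frames:
            raise ValueError("threshold must satisfy 1 <= T <= N")
        if self.match_radius <= 0:
            raise ValueError("match_radius must be positive")


@dataclass(frozen=True)
class ReliabilityInputs:
    """Per-frame detection probability P_d; P_f = 1 - P_d is the failure rate."""

    p_detect: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_detect <= 1.0:
            raise ValueError("p_detect must lie in [0, 1]")

    @property
    def p_fail(self) -> float:
        return 1.0 - self.p_detect


@dataclass
class FusionDecision:
    egg_present: bool
    fused_count: int
    per_egg_support: list[tuple[tuple[float, float], list[int]]] = field(default_factory=list)


def system_reliability(inputs: ReliabilityInputs, policy: VotingPolicy = VotingPolicy()) -> float:
    """Exact binomial tail: probability that >= T of N frames detect."""
    n, t = policy.n_frames, policy.threshold
    p = inputs.p_detect
    return float(
        sum(math.comb(n, k) * p**k * (1.0 - p) ** (n - k) for k in range(t, n + 1))
    )


def _check_frames(frames: list[FrameResult], policy: VotingPolicy) -> None:
    if len(frames) != policy.n_frames:
        raise ValueError(
            f"expected {policy.n_frames} frames per cycle, got {len(frames)}"
        )


def fuse_presence(frames: list[FrameResult], policy: VotingPolicy = VotingPolicy()) -> bool:
    """Nest-level vote: true iff >= T frames contain at least one detection."""
    _check_frames(frames, policy)
    positives = sum(1 for fr in frames if len(fr.detections) > 0)
    return positives >= policy.threshold


def fuse_count(frames: list[FrameResult], policy: VotingPolicy = VotingPolicy()) -> FusionDecision:
    """Per-egg vote via greedy cross-frame clustering.

    Detections are processed in descending confidence (ties: lower frame
    index, then input order).  Each joins the nearest existing cluster
    whose centroid lies within ``match_radius`` and which has no member
    from the same frame yet; otherwise it seeds a new cluster.  Clusters
    supported by >= T distinct frames each contribute one fused egg.
    """
    _check_frames(frames, policy)
    items = []
    for fr in frames:
        for j, det in enumerate(fr.detections):
            items.append((-det.confidence, fr.frame_index, j, det))
    items.sort(key=lambda it: (it[0], it[1], it[2]))

    clusters: list[dict] = []  # {"centers": [(x,y)...], "frames": set}
    for _, frame_idx, _, det in items:
        cx, cy = det.box.center
        best = None
        best_d = policy.match_radius
        for cl in clusters:
            if frame_idx in cl["frames"]:
                continue
            mx = sum(c[0] for c in cl["centers"]) / len(cl["centers"])
            my = sum(c[1] for c in cl["centers"]) / len(cl["centers"])
            d = math.hypot(cx - mx, cy - my)
            if d < best_d:
                best_d = d
                best = cl
        if best is None:
            clusters.append({"centers": [(cx, cy)], "frames": {frame_idx}})
        else:
            best["centers"].append((cx, cy))
            best["frames"].add(frame_idx)

    support = []
    for cl in clusters:
        if len(cl["frames"]) >= policy.threshold:
            mx = sum(c[0] for c in cl["centers"]) / len(cl["centers"])
            my = sum(c[1] for c in cl["centers"]) / len(cl["centers"])
            support.append(((mx, my), sorted(cl["frames"])))
    support.sort(key=lambda s: (s[0][1], s[0][0]))
    return FusionDecision(
        egg_present=len(support) >= 1,
        fused_count=len(support),
        per_egg_support=support,
    )


def simulate_cycles(
    inputs: ReliabilityInputs,
    policy: VotingPolicy = VotingPolicy(),
    n_cycles: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo miss rate of the vote for a truly occupied nest.

    Draws per-frame Bernoulli(P_d) successes and returns the fraction of
    cycles in which fewer than T frames succeed; converges to
    1 - system_reliability.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    hits = rng.random((n_cycles, policy.n_frames)) < inputs.p_detect
    misses = hits.sum(axis=1) < policy.threshold
    return float(misses.mean())
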