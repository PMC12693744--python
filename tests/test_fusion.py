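import itertools

import numpy as np
import pytest

from nestvision.fusion import (
    FusionDecision,
    ReliabilityInputs,
    VotingPolicy,
    fuse_count,
    fuse_presence,
    simulate_cycles,
    system_reliability,
)
from nestvision.geometry import Box, Detection, FrameResult


def frame(idx, centers, conf=0.8):
    dets = [
        Detection(Box(cx - 10, cy - 10, cx + 10, cy + 10), conf) for cx, cy in centers
    ]
    return FrameResult(idx, idx * 10.0, dets)


def brute_force_reliability(p, n, t):
    """Enumerate all 2^n frame outcomes."""
    total = 0.0
    for outcome in itertools.product([0, 1], repeat=n):
        if sum(outcome) >= t:
            prob = 1.0
            for o in outcome:
                prob *= p if o else (1 - p)
            total += prob
    return total


class TestSystemReliability:
    def test_reference_point(self):
        assert system_reliability(ReliabilityInputs(0.8)) == pytest.approx(0.896, abs=1e-12)

    def test_certain_detection(self):
        for n, t in [(1, 1), (3, 2), (5, 5), (7, 3)]:
            p = VotingPolicy(n_frames=n, threshold=t)
            assert system_reliability(ReliabilityInputs(1.0), p) == 1.0

    def test_fair_coin_majority(self):
        assert system_reliability(ReliabilityInputs(0.5)) == pytest.approx(0.5, abs=1e-12)

    def test_matches_exhaustive_enumeration(self, rng):
        for n in range(1, 11):
            for t in range(1, n + 1):
                p = float(rng.uniform(0.05, 0.95))
                policy = VotingPolicy(n_frames=n, threshold=t)
                assert system_reliability(ReliabilityInputs(p), policy) == pytest.approx(
                    brute_force_reliability(p, n, t), abs=1e-12
                )

    def test_non_decreasing_in_pd(self):
        vals = [
            system_reliability(ReliabilityInputs(p)) for p in np.linspace(0, 1, 101)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_vote_beats_single_frame_above_half(self):
        """With N=3, T=2 the fused reliability is at least P_d once P_d >= 0.5."""
        for p in np.linspace(0.5, 1.0, 51):
            assert system_reliability(ReliabilityInputs(float(p))) >= p - 1e-12

    def test_invalid_policy(self):
        with pytest.raises(ValueError):
            VotingPolicy(n_frames=3, threshold=4)


class TestFusePresence:
    def test_two_of_three_present(self):
        frames = [frame(0, [(50, 50)]), frame(1, [(52, 51)]), frame(2, [])]
        assert fuse_presence(frames) is True

    def test_all_empty_absent(self):
        assert fuse_presence([frame(i, []) for i in range(3)]) is False

    def test_one_of_three_absent(self):
        frames = [frame(0, [(50, 50)]), frame(1, []), frame(2, [])]
        assert fuse_presence(frames) is False

    def test_frame_count_enforced(self):
        with pytest.raises(ValueError):
            fuse_presence([frame(0, [])])

    def test_order_invariance(self):
        frames = [frame(0, [(10, 10), (90, 90)]), frame(1, [(90, 92), (11, 9)]), frame(2, [])]
        shuffled = [
            FrameResult(f.frame_index, f.timestamp, list(reversed(f.detections)))
            for f in frames
        ]
        assert fuse_presence(frames) == fuse_presence(shuffled)


class TestFuseCount:
    def test_stable_single_egg(self):
        frames = [frame(0, [(100, 100)]), frame(1, [(105, 103)]), frame(2, [(98, 101)])]
        d = fuse_count(frames)
        assert d.fused_count == 1 and d.egg_present
        assert d.per_egg_support[0][1] == [0, 1, 2]

    def test_two_clusters_with_partial_support(self):
        """Two eggs seen twice each still count, one frame missing one egg."""
        frames = [
            frame(0, [(100, 100), (300, 300)]),
            frame(1, [(103, 98), (302, 297)]),
            frame(2, [(99, 102)]),
        ]
        d = fuse_count(frames)
        assert d.fused_count == 2
        supports = sorted(len(s[1]) for s in d.per_egg_support)
        assert supports == [2, 3]

    def test_single_frame_spurious_detection_filtered(self):
        frames = [frame(0, [(400, 200)]), frame(1, []), frame(2, [])]
        d = fuse_count(frames)
        assert d.fused_count == 0 and not d.egg_present

    def test_presence_consistent_with_count(self):
        frames = [frame(0, [(50, 50)]), frame(1, [(51, 49)]), frame(2, [])]
        d = fuse_count(frames)
        assert d.egg_present == (d.fused_count >= 1)

    def test_order_invariance(self):
        frames = [
            frame(0, [(100, 100), (300, 300)]),
            frame(1, [(300, 305), (101, 99)]),
            frame(2, [(299, 300), (100, 104)]),
        ]
        shuffled = [
            FrameResult(f.frame_index, f.timestamp, list(reversed(f.detections)))
            for f in frames
        ]
        assert fuse_count(frames).fused_count == fuse_count(shuffled).fused_count == 2


class TestSimulateCycles:
    def test_certain_detection_never_misses(self):
        assert simulate_cycles(ReliabilityInputs(1.0), n_cycles=1000, seed=3) == 0.0

    def test_blind_detector_always_misses(self):
        assert simulate_cycles(ReliabilityInputs(0.0), n_cycles=1000, seed=3) == 1.0

    def test_converges_to_binomial_complement(self):
        n = 100_000
        miss = simulate_cycles(ReliabilityInputs(0.8), n_cycles=n, seed=11)
        expected = 1.0 - 0.896
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert abs(miss - expected) < 3 * sigma

    def test_deterministic_given_seed(self):
        a = simulate_cycles(ReliabilityInputs(0.7), n_cycles=5000, seed=42)
        b = simulate_cycles(ReliabilityInputs(0.7), n_cycles=5000, seed=42)
        assert a == b
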