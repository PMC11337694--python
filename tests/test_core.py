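import numpy as np
import pytest
from scipy.spatial import cKDTree

import psar
from psar import ECGSignal
from psar.core import CycleSegment
from psar.fiducials import Beat, FiducialPoints

from conftest import periodic_fiducials, single_cycle_signal

FS = 500.0


class TestComputeTau:
    @pytest.mark.parametrize("period,expected", [(900, 300), (400, 133), (3, 1),
                                                 (1000, 333), (500, 167)])
    def test_third_of_period_rounded(self, period, expected):
        assert psar.compute_tau(period) == expected

    def test_degenerate_period_rejected(self):
        with pytest.raises(ValueError):
            psar.compute_tau(2)


class TestSplitCycles:
    def _beats(self, r_list, q_off=-20, s_off=20):
        beats = [Beat(R=r, Q=r + q_off, S=r + s_off) for r in r_list]
        return FiducialPoints(beats, fs=FS)

    def test_rr_split_consecutive_pairs(self):
        fids = self._beats([400 * k for k in range(10)])
        segs = psar.split_cycles(fids, "RR")
        assert len(segs) == 9
        assert all(s.method == "RR" for s in segs)
        # contiguity and boundaries
        for k, s in enumerate(segs):
            assert (s.start, s.end) == (400 * k, 400 * (k + 1))
        assert all(a.end == b.start for a, b in zip(segs, segs[1:]))

    def test_stpq_split_spans_beat_pairs(self):
        fids = self._beats([500 * k + 100 for k in range(10)])
        segs = psar.split_cycles(fids, "STPQ")
        assert len(segs) == 9
        for k, s in enumerate(segs):
            assert s.start == 500 * k + 120  # S of beat k
            assert s.end == 500 * (k + 1) + 80  # Q of beat k+1

    def test_qrs_split_within_beats(self):
        fids = self._beats([500 * k + 100 for k in range(10)], q_off=-30, s_off=30)
        segs = psar.split_cycles(fids, "QRS")
        assert len(segs) == 10
        assert all(s.period_samples == 60 for s in segs)

    def test_single_pair(self):
        fids = FiducialPoints([Beat(R=0), Beat(R=500)], fs=FS)
        segs = psar.split_cycles(fids, "RR")
        assert len(segs) == 1
        assert (segs[0].start, segs[0].end, segs[0].period_samples) == (0, 500, 500)

    def test_fewer_than_two_beats_empty(self):
        assert psar.split_cycles(FiducialPoints([Beat(R=5)], fs=FS), "RR") == []

    def test_short_segments_dropped(self):
        fids = FiducialPoints([Beat(R=0), Beat(R=5), Beat(R=505)], fs=FS)
        segs = psar.split_cycles(fids, "RR")
        assert len(segs) == 1  # the 5-sample segment is below the 9-sample floor


class TestEmbedSegment:
    def test_constant_segment_maps_to_diagonal_point(self):
        sig = ECGSignal(np.full(300, 0.42), fs=FS)
        seg = CycleSegment.from_bounds(0, 300, "RR")
        traj = psar.embed_segment(sig, seg, mode="circular")
        assert len(traj) == 300
        assert np.abs(traj.points - 0.42).max() == 0.0

    def test_z3_symmetry_exact_for_t_divisible_by_3(self):
        T = 900
        sig = single_cycle_signal(T)
        traj = psar.embed_segment(sig, CycleSegment.from_bounds(0, T, "RR"),
                                  mode="circular")
        assert traj.points.shape == (T, 3)
        permuted = traj.points[:, [1, 2, 0]]
        dist, _ = cKDTree(traj.points).query(permuted)
        assert dist.max() == 0.0

    @pytest.mark.parametrize("tau_mult", [1, 2])
    def test_full_period_delay_collapses_to_diagonal(self, tau_mult):
        T = 800
        sig = single_cycle_signal(T)
        traj = psar.embed_segment(sig, CycleSegment.from_bounds(0, T, "RR"),
                                  mode="circular", tau_override=tau_mult * T)
        assert np.abs(traj.points[:, 0] - traj.points[:, 1]).max() == 0.0
        assert np.abs(traj.points[:, 0] - traj.points[:, 2]).max() == 0.0

    def test_truncated_mode_point_count(self):
        sig = ECGSignal(np.arange(300, dtype=float), fs=FS)
        seg = CycleSegment.from_bounds(0, 300, "RR")  # tau = 100
        traj = psar.embed_segment(sig, seg, mode="truncated")
        assert len(traj) == 300 - 200
        # no wrap: coordinates strictly from increasing ramp
        assert np.all(np.diff(traj.points[:, 0]) > 0)

    def test_truncated_mode_empty_when_period_too_short(self):
        sig = ECGSignal(np.ones(300), fs=FS)
        seg = CycleSegment.from_bounds(0, 300, "RR")
        traj = psar.embed_segment(sig, seg, mode="truncated", tau_override=200)
        assert len(traj) == 0


class TestReconstructAttractor:
    def test_circular_point_count_is_total_period(self, sine_8s):
        fids = periodic_fiducials(10)
        traj = psar.reconstruct_attractor(sine_8s, fids, "RR", "circular")
        segs = psar.split_cycles(fids, "RR")
        assert len(traj) == sum(s.period_samples for s in segs)

    def test_periodic_signal_gives_identical_cycles(self, sine_8s):
        fids = periodic_fiducials(10)
        traj = psar.reconstruct_attractor(sine_8s, fids, "RR", "circular")
        first = traj.points[traj.cycle_ids == 0]
        for cid in range(1, traj.n_cycles):
            np.testing.assert_allclose(traj.points[traj.cycle_ids == cid], first,
                                       atol=1e-9)

    def test_alternating_segment_lengths_alternate_tau(self):
        # beats spaced 800 / 1200 ms: tau should alternate 133 and 200 samples
        r, pos = [], 0
        for k in range(8):
            r.append(pos)
            pos += 400 if k % 2 == 0 else 600
        fids = FiducialPoints([Beat(R=i) for i in r], fs=FS)
        segs = psar.split_cycles(fids, "RR")
        assert [s.tau_samples for s in segs] == [133, 200] * 3 + [133]

    def test_concatenation_order_independence(self, sine_8s):
        fids = periodic_fiducials(10)
        segs = psar.split_cycles(fids, "RR")
        direct = psar.embed_cycles(sine_8s, segs)
        shuffled_parts = [
            psar.embed_segment(sine_8s, seg, "circular", cycle_id=i)
            for i, seg in sorted(enumerate(segs), key=lambda kv: -kv[0])
        ]
        pts = np.concatenate([p.points for p in shuffled_parts])
        ids = np.concatenate([p.cycle_ids for p in shuffled_parts])
        order = np.argsort(ids, kind="stable")
        assert np.array_equal(pts[order], direct.points)
        assert np.array_equal(ids[order], direct.cycle_ids)

    def test_no_segments_gives_empty_trajectory(self):
        sig = ECGSignal(np.zeros(5000), fs=FS)
        traj = psar.reconstruct_attractor(
            sig, FiducialPoints([], fs=FS), "RR", "circular"
        )
        assert len(traj) == 0


class TestRescalingInvariance:
    def test_integer_resampling_preserves_projected_orbit(self):
        T, k = 900, 3
        sig = single_cycle_signal(T)
        traj = psar.embed_segment(sig, CycleSegment.from_bounds(0, T, "RR"),
                                  "circular")
        fine = single_cycle_signal(T * k, fs=FS * k)
        seg_k = CycleSegment(0, T * k, "RR",
                             tau_samples=k * psar.compute_tau(T))
        traj_k = psar.embed_segment(fine, seg_k, "circular")
        a = psar.project_points(traj)
        b = psar.project_points(traj_k)
        A = np.column_stack([a.u, a.v])
        B = np.column_stack([b.u, b.v])
        dist, _ = cKDTree(B).query(A)
        assert dist.max() < 0.01 * 0.2  # < 1 % of the signal amplitude
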