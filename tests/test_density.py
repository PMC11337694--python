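import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psar
from psar.core import CycleSegment, EmbeddedTrajectory
from psar.density import PROJECTION_BASIS, ProjectedPoints

from conftest import periodic_fiducials, single_cycle_signal

FS = 500.0


def traj_from_points(pts):
    pts = np.asarray(pts, dtype=float)
    return EmbeddedTrajectory(points=pts, cycle_ids=np.zeros(len(pts), dtype=int),
                              mode="circular")


class TestProjection:
    def test_basis_is_orthonormal_with_diagonal_third_axis(self):
        assert np.allclose(PROJECTION_BASIS @ PROJECTION_BASIS.T, np.eye(3),
                           atol=1e-15)
        assert np.allclose(PROJECTION_BASIS[2], np.full(3, 1 / np.sqrt(3)))

    def test_diagonal_points_project_to_origin(self):
        pts = traj_from_points([[c, c, c] for c in (-3.0, 0.0, 0.17, 9.9)])
        p = psar.project_points(pts)
        assert np.abs(p.u).max() == 0.0
        assert np.abs(p.v).max() == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=3))
    def test_norm_preserved(self, xyz):
        p = psar.project_points(traj_from_points([xyz]))
        lhs = p.u[0] ** 2 + p.v[0] ** 2 + p.w[0] ** 2
        rhs = float(np.sum(np.square(xyz)))
        assert abs(lhs - rhs) <= 1e-10 * max(1.0, rhs)

    def test_constant_offset_moves_only_w(self, sine_8s):
        fids = periodic_fiducials(10)
        base = psar.project_points(
            psar.reconstruct_attractor(sine_8s, fids, "RR", "circular")
        )
        shifted_sig = psar.add_drift(sine_8s, "constant", 0.1)
        shifted = psar.project_points(
            psar.reconstruct_attractor(shifted_sig, fids, "RR", "circular")
        )
        assert np.abs(base.u - shifted.u).max() < 1e-12
        assert np.abs(base.v - shifted.v).max() < 1e-12
        assert np.abs((shifted.w - base.w) - 0.3 / np.sqrt(3)).max() < 1e-12

    def test_empty_trajectory(self):
        p = psar.project_points(EmbeddedTrajectory.empty("circular"))
        assert len(p) == 0


class TestDensityMap:
    def _pts(self, u, v):
        u = np.asarray(u, float)
        return ProjectedPoints(u=u, v=np.asarray(v, float),
                               w=np.zeros_like(u),
                               cycle_ids=np.zeros(u.size, dtype=int))

    def test_sum_equals_in_range_count(self):
        rng = np.random.default_rng(0)
        p = self._pts(rng.uniform(-1, 1, 500), rng.uniform(-1, 1, 500))
        dm = psar.make_density_map(p, 64, 64, (-1, 1), (-1, 1))
        assert dm.grid.sum() == 500
        assert dm.n_points_in == 500
        assert dm.n_points_clipped == 0

    def test_out_of_range_points_clipped(self):
        p = self._pts([0.0, 5.0], [0.0, 0.0])
        dm = psar.make_density_map(p, 8, 8, (-1, 1), (-1, 1))
        assert dm.n_points_in == 1
        assert dm.n_points_clipped == 1

    def test_single_origin_point_lands_in_centre_of_odd_grid(self):
        p = self._pts([0.0], [0.0])
        dm = psar.make_density_map(p, 9, 9, (-1, 1), (-1, 1))
        nz = np.argwhere(dm.grid)
        assert nz.tolist() == [[4, 4]]

    def test_empty_points_with_ranges_gives_zero_map(self):
        p = self._pts([], [])
        dm = psar.make_density_map(p, 16, 16, (-1, 1), (-1, 1))
        assert dm.grid.shape == (16, 16)
        assert not dm.grid.any()

    def test_empty_points_without_ranges_is_error(self):
        with pytest.raises(ValueError):
            psar.make_density_map(self._pts([], []), 16, 16)

    def test_rotation_invariance_of_z3_orbit(self):
        T = 900
        sig = single_cycle_signal(T)
        traj = psar.embed_segment(sig, CycleSegment.from_bounds(0, T, "RR"),
                                  "circular")
        p = psar.project_points(traj)
        half = 1.05 * max(np.abs(p.u).max(), np.abs(p.v).max())
        dm = psar.make_density_map(p, 224, 224, (-half, half), (-half, half))
        c, s = np.cos(2 * np.pi / 3), np.sin(2 * np.pi / 3)
        rot = ProjectedPoints(u=c * p.u - s * p.v, v=s * p.u + c * p.v,
                              w=p.w, cycle_ids=p.cycle_ids)
        dm_rot = psar.make_density_map(rot, 224, 224, (-half, half), (-half, half))
        overlap = np.minimum(dm.grid, dm_rot.grid).sum() / dm.grid.sum()
        assert overlap >= 0.95


class TestNormalize:
    def test_linear_normalization_peak_one(self):
        grid = np.zeros((4, 4))
        grid[1, 2] = 7.0
        grid[0, 0] = 3.0
        dm = psar.DensityMap(grid, (-1, 1), (-1, 1), False, 10, 0)
        out = psar.normalize_density(dm, "linear")
        assert out.grid.max() == 1.0
        assert out.grid[0, 0] == pytest.approx(3 / 7)

    def test_zero_map_unchanged_no_nan(self):
        dm = psar.DensityMap(np.zeros((4, 4)), (-1, 1), (-1, 1), False, 0, 0)
        for mode in ("linear", "log"):
            out = psar.normalize_density(dm, mode)
            assert not out.grid.any()
            assert np.isfinite(out.grid).all()

    def test_log_mode_monotone(self):
        rng = np.random.default_rng(1)
        grid = rng.integers(0, 50, size=(8, 8)).astype(float)
        dm = psar.DensityMap(grid, (-1, 1), (-1, 1), False, int(grid.sum()), 0)
        out = psar.normalize_density(dm, "log")
        flat_in, flat_out = grid.ravel(), out.grid.ravel()
        order = np.argsort(flat_in)
        assert np.all(np.diff(flat_out[order]) >= -1e-15)


class TestRenderImage:
    def test_png_dimensions_and_determinism(self, tmp_path):
        rng = np.random.default_rng(2)
        grid = rng.integers(0, 9, size=(224, 224)).astype(float)
        dm = psar.DensityMap(grid, (-1, 1), (-1, 1), False, int(grid.sum()), 0)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        psar.render_image(dm, p1)
        psar.render_image(dm, p2)
        from PIL import Image

        with Image.open(p1) as im:
            assert im.size == (224, 224)
            assert im.mode == "L"
        assert p1.read_bytes() == p2.read_bytes()

    def test_zero_map_renders_black(self, tmp_path):
        dm = psar.DensityMap(np.zeros((32, 32)), (-1, 1), (-1, 1), False, 0, 0)
        out = tmp_path / "z.png"
        psar.render_image(dm, out)
        from PIL import Image

        with Image.open(out) as im:
            assert np.asarray(im).max() == 0
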