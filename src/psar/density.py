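"""Projection onto the plane orthogonal to x = y = z, and density maps.

Any constant added to the input signal moves a delay-embedded trajectory
along the (1, 1, 1) diagonal only.  Projecting onto the orthogonal plane
therefore cancels constant baseline offsets exactly, which is why the
density features are built in (u, v) rather than in the raw embedding
coordinates.  The orthonormal basis used is

    u = (x - z) / sqrt(2)
    v = (x - 2 y + z) / sqrt(6)
    w = (x + y + z) / sqrt(3)        (the discarded diagonal coordinate)

so Euclidean norms are preserved and w alone carries the offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import EmbeddedTrajectory

#: Rows of the orthonormal change-of-basis matrix (u, v, w).
PROJECTION_BASIS = np.array(
    [
        [1.0 / np.sqrt(2.0), 0.0, -1.0 / np.sqrt(2.0)],
        [1.0 / np.sqrt(6.0), -2.0 / np.sqrt(6.0), 1.0 / np.sqrt(6.0)],
        [1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0)],
    ]
)

DEFAULT_GRID = 224
#: Adaptive range padding: half-width = 1.05 * max(|u|, |v|).
RANGE_PAD = 1.05


@dataclass
class ProjectedPoints:
    """In-plane coordinates (u, v) and diagonal coordinate w, in mV."""

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    cycle_ids: np.ndarray

    def __len__(self) -> int:
        return self.u.size


def project_points(traj: EmbeddedTrajectory) -> ProjectedPoints:
    """Orthonormal change of basis with third axis along (1, 1, 1)/sqrt(3).

    Empty trajectories map to empty output.
    """
    x, y, z = traj.points[:, 0], traj.points[:, 1], traj.points[:, 2]
    # explicit differences (not a matmul) so diagonal points cancel exactly
    u = (x - z) / np.sqrt(2.0)
    v = (x + z - 2.0 * y) / np.sqrt(6.0)
    w = (x + y + z) / np.sqrt(3.0)
    return ProjectedPoints(u=u, v=v, w=w, cycle_ids=traj.cycle_ids.copy())


@dataclass
class DensityMap:
    """2-D binned occupancy of projected (u, v) points.

    ``grid[r, c]`` counts points whose v falls in row bin r (ascending v)
    and u in column bin c (ascending u).  Bins are half-open with the top
    edge inclusive (numpy histogram convention).
    """

    grid: np.ndarray
    u_range: tuple[float, float]
    v_range: tuple[float, float]
    normalized: bool
    n_points_in: int
    n_points_clipped: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2 or min(self.grid.shape) < 1:
            raise ValueError("grid must be 2-D with at least one bin per axis")
        for lo, hi in (self.u_range, self.v_range):
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError("axis ranges must be finite with max > min")
        if np.any(self.grid < 0):
            raise ValueError("grid values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def occupied_bins(self) -> int:
        """Number of bins with nonzero occupancy."""
        return int(np.count_nonzero(self.grid))


def make_density_map(
    pts: ProjectedPoints,
    rows: int = DEFAULT_GRID,
    cols: int = DEFAULT_GRID,
    u_range: tuple[float, float] | None = None,
    v_range: tuple[float, float] | None = None,
) -> DensityMap:
    """Bin projected points into a rows x cols occupancy grid.

    When ranges are omitted a symmetric range of half-width
    ``1.05 * max(|u|, |v|)`` is used (so rescaled copies of one record map to
    the same raster).  Points outside the range are excluded and counted in
    ``n_points_clipped``.  Empty input with explicit ranges yields an
    all-zero map; empty input without ranges is an error.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if u_range is None or v_range is None:
        if len(pts) == 0:
            raise ValueError("cannot infer axis ranges from an empty point set")
        half = RANGE_PAD * float(max(np.abs(pts.u).max(), np.abs(pts.v).max()))
        if half == 0.0:
            half = 1e-6  # degenerate all-at-origin cloud
        auto = (-half, half)
        u_range = u_range or auto
        v_range = v_range or auto
    if len(pts) == 0:
        grid = np.zeros((rows, cols))
        return DensityMap(grid, u_range, v_range, False, 0, 0)
    hist, _, _ = np.histogram2d(
        pts.v, pts.u, bins=(rows, cols), range=(v_range, u_range)
    )
    n_in = int(hist.sum())
    return DensityMap(
        grid=hist,
        u_range=(float(u_range[0]), float(u_range[1])),
        v_range=(float(v_range[0]), float(v_range[1])),
        normalized=False,
        n_points_in=n_in,
        n_points_clipped=len(pts) - n_in,
    )


def normalize_density(dm: DensityMap, mode: str = "linear") -> DensityMap:
    """Scale a density map so its maximum is 1.

    ``linear``: grid / max.  ``log``: log1p(grid) / log1p(max), a monotone
    compression that keeps sparse structure visible.  An all-zero map is
    returned unchanged (never NaN).
    """
    if mode not in ("linear", "log"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    peak = float(dm.grid.max(initial=0.0))
    if peak == 0.0:
        return replace(dm, grid=dm.grid.copy(), normalized=True)
    if mode == "linear":
        grid = dm.grid / peak
    else:
        grid = np.log1p(dm.grid) / np.log1p(peak)
    return replace(dm, grid=grid, normalized=True)


def render_image(dm: DensityMap, path, colormap: str | None = None) -> None:
    """Write the density map as a rows x cols PNG, v increasing upward.

    Grayscale 8-bit by default; a matplotlib colormap name yields RGB.
    Output bytes are deterministic for identical maps.
    """
    from PIL import Image

    dmn = dm if dm.normalized else normalize_density(dm)
    # grid row 0 is the lowest v bin; flip so v increases upward in the image
    img8 = np.flipud(np.round(dmn.grid * 255.0)).astype(np.uint8)
    if colormap is None:
        im = Image.fromarray(img8, mode="L")
    else:
        import matplotlib

        rgba = matplotlib.colormaps[colormap](np.flipud(dmn.grid))
        im = Image.fromarray(np.round(rgba[..., :3] * 255.0).astype(np.uint8), "RGB")
    im.save(path, format="PNG")
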