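"""Super-resolution map construction.

Accumulating microbubble trajectories on a grid upsampled beyond the
acquisition pixel pitch yields the super-resolution vascular map: the count
map holds the number of distinct bubble passages through each SR pixel, the
velocity map the mean of the covering tracks' mean speeds, and the signed
axial-direction map the mean axial velocity component (positive = downward),
used to render opposite axial flow directions.  Maps are restricted to the
manually drawn lymph-node boundary, and per-plane maps acquired along a
motorized elevation sweep stack into a 3D volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import shapely

from .errors import InvalidParameterError, InvalidRoiError, OutOfBoundsError, ShapeMismatchError
from .tracking import Track


@dataclass
class SRGrid:
    """Super-resolution maps on an upsampled pixel grid.

    The SR pixel pitch is the acquisition pitch divided by ``factor``;
    SR pixel (0, 0) starts at the upper-left corner of acquisition pixel
    (0, 0), i.e. at −pitch/2 in μm.
    """

    factor: int
    counts: np.ndarray  # int32, (rows·factor, cols·factor)
    velocity: np.ndarray  # mm/s, 0 where counts == 0
    direction: np.ndarray  # signed axial mm/s, 0 where counts == 0
    pixel_size_axial_um: float
    pixel_size_lateral_um: float
    roi_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.counts.shape != self.velocity.shape or self.counts.shape != self.direction.shape:
            raise ShapeMismatchError("count/velocity/direction maps must share shape")
        if self.roi_mask is not None and self.roi_mask.shape != self.counts.shape:
            raise ShapeMismatchError("ROI mask must share the SR grid shape")

    @property
    def sr_pixel_sizes_um(self) -> tuple[float, float]:
        return (
            self.pixel_size_axial_um / self.factor,
            self.pixel_size_lateral_um / self.factor,
        )

    def roi_or_full(self) -> np.ndarray:
        if self.roi_mask is None:
            return np.ones_like(self.counts, dtype=bool)
        return self.roi_mask


@dataclass
class RoiPolygon:
    """Closed lymph-node boundary polygon with optional hilum point (μm)."""

    vertices_um: np.ndarray
    hilum_um: tuple[float, float] | None = None
    name: str = "LN"

    def __post_init__(self):
        self.vertices_um = np.asarray(self.vertices_um, dtype=np.float64)
        if self.vertices_um.ndim != 2 or len(self.vertices_um) < 3:
            raise InvalidRoiError("ROI polygon needs at least 3 vertices")
        poly = self.shapely()
        if not poly.is_valid:
            raise InvalidRoiError("ROI polygon is self-intersecting or degenerate")
        if self.hilum_um is not None:
            if not poly.covers(shapely.Point(self.hilum_um[1], self.hilum_um[0])):
                raise InvalidRoiError("hilum point lies outside the ROI polygon")

    def shapely(self) -> shapely.Polygon:
        # shapely uses (x, y) = (lateral, axial)
        return shapely.Polygon([(l, a) for a, l in self.vertices_um])


@dataclass
class Volume3D:
    """Ordered stack of per-plane SR grids with inter-plane spacing."""

    planes: list
    spacing_um: float

    def __post_init__(self):
        if not self.planes:
            raise InvalidParameterError("a volume needs at least one plane")
        if self.spacing_um <= 0:
            raise InvalidParameterError("plane spacing must be positive")
        shape = self.planes[0].counts.shape
        factor = self.planes[0].factor
        for p in self.planes[1:]:
            if p.counts.shape != shape or p.factor != factor:
                raise ShapeMismatchError("all planes must share grid shape and factor")

    @property
    def n_planes(self) -> int:
        return len(self.planes)

    @property
    def span_um(self) -> float:
        """Distance between first and last slice centers."""
        return (self.n_planes - 1) * self.spacing_um


def supercover_pixels(p0, p1) -> list[tuple[int, int]]:
    """All integer grid cells a 2D segment passes through (supercover).

    Coordinates are continuous grid coordinates (cell (i, j) spans
    [i, i+1) × [j, j+1)).  At an exact lattice-corner crossing, all four
    adjacent cells are included — no cell the segment touches is skipped.
    """
    r0, c0 = float(p0[0]), float(p0[1])
    r1, c1 = float(p1[0]), float(p1[1])
    dr, dc = r1 - r0, c1 - c0
    # parameter values where the segment crosses horizontal / vertical grid lines
    ts = {0.0, 1.0}
    for start, d in ((r0, dr), (c0, dc)):
        if d != 0:
            lo, hi = sorted((start, start + d))
            for g in range(math.ceil(lo), math.floor(hi) + 1):
                t = (g - start) / d
                if 0.0 <= t <= 1.0:
                    ts.add(t)
    ts = sorted(ts)
    cells: set[tuple[int, int]] = set()

    def add_point(r, c):
        # a point on a grid line belongs to every adjacent cell (supercover)
        rs = [math.floor(r)] if r != math.floor(r) else [math.floor(r) - 1, math.floor(r)]
        cs = [math.floor(c)] if c != math.floor(c) else [math.floor(c) - 1, math.floor(c)]
        for ri in rs:
            for ci in cs:
                cells.add((ri, ci))

    for ta, tb in zip(ts[:-1], ts[1:]):
        tm = 0.5 * (ta + tb)
        cells.add((math.floor(r0 + tm * dr), math.floor(c0 + tm * dc)))
    add_point(r0, c0)
    add_point(r1, c1)
    for t in ts[1:-1]:
        add_point(r0 + t * dr, c0 + t * dc)
    return sorted(cells)


def _to_sr_coords(positions_um, factor, pixel_sizes) -> np.ndarray:
    """Continuous SR grid coordinates of μm positions.

    Position 0 μm sits at the center of acquisition pixel 0, i.e. at SR
    coordinate factor/2.
    """
    pos = np.asarray(positions_um, dtype=np.float64)
    out = np.empty_like(pos)
    out[:, 0] = (pos[:, 0] + pixel_sizes[0] / 2.0) / (pixel_sizes[0] / factor)
    out[:, 1] = (pos[:, 1] + pixel_sizes[1] / 2.0) / (pixel_sizes[1] / factor)
    return out


def accumulate_map(
    tracks: list[Track],
    factor: int,
    fov_shape: tuple[int, int],
    pixel_sizes: tuple[float, float],
) -> SRGrid:
    """Rasterize tracks into SR accumulation / velocity / direction maps.

    Each track contributes at most one count per SR pixel (one bubble = one
    passage); the pixels covered are found by supercover rasterization of
    the polyline between consecutive localizations, so no pixel along a
    continuous trajectory is skipped.  Velocity at a pixel is the mean of
    the mean speeds of the tracks covering it; the direction map averages
    their mean axial velocity components.
    """
    if factor < 1:
        raise InvalidParameterError("upsampling factor must be >= 1")
    rows, cols = fov_shape
    sr_shape = (rows * factor, cols * factor)
    counts = np.zeros(sr_shape, dtype=np.int32)
    vsum = np.zeros(sr_shape, dtype=np.float64)
    dsum = np.zeros(sr_shape, dtype=np.float64)

    bad_ids = []
    for t in tracks:
        sr = _to_sr_coords(t.positions_um, factor, pixel_sizes)
        if (sr < 0).any() or (sr[:, 0] > sr_shape[0]).any() or (sr[:, 1] > sr_shape[1]).any():
            bad_ids.append(t.track_id)
    if bad_ids:
        raise OutOfBoundsError(
            f"track coordinates outside the field of view: {bad_ids}", track_ids=bad_ids
        )

    for t in tracks:
        sr = _to_sr_coords(t.positions_um, factor, pixel_sizes)
        covered: set[tuple[int, int]] = set()
        for a, b in zip(sr[:-1], sr[1:]):
            covered.update(supercover_pixels(a, b))
        for r, c in covered:
            if 0 <= r < sr_shape[0] and 0 <= c < sr_shape[1]:
                counts[r, c] += 1
                vsum[r, c] += t.mean_speed_mm_s
                dsum[r, c] += t.mean_velocity_mm_s[0]

    nz = counts > 0
    velocity = np.zeros(sr_shape)
    direction = np.zeros(sr_shape)
    velocity[nz] = vsum[nz] / counts[nz]
    direction[nz] = dsum[nz] / counts[nz]
    return SRGrid(
        factor=factor,
        counts=counts,
        velocity=velocity,
        direction=direction,
        pixel_size_axial_um=pixel_sizes[0],
        pixel_size_lateral_um=pixel_sizes[1],
    )


def sr_pixel_centers_um(grid: SRGrid) -> tuple[np.ndarray, np.ndarray]:
    """(axial, lateral) μm coordinates of every SR pixel center (meshgrid)."""
    sa, sl = grid.sr_pixel_sizes_um
    r = np.arange(grid.counts.shape[0])
    c = np.arange(grid.counts.shape[1])
    ax = -grid.pixel_size_axial_um / 2.0 + (r + 0.5) * sa
    lat = -grid.pixel_size_lateral_um / 2.0 + (c + 0.5) * sl
    return np.meshgrid(ax, lat, indexing="ij")


def apply_roi(grid: SRGrid, roi: RoiPolygon) -> SRGrid:
    """Zero the maps outside the LN boundary polygon.

    A pixel survives iff its center is inside or on the polygon (even-odd
    rule; the boundary counts as inside).
    """
    poly = roi.shapely()
    ax, lat = sr_pixel_centers_um(grid)
    pts = shapely.points(lat.ravel(), ax.ravel())
    mask = shapely.covers(poly, pts).reshape(grid.counts.shape)
    counts = np.where(mask, grid.counts, 0).astype(np.int32)
    velocity = np.where(mask, grid.velocity, 0.0)
    direction = np.where(mask, grid.direction, 0.0)
    return SRGrid(
        factor=grid.factor,
        counts=counts,
        velocity=velocity,
        direction=direction,
        pixel_size_axial_um=grid.pixel_size_axial_um,
        pixel_size_lateral_um=grid.pixel_size_lateral_um,
        roi_mask=mask,
    )


def stack_planes(planes: list[SRGrid], spacing_um: float = 150.0) -> Volume3D:
    """Stack per-plane SR grids into an ordered volume (no registration)."""
    return Volume3D(planes=list(planes), spacing_um=spacing_um)
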