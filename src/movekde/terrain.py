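"""Terrain surface areas and the 2.5D area-corrected utilization distribution.

Planimetric cell areas systematically understate the ground area available to
a terrestrial animal on rugged terrain. The correction tessellates each
raster cell into eight 3D triangular facets: the cell's four corners and four
side midpoints (elevations by bilinear interpolation among the surrounding
cell centers) fan around the cell-center vertex, and each facet's area comes
from its three 3D side lengths via Heron's formula. The per-cell surface
area is then at least the planimetric area, with equality on flat terrain.

A 2D movement-based UD is corrected by weighting each cell's probability by
its surface area and renormalizing; home-range areas are reported by summing
surface areas of cells inside a probability contour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElevationRaster",
    "SurfaceAreaRaster",
    "bilinear_elevation",
    "cell_surface_area",
    "surface_area_raster",
    "adjust_ud_25d",
    "area_within_contour",
]


@dataclass(frozen=True)
class ElevationRaster:
    """Square-cell elevation grid; row 0 holds the minimum-y cells.

    ``values`` has shape (n_rows, n_cols) with NaN marking nodata; ``x0, y0``
    is the lower-left *corner* of the grid and ``cell`` the cell edge (m).
    """

    x0: float
    y0: float
    cell: float
    values: np.ndarray
    nodata_value: float = -9999.0

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be > 0, got {self.cell}")
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("elevation values must be 2D")
        object.__setattr__(self, "values", v)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.n_rows) + 0.5) * self.cell

    def value_at(self, x: float, y: float) -> float:
        """Nearest-cell elevation at a planar point."""
        j = int(np.floor((x - self.x0) / self.cell))
        i = int(np.floor((y - self.y0) / self.cell))
        if not (0 <= i < self.n_rows and 0 <= j < self.n_cols):
            raise ValueError(f"point ({x}, {y}) outside raster extent")
        return float(self.values[i, j])


@dataclass(frozen=True)
class SurfaceAreaRaster:
    """Per-cell terrain surface areas (m^2), same geometry as the source DEM."""

    x0: float
    y0: float
    cell: float
    values: np.ndarray  # NaN where not computable (edge ring / nodata)

    @property
    def planimetric_cell_area(self) -> float:
        return self.cell * self.cell


def bilinear_elevation(dem: ElevationRaster, x, y):
    """Bilinear interpolation among the four surrounding cell centers.

    Accepts scalars or arrays. Points outside the convex hull of cell
    centers, or with a nodata neighbor, raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    # fractional index relative to cell centers
    fx = (x - (dem.x0 + 0.5 * dem.cell)) / dem.cell
    fy = (y - (dem.y0 + 0.5 * dem.cell)) / dem.cell
    j0 = np.floor(fx).astype(int)
    i0 = np.floor(fy).astype(int)
    # allow points exactly on the far edge of the center hull
    j0 = np.where((j0 == dem.n_cols - 1) & (fx == j0), j0 - 1, j0)
    i0 = np.where((i0 == dem.n_rows - 1) & (fy == i0), i0 - 1, i0)
    if np.any(j0 < 0) or np.any(j0 > dem.n_cols - 2) or np.any(i0 < 0) or np.any(
        i0 > dem.n_rows - 2
    ):
        raise ValueError("point outside the convex hull of DEM cell centers")
    tx = fx - j0
    ty = fy - i0
    z00 = dem.values[i0, j0]
    z01 = dem.values[i0, j0 + 1]
    z10 = dem.values[i0 + 1, j0]
    z11 = dem.values[i0 + 1, j0 + 1]
    if np.any(np.isnan(np.stack([z00, z01, z10, z11]))):
        raise ValueError("bilinear interpolation touches a nodata cell")
    out = (
        z00 * (1 - tx) * (1 - ty)
        + z01 * tx * (1 - ty)
        + z10 * (1 - tx) * ty
        + z11 * tx * ty
    )
    return out if out.ndim else float(out)


def _heron(p: np.ndarray, q: np.ndarray, r: np.ndarray) -> float:
    a = float(np.linalg.norm(q - p))
    b = float(np.linalg.norm(r - q))
    c = float(np.linalg.norm(p - r))
    s = 0.5 * (a + b + c)
    val = s * (s - a) * (s - b) * (s - c)
    return math.sqrt(max(val, 0.0))


def cell_surface_area(dem: ElevationRaster, i: int, j: int) -> float:
    """Surface area (m^2) of interior cell (i, j) from the 8-facet fan.

    The eight perimeter vertices are the cell's corners and side midpoints
    with bilinearly interpolated elevations; the fan's apex is the cell
    center at its DEM elevation.
    """
    if not (1 <= i <= dem.n_rows - 2 and 1 <= j <= dem.n_cols - 2):
        raise ValueError(
            f"cell ({i}, {j}) is not interior (needs all 8 neighbors)"
        )
    c = dem.cell
    cx = dem.x0 + (j + 0.5) * c
    cy = dem.y0 + (i + 0.5) * c
    h = 0.5 * c
    # perimeter in cyclic order: corner, mid, corner, mid, ...
    ring_xy = [
        (cx - h, cy - h), (cx, cy - h), (cx + h, cy - h), (cx + h, cy),
        (cx + h, cy + h), (cx, cy + h), (cx - h, cy + h), (cx - h, cy),
    ]
    zc = dem.values[i, j]
    if np.isnan(zc):
        raise ValueError(f"cell ({i}, {j}) is nodata")
    center = np.array([cx, cy, zc])
    ring = [
        np.array([px, py, bilinear_elevation(dem, px, py)]) for px, py in ring_xy
    ]
    area = 0.0
    for k in range(8):
        area += _heron(center, ring[k], ring[(k + 1) % 8])
    return area


def surface_area_raster(
    dem: ElevationRaster, edge_policy: str = "exclude"
) -> SurfaceAreaRaster:
    """Surface areas for all cells; the boundary ring follows ``edge_policy``.

    ``exclude`` (default) leaves the ring NaN; ``replicate`` pads the DEM by
    replicating the nearest elevations so ring cells can be computed too.
    Cells whose 3x3 neighborhood touches nodata are NaN.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("DEM must be at least 3x3")
    if edge_policy not in ("exclude", "replicate"):
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    work = dem
    offset = 0
    if edge_policy == "replicate":
        padded = np.pad(dem.values, 1, mode="edge")
        work = ElevationRaster(
            x0=dem.x0 - dem.cell,
            y0=dem.y0 - dem.cell,
            cell=dem.cell,
            values=padded,
            nodata_value=dem.nodata_value,
        )
        offset = 1
    out = np.full((dem.n_rows, dem.n_cols), np.nan)
    for i in range(dem.n_rows):
        for j in range(dem.n_cols):
            ii, jj = i + offset, j + offset
            if not (1 <= ii <= work.n_rows - 2 and 1 <= jj <= work.n_cols - 2):
                continue
            patch = work.values[ii - 1 : ii + 2, jj - 1 : jj + 2]
            if np.any(np.isnan(patch)):
                continue
            out[i, j] = cell_surface_area(work, ii, jj)
    return SurfaceAreaRaster(x0=dem.x0, y0=dem.y0, cell=dem.cell, values=out)


def _check_registration(ud2d, areas: SurfaceAreaRaster) -> None:
    spec = ud2d.spec
    if ud2d.ndim != 2:
        raise ValueError("2.5D adjustment applies to a 2D UD")
    if not (
        math.isclose(2 * spec.hx, areas.cell)
        and math.isclose(2 * spec.hy, areas.cell)
        and math.isclose(spec.x0, areas.x0)
        and math.isclose(spec.y0, areas.y0)
        and spec.I == areas.values.shape[0]
        and spec.J == areas.values.shape[1]
    ):
        raise ValueError("UD grid and surface-area raster are not co-registered")


def adjust_ud_25d(ud2d, areas: SurfaceAreaRaster):
    """Area-corrected 2D UD: P'_ij = P_ij * S_ij / sum(P * S).

    Cells where the surface area is unavailable (edge ring or nodata) fall
    back to the planimetric area, i.e. receive no correction.
    """
    from .grid import UDGrid

    _check_registration(ud2d, areas)
    S = np.where(np.isnan(areas.values), areas.planimetric_cell_area, areas.values)
    weighted = ud2d.probs * S
    total = weighted.sum()
    if total <= 0:
        raise ValueError("UD has no probability mass to adjust")
    meta = dict(ud2d.metadata)
    meta["area_corrected"] = True
    return UDGrid(
        spec=ud2d.spec,
        probs=weighted / total,
        ndim=2,
        total_time=ud2d.total_time,
        metadata=meta,
        bounds=ud2d.bounds,
    )


def area_within_contour(ud25, areas: SurfaceAreaRaster, p: float) -> float:
    """Terrain surface area (m^2) inside the p-probability contour."""
    from .contours import contour_threshold

    _check_registration(ud25, areas)
    thr = contour_threshold(ud25.probs, p)
    members = ud25.probs >= thr
    S = np.where(np.isnan(areas.values), areas.planimetric_cell_area, areas.values)
    return float(S[members].sum())
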