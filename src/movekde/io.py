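"""Readers and writers: telemetry tables, rasters, UD tables, ASCII VTK.

All writers are deterministic (fixed ordering, scientific notation with nine
significant digits) so identical inputs produce byte-identical files.
Rasters are normalized on read to the package convention: row 0 holds the
minimum-y cells and the origin is the grid's lower-left corner.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .grid import GridSpec3D, UDGrid
from .interaction import InteractionGrid
from .telemetry import ErrorModel, Track, build_track
from .terrain import ElevationRaster

__all__ = [
    "read_telemetry",
    "read_dem",
    "write_dem_ascii",
    "write_vtk",
    "write_table",
]

_FMT = "%.8e"  # nine significant digits


def read_telemetry(
    path: Union[str, Path],
    error: ErrorModel,
    sep: str = ",",
) -> dict[str, Track]:
    """Read a delimited fix table with header columns id,time,x,y,z.

    ``time`` may be ISO-8601 timestamps or numeric minutes; within each
    animal's track times are normalized to minutes from its first fix.
    Returns one :class:`Track` per animal id.
    """
    df = pd.read_csv(path, sep=sep)
    required = ["id", "time", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(bad | df[col].isna())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric {col!r} at line {row}")
        df[col] = pd.to_numeric(df[col])
    t_num = pd.to_numeric(df["time"], errors="coerce")
    if t_num.notna().all():
        minutes = t_num.astype(float)
    else:
        stamps = pd.to_datetime(df["time"], errors="coerce", format="ISO8601")
        if stamps.isna().any():
            row = int(np.flatnonzero(stamps.isna())[0]) + 2
            raise ValueError(f"{path}: unparseable time at line {row}")
        minutes = stamps.astype("int64") / (60 * 1e9)
    df = df.assign(_minutes=minutes)
    tracks: dict[str, Track] = {}
    for animal_id, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("_minutes")
        t0 = sub["_minutes"].iloc[0]
        rows = [
            (str(animal_id), float(t - t0), float(x), float(y), float(z))
            for t, x, y, z in zip(sub["_minutes"], sub["x"], sub["y"], sub["z"])
        ]
        tracks[str(animal_id)] = build_track(rows, error)
    return tracks


# ---------------------------------------------------------------------------
# rasters


def _read_esri_ascii(path: Path) -> ElevationRaster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                "yllcenter", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: ESRI ASCII grid missing {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"{path}: data shape {data.shape} != header ({nrows}, {ncols})"
        )
    if "xllcorner" in header:
        x0 = header["xllcorner"]
    else:
        x0 = header["xllcenter"] - cell / 2.0
    if "yllcorner" in header:
        y0 = header["yllcorner"]
    else:
        y0 = header["yllcenter"] - cell / 2.0
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(data == nodata, np.nan, data)
    # ESRI ASCII stores the top row first; flip to row 0 = min y
    return ElevationRaster(
        x0=x0, y0=y0, cell=cell, values=values[::-1].copy(), nodata_value=nodata
    )


def _read_geotiff(path: Path) -> ElevationRaster:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        tags = {t.code: t.value for t in page.tags.values()}
    if 33550 not in tags or 33922 not in tags:
        raise ValueError(
            f"{path}: TIFF lacks GeoTIFF georeferencing tags "
            "(ModelPixelScale/ModelTiepoint)"
        )
    sx, sy = float(tags[33550][0]), float(tags[33550][1])
    tie = tags[33922]
    x_ul, y_ul = float(tie[3]), float(tie[4])
    if not math.isclose(sx, sy):
        raise ValueError(f"{path}: non-square cells ({sx} x {sy}) unsupported")
    nrows, ncols = data.shape
    nodata = None
    if 42113 in tags:  # GDAL_NODATA, stored as ASCII
        try:
            nodata = float(str(tags[42113]).strip("\x00 "))
        except ValueError:
            nodata = None
    values = data
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    # TIFF row 0 is the top (max y); flip to row 0 = min y
    return ElevationRaster(
        x0=x_ul,
        y0=y_ul - nrows * sy,
        cell=sx,
        values=values[::-1].copy(),
        nodata_value=nodata if nodata is not None else -9999.0,
    )


def read_dem(path: Union[str, Path]) -> ElevationRaster:
    """Read a GeoTIFF or ESRI ASCII grid elevation raster."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".asc", ".grd", ".txt"):
        return _read_esri_ascii(path)
    if suffix in (".tif", ".tiff"):
        return _read_geotiff(path)
    # sniff: TIFF magic bytes, else try ASCII
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] in (b"II", b"MM"):
        return _read_geotiff(path)
    try:
        return _read_esri_ascii(path)
    except Exception as exc:
        raise ValueError(
            f"{path}: unsupported raster dialect (not GeoTIFF or ESRI ASCII): {exc}"
        ) from exc


def write_dem_ascii(dem: ElevationRaster, path: Union[str, Path]) -> None:
    """Write an elevation raster as an ESRI ASCII grid (top row first)."""
    values = np.where(np.isnan(dem.values), dem.nodata_value, dem.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {dem.n_cols}\n")
        fh.write(f"nrows {dem.n_rows}\n")
        fh.write(f"xllcorner {dem.x0!r}\n")
        fh.write(f"yllcorner {dem.y0!r}\n")
        fh.write(f"cellsize {dem.cell!r}\n")
        fh.write(f"NODATA_value {dem.nodata_value!r}\n")
        for row in values[::-1]:
            fh.write(" ".join(_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# grid exports


def _grid_field(grid: Union[UDGrid, InteractionGrid]) -> tuple[GridSpec3D, np.ndarray, int]:
    if isinstance(grid, UDGrid):
        return grid.spec, grid.probs, grid.ndim
    return grid.spec, grid.local, grid.ndim


def write_vtk(
    grid: Union[UDGrid, InteractionGrid],
    path: Union[str, Path],
    field_name: str = "probability",
) -> None:
    """Write a legacy ASCII VTK STRUCTURED_POINTS volume of the grid field.

    Values sit at voxel centers as point data, in x-fastest order, with
    spacing equal to the full voxel edge lengths.
    """
    spec, field, ndim = _grid_field(grid)
    K = spec.K if ndim == 3 else 1
    vals = field if ndim == 3 else field[:, :, None]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{field_name}\n")
        fh.write("ASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {spec.J} {spec.I} {K}\n")
        fh.write(
            "ORIGIN " + " ".join(
                _FMT % v
                for v in (spec.x0 + spec.hx, spec.y0 + spec.hy, spec.z0 + spec.hz)
            ) + "\n"
        )
        fh.write(
            "SPACING " + " ".join(_FMT % v for v in (spec.dx, spec.dy, spec.dz)) + "\n"
        )
        fh.write(f"POINT_DATA {spec.I * spec.J * K}\n")
        fh.write(f"SCALARS {field_name} float\n")
        fh.write("LOOKUP_TABLE default\n")
        for k in range(K):
            for i in range(spec.I):
                fh.write(
                    " ".join(_FMT % vals[i, j, k] for j in range(spec.J)) + "\n"
                )


def write_table(
    grid: Union[UDGrid, InteractionGrid],
    path: Union[str, Path],
    dense: bool = False,
) -> None:
    """Write the grid field as delimited text: i,j,k,x,y,z,value.

    k and z are omitted for 2D grids. By default only nonzero voxels are
    written, in linear-index order; ``dense`` writes every voxel.
    """
    spec, field, ndim = _grid_field(grid)
    xc, yc, zc = spec.x_centers, spec.y_centers, spec.z_centers
    with open(path, "w") as fh:
        if ndim == 2:
            fh.write("i,j,x,y,value\n")
            for j in range(spec.J):
                for i in range(spec.I):
                    v = field[i, j]
                    if dense or v != 0.0:
                        fh.write(f"{i},{j},{_FMT % xc[j]},{_FMT % yc[i]},{_FMT % v}\n")
        else:
            fh.write("i,j,k,x,y,z,value\n")
            for k in range(spec.K):
                for j in range(spec.J):
                    for i in range(spec.I):
                        v = field[i, j, k]
                        if dense or v != 0.0:
                            fh.write(
                                f"{i},{j},{k},{_FMT % xc[j]},{_FMT % yc[i]},"
                                f"{_FMT % zc[k]},{_FMT % v}\n"
                            )
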