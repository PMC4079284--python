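"""Seeded synthetic data: analytic DEMs and Brownian telemetry tracks.

The track generator realizes exactly the process the estimator assumes:
independent Brownian motion per axis with diffusion rates eta^2 (x, y) and
gamma^2 (z) in m^2/min, mirror-reflected in z at an optional terrain floor
and/or ceiling, sampled on a regular fix schedule with optional dropouts,
and observed through additive Gaussian error. The noise-free path is
returned alongside the observed track so recovery tests never re-derive it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .telemetry import ErrorModel, Track, build_track
from .terrain import ElevationRaster

__all__ = ["SimConfig", "generate_dem", "simulate_track"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic tracking deployment.

    Defaults mirror a GPS deployment of the kind the estimator targets:
    moderate horizontal diffusion, 10-minute fix schedule, and horizontal
    error variance of 25 m^2 per axis.
    """

    eta2: float = 100.0  # m^2/min
    gamma2: float = 1.0  # m^2/min
    fix_interval: float = 10.0  # minutes
    n_fixes: int = 500
    var_xy: float = 25.0  # m^2
    var_z: float = 4.0  # m^2
    dropout: float = 0.0
    seed: int = 0
    start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    animal_id: str = "sim"

    def __post_init__(self) -> None:
        if min(self.eta2, self.gamma2) < 0:
            raise ValueError("diffusion rates must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.fix_interval <= 0 or self.n_fixes < 2:
            raise ValueError("need a positive fix interval and >= 2 fixes")


def generate_dem(
    kind: str,
    n_rows: int = 11,
    n_cols: int = 11,
    cell: float = 30.0,
    x0: float = 0.0,
    y0: float = 0.0,
    **params,
) -> ElevationRaster:
    """Deterministic analytic elevation surfaces with known geometry.

    Kinds: ``flat`` (value), ``ramp`` (theta_deg, azimuth 'x'|'y'),
    ``gaussian_hill`` (amp, width), ``sinusoidal_bathymetry`` (amp, period,
    mean_depth; elevations negative below the 0 water surface).
    """
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    x = x0 + (jj + 0.5) * cell
    y = y0 + (ii + 0.5) * cell
    if kind == "flat":
        z = np.full((n_rows, n_cols), float(params.get("value", 0.0)))
    elif kind == "ramp":
        theta = math.radians(params.get("theta_deg", 15.0))
        slope = math.tan(theta)
        axis = params.get("azimuth", "x")
        z = slope * (x - x0) if axis == "x" else slope * (y - y0)
    elif kind == "gaussian_hill":
        amp = float(params.get("amp", 100.0))
        width = float(params.get("width", n_cols * cell / 6.0))
        cx = x0 + n_cols * cell / 2.0
        cy = y0 + n_rows * cell / 2.0
        z = amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * width**2))
    elif kind == "sinusoidal_bathymetry":
        amp = float(params.get("amp", 2.0))
        period = float(params.get("period", n_cols * cell / 2.0))
        mean_depth = float(params.get("mean_depth", 4.0))
        z = -mean_depth + amp * np.sin(2.0 * np.pi * (x - x0) / period)
    else:
        raise ValueError(f"unknown DEM kind {kind!r}")
    return ElevationRaster(x0=x0, y0=y0, cell=cell, values=np.asarray(z, float))


def _reflect(z: float, lo: float, hi: float) -> float:
    """Mirror-reflect z into [lo, hi] (repeatedly, for large excursions)."""
    if not (np.isfinite(lo) or np.isfinite(hi)):
        return z
    if np.isfinite(lo) and not np.isfinite(hi):
        return lo + abs(z - lo)
    if np.isfinite(hi) and not np.isfinite(lo):
        return hi - abs(hi - z)
    width = hi - lo
    if width <= 0:
        return lo
    u = (z - lo) % (2.0 * width)
    return lo + (u if u <= width else 2.0 * width - u)


def simulate_track(
    cfg: SimConfig,
    dem: Optional[ElevationRaster] = None,
    ceiling: Optional[float] = None,
) -> tuple[Track, pd.DataFrame]:
    """Simulate one track; returns (observed Track, true-path DataFrame).

    The floor, if a DEM is given, is its elevation at the path's current
    planar position; the ceiling is a constant. The true path is reflected
    at the active bounds; observations add Gaussian error and never re-apply
    the bounds (mimicking fixes that can fall below ground).
    """
    rng = np.random.default_rng(cfg.seed)
    dt = cfg.fix_interval
    sd_xy = math.sqrt(cfg.eta2 * dt)
    sd_z = math.sqrt(cfg.gamma2 * dt)
    x, y, z = cfg.start
    hi = np.inf if ceiling is None else float(ceiling)
    rows_true = []
    for m in range(cfg.n_fixes):
        if m > 0:
            x += rng.normal(0.0, sd_xy) if sd_xy > 0 else 0.0
            y += rng.normal(0.0, sd_xy) if sd_xy > 0 else 0.0
            z += rng.normal(0.0, sd_z) if sd_z > 0 else 0.0
        lo = -np.inf
        if dem is not None:
            try:
                lo = dem.value_at(x, y)
            except ValueError:
                lo = -np.inf  # wandered off the raster: unbounded below
        z = _reflect(z, lo, hi)
        rows_true.append((m * dt, x, y, z))
    truth = pd.DataFrame(rows_true, columns=["t", "x", "y", "z"])
    keep = np.ones(cfg.n_fixes, dtype=bool)
    if cfg.dropout > 0:
        keep = rng.random(cfg.n_fixes) >= cfg.dropout
        keep[0] = keep[-1] = True  # guarantee a valid track
    err = ErrorModel(var_xy=cfg.var_xy, var_z=cfg.var_z)
    noise = rng.normal(size=(cfg.n_fixes, 3)) * np.array(
        [math.sqrt(cfg.var_xy), math.sqrt(cfg.var_xy), math.sqrt(cfg.var_z)]
    )
    rows = [
        (
            cfg.animal_id,
            truth.t[m],
            truth.x[m] + noise[m, 0],
            truth.y[m] + noise[m, 1],
            truth.z[m] + noise[m, 2],
        )
        for m in range(cfg.n_fixes)
        if keep[m]
    ]
    return build_track(rows, err), truth
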