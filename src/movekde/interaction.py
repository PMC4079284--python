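"""Spatio-temporal interaction between two tracked animals.

The statistic extends the Bhattacharyya coefficient BC = integral of
sqrt(f_A * f_B) to temporally matched movement kernels: at each time inside a
matched pair of move steps, the square root of the product of the two
animals' kernels is integrated over space, then averaged over matched time.
Because each kernel is a product of axis-wise Gaussians, the square-root
product factorizes per axis into a scaled Gaussian:

    sqrt(N(mu_A, s2_A) * N(mu_B, s2_B)) = BC_axis * N(mu_c, s2_c)

    BC_axis = sqrt(2 s_A s_B / (s2_A + s2_B))
              * exp(-(mu_A - mu_B)^2 / (4 (s2_A + s2_B)))
    mu_c    = (mu_A s2_B + mu_B s2_A) / (s2_A + s2_B)
    s2_c    = 2 s2_A s2_B / (s2_A + s2_B)

so voxel values are products of BC_axis and CDF differences of the combined
Gaussian. Summed over voxels and time-averaged, the global score lies in
[0, 1]: 0 for no spatio-temporal overlap, 1 for identical kernels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .grid import (
    DEFAULT_BUFFER_SD,
    GridSpec3D,
    SnappedBounds,
    _axis_masses,
    _axis_window,
    _unravel,
)
from .kernel import MovementVariances, kernel_state, reflected_z_interval_mass
from .telemetry import ErrorModel, MoveStep, Observation, Track

__all__ = [
    "MatchedStepPair",
    "InteractionGrid",
    "match_steps",
    "pair_voxel_masses",
    "interaction_ud",
]


@dataclass(frozen=True)
class MatchedStepPair:
    """Two usable move steps sharing one time support [t0, t1]."""

    step_A: MoveStep
    step_B: MoveStep

    def __post_init__(self) -> None:
        if not (self.step_A.usable and self.step_B.usable):
            raise ValueError("both steps of a matched pair must be usable")
        if not (
            math.isclose(self.step_A.start.t, self.step_B.start.t)
            and math.isclose(self.step_A.end.t, self.step_B.end.t)
        ):
            raise ValueError("matched steps must share their time support")

    @property
    def dt(self) -> float:
        return self.step_A.dt


@dataclass(frozen=True)
class InteractionGrid:
    """Local (per-voxel) and global spatio-temporal similarity."""

    spec: GridSpec3D
    local: np.ndarray
    global_similarity: float
    matched_duration: float
    ndim: int = 3
    metadata: dict | None = None


def _retime(obs: Observation, t: float) -> Observation:
    return Observation(x=obs.x, y=obs.y, z=obs.z, t=t)


def match_steps(
    steps_A: Sequence[MoveStep],
    steps_B: Sequence[MoveStep],
    tolerance: float = 0.0,
) -> list[MatchedStepPair]:
    """Pair usable steps whose endpoint times agree within ``tolerance`` min.

    Matched steps are re-timed onto the average of the two schedules so the
    pair shares an exact common support. Each step matches at most once.
    """
    usable_B = [s for s in steps_B if s.usable]
    pairs: list[MatchedStepPair] = []
    used_b: set[int] = set()
    for sa in (s for s in steps_A if s.usable):
        for sb in usable_B:
            if sb.index in used_b:
                continue
            if (
                abs(sa.start.t - sb.start.t) <= tolerance
                and abs(sa.end.t - sb.end.t) <= tolerance
            ):
                t0 = 0.5 * (sa.start.t + sb.start.t)
                t1 = 0.5 * (sa.end.t + sb.end.t)
                a = replace(sa, start=_retime(sa.start, t0), end=_retime(sa.end, t1))
                b = replace(sb, start=_retime(sb.start, t0), end=_retime(sb.end, t1))
                pairs.append(MatchedStepPair(step_A=a, step_B=b))
                used_b.add(sb.index)
                break
    return pairs


def _bc_axis(mu_a, s2_a, mu_b, s2_b):
    """Coefficient, mean and variance of sqrt(N_A * N_B) along one axis."""
    s2_sum = s2_a + s2_b
    coef = math.sqrt(2.0 * math.sqrt(s2_a * s2_b) / s2_sum) * math.exp(
        -((mu_a - mu_b) ** 2) / (4.0 * s2_sum)
    )
    mu_c = (mu_a * s2_b + mu_b * s2_a) / s2_sum
    s2_c = 2.0 * s2_a * s2_b / s2_sum
    return coef, mu_c, s2_c


def pair_voxel_masses(
    pair: MatchedStepPair,
    mv_A: MovementVariances,
    mv_B: MovementVariances,
    err_A: ErrorModel,
    err_B: ErrorModel,
    spec: GridSpec3D,
    bounds: Optional[SnappedBounds] = None,
    dt_int: float = 1.0,
    buffer_sd: float = DEFAULT_BUFFER_SD,
    ndim: int = 3,
    normalize: bool = True,
) -> dict[int, float]:
    """Per-voxel similarity contribution of one matched step pair.

    With ``normalize`` (default) values are divided by the pair duration, so
    identical kernels sum to 1 over a covering grid; with ``normalize=False``
    the raw time-integral (minutes) is returned for aggregation.
    """
    if dt_int <= 0:
        raise ValueError("dt_int must be > 0")
    dt = pair.dt
    n_sub = max(1, int(round(dt / dt_int)))
    dt_eff = dt / n_sub
    shape = (spec.I, spec.J) if ndim == 2 else (spec.I, spec.J, spec.K)
    acc = np.zeros(shape)
    for s in range(n_sub):
        t = pair.step_A.start.t + (s + 0.5) * dt_eff
        sa = kernel_state(pair.step_A, t, mv_A, err_A)
        sb = kernel_state(pair.step_B, t, mv_B, err_B)
        if min(sa.var_xy, sb.var_xy, sa.var_z, sb.var_z) <= 0:
            raise ValueError("degenerate kernel variance in matched pair")
        cx, mx, vx = _bc_axis(sa.mu[0], sa.var_xy, sb.mu[0], sb.var_xy)
        cy, my, vy = _bc_axis(sa.mu[1], sa.var_xy, sb.mu[1], sb.var_xy)
        sdx, sdy = math.sqrt(vx), math.sqrt(vy)
        j0, j1 = _axis_window(mx, buffer_sd * sdx, spec.x0, spec.dx, spec.J)
        i0, i1 = _axis_window(my, buffer_sd * sdy, spec.y0, spec.dy, spec.I)
        if j1 <= j0 or i1 <= i0:
            continue
        xm = cx * _axis_masses(mx, sdx, spec.x_edges, j0, j1)
        ym = cy * _axis_masses(my, sdy, spec.y_edges, i0, i1)
        if ndim == 2:
            acc[i0:i1, j0:j1] += dt_eff * np.outer(ym, xm)
            continue
        cz, mz, vz = _bc_axis(sa.mu[2], sa.var_z, sb.mu[2], sb.var_z)
        sdz = math.sqrt(vz)
        k0, k1 = _axis_window(mz, buffer_sd * sdz, spec.z0, spec.dz, spec.K)
        if k1 <= k0:
            continue
        ze = spec.z_edges
        if bounds is None:
            zm = cz * _axis_masses(mz, sdz, ze, k0, k1)
            acc[i0:i1, j0:j1, k0:k1] += dt_eff * (
                ym[:, None, None] * xm[None, :, None] * zm[None, None, :]
            )
        else:
            # boundary correction applied to the combined Gaussian
            zmat = _bounded_combined_z(
                mz, vz, spec, bounds, i0, i1, j0, j1, k0, k1
            )
            acc[i0:i1, j0:j1, k0:k1] += dt_eff * cz * (
                ym[:, None, None] * xm[None, :, None] * zmat
            )
    if normalize:
        acc /= dt
    flat_idx = np.nonzero(acc)
    if ndim == 2:
        v = spec.voxel_index(flat_idx[0], flat_idx[1])
    else:
        v = spec.voxel_index(flat_idx[0], flat_idx[1], flat_idx[2])
    return dict(zip(v.tolist(), acc[flat_idx].tolist()))


def _bounded_combined_z(mz, vz, spec, bounds, i0, i1, j0, j1, k0, k1):
    ze = spec.z_edges
    zlo_w = bounds.z_lo[i0:i1, j0:j1]
    zhi_w = bounds.z_hi[i0:i1, j0:j1]
    klo_w = bounds.k_lo[i0:i1, j0:j1]
    khi_w = bounds.k_hi[i0:i1, j0:j1]
    out = np.zeros((i1 - i0, j1 - j0, k1 - k0))
    pairs = np.stack(
        [zlo_w.ravel(), zhi_w.ravel(), klo_w.ravel(), khi_w.ravel()], axis=1
    )
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    inverse = inverse.reshape(zlo_w.shape)
    for u_idx in range(uniq.shape[0]):
        a, b, klo, khi = uniq[u_idx]
        ka, kb = max(k0, int(klo)), min(k1, int(khi))
        if kb <= ka:
            continue
        zm = reflected_z_interval_mass(
            mz, vz, ze[ka:kb], ze[ka + 1 : kb + 1], a=a, b=b
        )
        out[inverse == u_idx, ka - k0 : kb - k0] = np.asarray(zm)
    return out


def interaction_ud(
    track_A: Track,
    steps_A: Sequence[MoveStep],
    track_B: Track,
    steps_B: Sequence[MoveStep],
    mv_A: MovementVariances,
    mv_B: MovementVariances,
    spec: GridSpec3D,
    bounds: Optional[SnappedBounds] = None,
    dt_int: float = 1.0,
    tolerance: float = 0.0,
    buffer_sd: float = DEFAULT_BUFFER_SD,
    ndim: int = 3,
) -> InteractionGrid:
    """Local and global spatio-temporal similarity of two animals.

    Pairs are weighted by their duration and the sum is normalized by the
    total matched duration; unmatched time does not enter the normalizer.
    """
    pairs = match_steps(steps_A, steps_B, tolerance=tolerance)
    if not pairs:
        raise ValueError("no temporally matched usable step pairs")
    T_matched = sum(p.dt for p in pairs)
    shape = (spec.I, spec.J) if ndim == 2 else (spec.I, spec.J, spec.K)
    acc = np.zeros(shape)
    for pr in pairs:
        masses = pair_voxel_masses(
            pr, mv_A, mv_B, track_A.error, track_B.error, spec,
            bounds=bounds, dt_int=dt_int, buffer_sd=buffer_sd, ndim=ndim,
            normalize=False,
        )
        for v, val in masses.items():
            acc[_unravel(v, spec, ndim)] += val
    local = acc / T_matched
    total_A = sum(s.dt for s in steps_A if s.usable)
    total_B = sum(s.dt for s in steps_B if s.usable)
    return InteractionGrid(
        spec=spec,
        local=local,
        global_similarity=float(local.sum()),
        matched_duration=T_matched,
        ndim=ndim,
        metadata={
            "n_pairs": len(pairs),
            "usable_duration_A": total_A,
            "usable_duration_B": total_B,
            "dt_int": dt_int,
        },
    )
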