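"""Time-dependent Brownian-bridge movement kernel.

Within a usable move step the true path is approximated by linear
interpolation between the two observed endpoints. Conditioning a Brownian
motion on noisy endpoints gives, at within-step time fraction
alpha = (t - t_m) / dt, a Gaussian kernel per axis with

    mean      mu(t)   = (1 - alpha) * loc_m + alpha * loc_{m+1}
    variance  var(t)  = dt * alpha * (1 - alpha) * sigma2_move
                        + ((1 - alpha)^2 + alpha^2) * var_obs

where sigma2_move is the diffusion coefficient (m^2/min) for that axis
(eta^2 horizontally, gamma^2 vertically) and var_obs the observation-error
variance. The variance is smallest at the endpoints (observation error only)
and maximal mid-interval. The 3D kernel is the product of the three
univariate normals (zero covariance across axes, equal x/y variance).

When movement is bounded in z by a <= z <= b, the kernel mass that would fall
beyond a boundary is reflected back: the density on [a, b] gains the mirror
images about a (z -> 2a - z) and about b (z -> 2b - z). A single reflection
per active boundary is applied, which is accurate whenever the domain height
b - a is large relative to the kernel SD in z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .telemetry import ErrorModel, MoveStep

__all__ = [
    "MovementVariances",
    "KernelState",
    "kernel_state",
    "density_at",
    "axis_interval_mass",
    "reflected_z_interval_mass",
]


@dataclass(frozen=True)
class MovementVariances:
    """Diffusion coefficients: horizontal eta^2 and vertical gamma^2 (m^2/min)."""

    eta2: float
    gamma2: float

    def __post_init__(self) -> None:
        if self.eta2 < 0 or self.gamma2 < 0:
            raise ValueError(
                f"diffusion coefficients must be >= 0, got "
                f"eta2={self.eta2}, gamma2={self.gamma2}"
            )


@dataclass(frozen=True)
class KernelState:
    """Kernel mean and variances at one time inside a move step."""

    alpha: float
    mu: tuple[float, float, float]
    var_xy: float
    var_z: float


def kernel_state(
    step: MoveStep, t: float, mv: MovementVariances, err: ErrorModel
) -> KernelState:
    """Evaluate the bridge kernel parameters at time ``t`` within ``step``."""
    t0, t1 = step.start.t, step.end.t
    if not (t0 <= t <= t1):
        raise ValueError(f"t={t} outside step interval [{t0}, {t1}]")
    dt = step.dt
    alpha = (t - t0) / dt
    w0, w1 = 1.0 - alpha, alpha
    mu = (
        w0 * step.start.x + w1 * step.end.x,
        w0 * step.start.y + w1 * step.end.y,
        w0 * step.start.z + w1 * step.end.z,
    )
    endpoint_w = w0 * w0 + w1 * w1
    var_xy = dt * alpha * (1.0 - alpha) * mv.eta2 + endpoint_w * err.var_xy
    var_z = dt * alpha * (1.0 - alpha) * mv.gamma2 + endpoint_w * err.var_z
    return KernelState(alpha=alpha, mu=mu, var_xy=var_xy, var_z=var_z)


def density_at(state: KernelState, point: tuple[float, float, float]) -> float:
    """Trivariate kernel density (m^-3) at ``point``: product of univariates."""
    out = 1.0
    for value, mean, var in zip(
        point, state.mu, (state.var_xy, state.var_xy, state.var_z)
    ):
        out *= math.exp(-0.5 * (value - mean) ** 2 / var) / math.sqrt(
            2.0 * math.pi * var
        )
    return out


def axis_interval_mass(mean, var, lo, hi):
    """Gaussian probability mass on [lo, hi) along one axis.

    ``lo``/``hi`` may be arrays (broadcast); ``var`` must be > 0.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo >= hi):
        raise ValueError("interval requires lo < hi")
    if not var > 0:
        raise ValueError(f"variance must be > 0, got {var}")
    sd = math.sqrt(var)
    out = ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)
    return out if out.ndim else float(out)


def reflected_z_interval_mass(mean, var, lo, hi, a=-np.inf, b=np.inf):
    """Boundary-corrected Gaussian mass on [lo, hi) within z-domain [a, b].

    Adds to the direct mass the mirror images about the lower bound ``a``
    (z -> 2a - z) and the upper bound ``b`` (z -> 2b - z), one reflection per
    side. An infinite bound contributes nothing. Requires a <= lo < hi <= b.
    """
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(lo >= hi):
        raise ValueError("interval requires lo < hi")
    if np.any(lo < a) or np.any(hi > b):
        raise ValueError("interval must lie within the bounded domain [a, b]")
    if not var > 0:
        raise ValueError(f"variance must be > 0, got {var}")
    sd = math.sqrt(var)
    mass = ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd)
    if np.isfinite(a):
        mass = mass + (ndtr((2.0 * a - lo - mean) / sd) - ndtr((2.0 * a - hi - mean) / sd))
    if np.isfinite(b):
        mass = mass + (ndtr((2.0 * b - lo - mean) / sd) - ndtr((2.0 * b - hi - mean) / sd))
    return mass if mass.ndim else float(mass)
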