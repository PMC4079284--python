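"""Likelihood estimation of the diffusion coefficients eta^2 and gamma^2.

The estimator uses alternating observed locations: within each maximal run of
consecutive usable move steps, every odd-position fix is treated as held out.
Under the Brownian-bridge model, a held-out middle fix given its flanking
fixes is Gaussian around the chord point with predictive variance

    T * alpha * (1 - alpha) * sigma2_move
      + ((1 - alpha)^2 + alpha^2) * var_obs   (endpoint error propagated)
      + var_obs                               (the middle fix's own error)

with T the flanking time span and alpha the middle fix's time fraction along
it. The diffusion coefficient is then fit by bounded scalar minimization of
the negative log-likelihood on a log-transformed parameter, separately for
the horizontal (x and y share one eta^2) and vertical dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .kernel import MovementVariances
from .telemetry import ErrorModel, MoveStep, Observation, Track

__all__ = [
    "Triple",
    "DiffusionFit",
    "alternating_triples",
    "neg_log_likelihood",
    "fit_diffusion",
    "estimate_variances",
]

_LOG_EPS = 1e-9


@dataclass(frozen=True)
class Triple:
    """A held-out middle observation with its flanking neighbors."""

    left: Observation
    middle: Observation
    right: Observation


@dataclass(frozen=True)
class DiffusionFit:
    """Result of a one-dimensional diffusion-coefficient fit."""

    dimension: str
    estimate: float  # m^2/min
    nll: float
    n_triples: int


def alternating_triples(
    track: Track, steps: Sequence[MoveStep]
) -> list[Triple]:
    """Leave-out triples from maximal runs of consecutive usable steps.

    A run of L consecutive usable steps spans L+1 fixes; fixes at odd
    positions 1, 3, ... within the run become middles, flanked by their
    immediate neighbors. Runs shorter than 2 steps contribute nothing, and
    triples never span a rejected step.
    """
    obs = track.observations
    triples: list[Triple] = []
    run_start: int | None = None  # first step index of the current run
    indexed = sorted(steps, key=lambda s: s.index)

    def flush(first_step: int, last_step: int) -> None:
        n_fix = last_step - first_step + 2  # fixes covered by the run
        for p in range(1, n_fix - 1, 2):
            i = first_step + p
            triples.append(Triple(obs[i - 1], obs[i], obs[i + 1]))

    prev = None
    for s in indexed:
        if s.usable:
            if run_start is None:
                run_start = s.index
            elif prev is not None and s.index != prev + 1:
                flush(run_start, prev)
                run_start = s.index
            prev = s.index
        else:
            if run_start is not None:
                flush(run_start, prev)
                run_start = None
    if run_start is not None:
        flush(run_start, prev)
    return triples


def _triple_arrays(triples: Sequence[Triple]):
    t_l = np.array([tr.left.t for tr in triples])
    t_m = np.array([tr.middle.t for tr in triples])
    t_r = np.array([tr.right.t for tr in triples])
    T = t_r - t_l
    alpha = (t_m - t_l) / T
    return T, alpha


def neg_log_likelihood(
    sigma2_move: float,
    triples: Sequence[Triple],
    err: ErrorModel,
    dim: Literal["horizontal", "vertical"],
) -> float:
    """Negative log-likelihood of the middle fixes given sigma2_move."""
    if not triples:
        raise ValueError("no triples available for likelihood evaluation")
    if sigma2_move < 0:
        raise ValueError(f"sigma2_move must be >= 0, got {sigma2_move}")
    T, alpha = _triple_arrays(triples)
    var_obs = err.var_xy if dim == "horizontal" else err.var_z
    pred_var = (
        T * alpha * (1.0 - alpha) * sigma2_move
        + ((1.0 - alpha) ** 2 + alpha**2) * var_obs
        + var_obs
    )

    def axis_nll(getter) -> float:
        left = np.array([getter(tr.left) for tr in triples])
        mid = np.array([getter(tr.middle) for tr in triples])
        right = np.array([getter(tr.right) for tr in triples])
        mu = (1.0 - alpha) * left + alpha * right
        resid = mid - mu
        return float(
            np.sum(0.5 * np.log(2.0 * np.pi * pred_var) + 0.5 * resid**2 / pred_var)
        )

    if dim == "horizontal":
        return axis_nll(lambda o: o.x) + axis_nll(lambda o: o.y)
    return axis_nll(lambda o: o.z)


def fit_diffusion(
    triples: Sequence[Triple],
    err: ErrorModel,
    dim: Literal["horizontal", "vertical"],
    bounds: tuple[float, float] = (1e-9, 1e9),
    tol: float = 1e-8,
) -> DiffusionFit:
    """Bounded 1D minimization of the NLL on log(sigma2_move + eps)."""
    if not triples:
        raise ValueError("no triples available: cannot fit diffusion coefficient")
    lo, hi = bounds
    if lo < 0:
        raise ValueError("lower bound must be >= 0")

    def objective(theta: float) -> float:
        return neg_log_likelihood(math.exp(theta) - _LOG_EPS, triples, err, dim)

    res = minimize_scalar(
        objective,
        bounds=(math.log(lo + _LOG_EPS), math.log(hi + _LOG_EPS)),
        method="bounded",
        options={"xatol": tol},
    )
    if not res.success:
        raise RuntimeError(
            f"diffusion fit did not converge for {dim}: {res.message} "
            f"(n_triples={len(triples)})"
        )
    estimate = max(math.exp(res.x) - _LOG_EPS, 0.0)
    return DiffusionFit(
        dimension=dim, estimate=estimate, nll=float(res.fun), n_triples=len(triples)
    )


def estimate_variances(
    track: Track,
    steps: Sequence[MoveStep],
    err: ErrorModel | None = None,
    bounds: tuple[float, float] = (1e-9, 1e9),
) -> MovementVariances:
    """Estimate eta^2 (horizontal) and gamma^2 (vertical) from a track.

    Uses the alternating-locations likelihood; x and y share one horizontal
    coefficient. Raises if the classified steps yield no triples.
    """
    if err is None:
        err = track.error
    triples = alternating_triples(track, steps)
    fit_h = fit_diffusion(triples, err, "horizontal", bounds=bounds)
    fit_v = fit_diffusion(triples, err, "vertical", bounds=bounds)
    return MovementVariances(eta2=fit_h.estimate, gamma2=fit_v.estimate)
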