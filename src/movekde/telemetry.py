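"""Telemetry data model and move-step screening.

A track is an ordered sequence of biologger fixes (x, y, z, t) in a projected
metric coordinate system, with time expressed in minutes from the first fix.
Observed locations are modelled as the true location plus independent Gaussian
observation error with user-supplied per-axis variances.

The unit of all downstream kernel computation is the *move step*: a pair of
consecutive fixes. A step enters the estimator only if

1. its duration does not exceed ``t_max`` (consistency with the fix schedule),
2. the displacement in at least one spatial dimension is improbably large
   under the observation-error-only null (i.e. the animal actually moved), and
3. for 3D analyses, both endpoint z-coordinates lie inside the admissible
   vertical range ``[a(x, y), b(x, y)]``.

Under the no-movement null each coordinate difference is the difference of two
independent error draws, hence Normal(0, 2·var_dim). A step counts as a
movement when Phi(|d| / sqrt(2·var_dim)) exceeds the movement quantile
(default 0.975) in any dimension.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "Observation",
    "ErrorModel",
    "Track",
    "FilterConfig",
    "RejectionReason",
    "MoveStep",
    "build_track",
    "classify_move_steps",
    "total_used_duration",
]


@dataclass(frozen=True)
class Observation:
    """A single biologger fix: coordinates in meters, time in minutes."""

    x: float
    y: float
    z: float
    t: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z", "t"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"observation {name!r} must be finite, got {v}")

    @property
    def location(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class ErrorModel:
    """Per-axis observation-error variances (m^2).

    ``var_xy`` applies to each horizontal axis independently; ``var_z`` to the
    vertical axis. Both must be strictly positive.
    """

    var_xy: float
    var_z: float

    def __post_init__(self) -> None:
        if not (self.var_xy > 0 and math.isfinite(self.var_xy)):
            raise ValueError(f"var_xy must be > 0, got {self.var_xy}")
        if not (self.var_z > 0 and math.isfinite(self.var_z)):
            raise ValueError(f"var_z must be > 0, got {self.var_z}")


@dataclass(frozen=True)
class Track:
    """Time-ordered fixes for one animal plus its observation-error model."""

    animal_id: str
    observations: tuple[Observation, ...]
    error: ErrorModel

    def __post_init__(self) -> None:
        if len(self.observations) < 2:
            raise ValueError(
                f"track {self.animal_id!r} needs >= 2 observations, "
                f"got {len(self.observations)}"
            )
        times = np.array([o.t for o in self.observations])
        if not np.all(np.diff(times) > 0):
            bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 1
            raise ValueError(
                f"track {self.animal_id!r}: times not strictly increasing at "
                f"observation index {bad} (t={times[bad]})"
            )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def times(self) -> np.ndarray:
        return np.array([o.t for o in self.observations])

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of x, y, z."""
        return np.array([[o.x, o.y, o.z] for o in self.observations])


@dataclass(frozen=True)
class FilterConfig:
    """Screening parameters for move-step usability.

    t_max: maximum step duration in minutes.
    movement_quantile: one-sided normal CDF threshold for the movement test.
    z_bounds_check: require endpoint z within [a, b] (3D analyses).
    z_slack: if True, tolerate bound violations up to one observation-error
        SD in z before rejecting; default strict.
    """

    t_max: float
    movement_quantile: float = 0.975
    z_bounds_check: bool = False
    z_slack: bool = False

    def __post_init__(self) -> None:
        if not self.t_max > 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if not 0.5 < self.movement_quantile < 1.0:
            raise ValueError(
                f"movement_quantile must be in (0.5, 1), got {self.movement_quantile}"
            )


class RejectionReason(enum.Enum):
    NONE = "none"
    TOO_LONG = "too_long"
    NO_MOVEMENT = "no_movement"
    Z_OUT_OF_RANGE = "z_out_of_range"


class ZBounds(Protocol):
    """Vertical-range provider: lower/upper admissible z at a planar point."""

    def lower_at(self, x: float, y: float) -> float: ...

    def upper_at(self, x: float, y: float) -> float: ...


@dataclass(frozen=True)
class MoveStep:
    """A consecutive fix pair with its usability classification."""

    index: int
    start: Observation
    end: Observation
    usable: bool
    rejection_reason: RejectionReason = RejectionReason.NONE

    def __post_init__(self) -> None:
        if self.end.t <= self.start.t:
            raise ValueError(f"step {self.index}: non-positive duration")
        if self.usable != (self.rejection_reason is RejectionReason.NONE):
            raise ValueError("usable flag inconsistent with rejection reason")

    @property
    def dt(self) -> float:
        """Step duration Delta t in minutes."""
        return self.end.t - self.start.t


def build_track(
    rows: Sequence[tuple[str, float, float, float, float]],
    error: ErrorModel,
) -> Track:
    """Assemble a :class:`Track` from (id, t, x, y, z) rows.

    Rows may arrive in any order; they are sorted by time. All rows must share
    one animal id, and duplicate timestamps are rejected.
    """
    if not rows:
        raise ValueError("no rows supplied")
    ids = {r[0] for r in rows}
    if len(ids) != 1:
        raise ValueError(f"rows span multiple animal ids: {sorted(ids)}")
    animal_id = rows[0][0]
    ordered = sorted(rows, key=lambda r: float(r[1]))
    times = [float(r[1]) for r in ordered]
    for k in range(1, len(times)):
        if times[k] == times[k - 1]:
            raise ValueError(
                f"duplicate timestamp t={times[k]} for animal {animal_id!r}"
            )
    obs = tuple(
        Observation(x=float(r[2]), y=float(r[3]), z=float(r[4]), t=float(r[1]))
        for r in ordered
    )
    return Track(animal_id=animal_id, observations=obs, error=error)


def _is_movement(
    start: Observation, end: Observation, err: ErrorModel, q: float
) -> bool:
    # Null: coordinate difference ~ Normal(0, 2 var_dim); one-sided test on |d|.
    dx, dy, dz = end.x - start.x, end.y - start.y, end.z - start.z
    p_x = ndtr(abs(dx) / math.sqrt(2.0 * err.var_xy))
    p_y = ndtr(abs(dy) / math.sqrt(2.0 * err.var_xy))
    p_z = ndtr(abs(dz) / math.sqrt(2.0 * err.var_z))
    return bool(p_x > q or p_y > q or p_z > q)


def _z_in_range(obs: Observation, bounds: ZBounds, slack: float) -> bool:
    lo = bounds.lower_at(obs.x, obs.y)
    hi = bounds.upper_at(obs.x, obs.y)
    return (obs.z >= lo - slack) and (obs.z <= hi + slack)


def classify_move_steps(
    track: Track,
    cfg: FilterConfig,
    bounds: Optional[ZBounds] = None,
) -> list[MoveStep]:
    """Classify every consecutive fix pair of ``track`` as usable or not.

    Order of screens per step: duration, movement test, then (if
    ``cfg.z_bounds_check``) the endpoint z-range check. The classification is
    deterministic given the track and configuration.
    """
    if cfg.z_bounds_check and bounds is None:
        raise ValueError("z_bounds_check requires a bounds surface")
    slack = math.sqrt(track.error.var_z) if cfg.z_slack else 0.0
    steps: list[MoveStep] = []
    obs = track.observations
    for m in range(len(obs) - 1):
        start, end = obs[m], obs[m + 1]
        reason = RejectionReason.NONE
        if end.t - start.t > cfg.t_max:
            reason = RejectionReason.TOO_LONG
        elif not _is_movement(start, end, track.error, cfg.movement_quantile):
            reason = RejectionReason.NO_MOVEMENT
        elif cfg.z_bounds_check and not (
            _z_in_range(start, bounds, slack) and _z_in_range(end, bounds, slack)
        ):
            reason = RejectionReason.Z_OUT_OF_RANGE
        steps.append(
            MoveStep(
                index=m,
                start=start,
                end=end,
                usable=reason is RejectionReason.NONE,
                rejection_reason=reason,
            )
        )
    return steps


def total_used_duration(steps: Sequence[MoveStep]) -> float:
    """Total time T = sum of durations over usable steps, in minutes."""
    T = sum(s.dt for s in steps if s.usable)
    if T <= 0:
        raise ValueError("no usable move steps")
    return T
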