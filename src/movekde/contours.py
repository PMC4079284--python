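"""Minimum-volume/area contours and probability summaries of a UD.

A p-contour is the smallest set of voxels (cells) whose probabilities sum to
at least p: sort all probabilities ascending, take the largest prefix whose
cumulative sum does not exceed 1 - p, and exclude it; the threshold is the
first retained value and every voxel with probability >= threshold is a
member. Ties at the threshold are all included. Achieved mass can exceed p by
at most the excluded prefix's quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import UDGrid

__all__ = [
    "ContourResult",
    "contour_threshold",
    "contour",
    "contour_volume",
    "depth_bin_probabilities",
    "detection_zone_probability",
]


@dataclass(frozen=True)
class ContourResult:
    p: float
    threshold: float
    members: np.ndarray  # boolean mask, shape of the probability field
    achieved_mass: float
    measure: float  # m^3 for 3D, m^2 for 2D


def contour_threshold(values: np.ndarray, p: float) -> float:
    """Probability cutoff of the minimum-volume p-contour.

    ``values`` is any-shape nonnegative probability field summing to <= 1+eps.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError(f"p must be in (0, 1], got {p}")
    flat = np.asarray(values, dtype=float).ravel()
    if np.any(flat < 0):
        raise ValueError("probability field has negative entries")
    total = float(flat.sum())
    if total <= 0:
        raise ValueError("probability field is identically zero")
    order = np.sort(flat)
    csum = np.cumsum(order)
    # largest prefix we may exclude while keeping mass >= p of the total
    # (scale-equivariant: fields not summing to exactly 1, e.g. interaction
    # local values, are handled relative to their own total)
    target = (1.0 - p) * total
    n_excl = int(np.searchsorted(csum, target * (1.0 + 1e-12) + 1e-300, side="right"))
    if n_excl >= order.size:
        n_excl = order.size - 1
    thr = order[n_excl]
    if thr <= 0.0:
        pos = order[order > 0]
        if pos.size == 0:
            raise ValueError("probability field is identically zero")
        thr = pos[0]
    return float(thr)


def contour(ud: UDGrid, p: float) -> ContourResult:
    """Minimum-volume (3D) or minimum-area (2D) p-contour of a UD."""
    thr = contour_threshold(ud.probs, p)
    members = ud.probs >= thr
    unit = ud.spec.voxel_volume if ud.ndim == 3 else ud.spec.cell_area
    return ContourResult(
        p=p,
        threshold=thr,
        members=members,
        achieved_mass=float(ud.probs[members].sum()),
        measure=float(members.sum()) * unit,
    )


def contour_volume(ud: UDGrid, p: float) -> float:
    """Volume (m^3, 3D) or area (m^2, 2D) of the p-contour."""
    return contour(ud, p).measure


def depth_bin_probabilities(
    ud: UDGrid,
    bin_edges: np.ndarray,
    reference: float | None = None,
) -> pd.DataFrame:
    """Probability mass per depth bin below a reference surface level.

    Each voxel is assigned to the half-open bin [lo, hi) containing the depth
    of its center, depth = reference - z_center. ``reference`` defaults to
    the UD's snapped upper bound when that is a single constant. Raises if
    the bins leave any probability mass uncovered.
    """
    if ud.ndim != 3:
        raise ValueError("depth bins require a 3D UD")
    if reference is None:
        if ud.bounds is None:
            raise ValueError("no reference level: UD has no upper bound")
        hi = np.unique(ud.bounds.z_hi[np.isfinite(ud.bounds.z_hi)])
        if hi.size != 1:
            raise ValueError(
                "reference level ambiguous: upper bound is not constant"
            )
        reference = float(hi[0])
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be a 1D increasing array")
    depth = reference - ud.spec.z_centers  # per level k
    level_mass = ud.probs.sum(axis=(0, 1))
    idx = np.searchsorted(edges, depth, side="right") - 1
    covered = (idx >= 0) & (idx < edges.size - 1) & (depth >= edges[0])
    uncovered_mass = float(level_mass[~covered].sum())
    if uncovered_mass > 1e-9:
        raise ValueError(
            f"depth bins do not cover the UD z-range: {uncovered_mass:.3e} "
            "probability mass falls outside the bins"
        )
    probs = np.zeros(edges.size - 1)
    for k in range(level_mass.size):
        if covered[k]:
            probs[idx[k]] += level_mass[k]
    return pd.DataFrame(
        {"depth_lo": edges[:-1], "depth_hi": edges[1:], "probability": probs}
    )


def detection_zone_probability(
    ud: UDGrid, cutoff_depth: float, reference: float | None = None
) -> float:
    """Cumulative probability within ``cutoff_depth`` of the reference surface."""
    if ud.ndim != 3:
        raise ValueError("detection zone requires a 3D UD")
    if reference is None:
        if ud.bounds is None:
            raise ValueError("no reference level: UD has no upper bound")
        hi = np.unique(ud.bounds.z_hi[np.isfinite(ud.bounds.z_hi)])
        if hi.size != 1:
            raise ValueError("reference level ambiguous: upper bound not constant")
        reference = float(hi[0])
    depth = reference - ud.spec.z_centers
    level_mass = ud.probs.sum(axis=(0, 1))
    return float(level_mass[(depth >= 0) & (depth <= cutoff_depth)].sum())
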