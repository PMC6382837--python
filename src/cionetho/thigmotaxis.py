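"""Equal-area concentric zoning of the circular arena and wall-affinity metrics.

Thigmotaxis (wall hugging) is quantified by splitting the arena into an
inner disc and an outer annulus of equal area — for radius R the inner
radius is R/sqrt(2), so a 5 mm arena has a 3.54 mm inner zone and a
1.46 mm wide outer zone — and measuring the fraction of time (TTO) and of
travelled distance (TDO) spent in the outer zone, plus the median distance
from the arena centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .track_io import Trajectory

__all__ = ["ZoneSpec", "ThigmoMetrics", "equal_area_zones", "thigmo_metrics"]


@dataclass(frozen=True)
class ZoneSpec:
    """Concentric two-zone split of a circular arena (radii in mm)."""

    arena_radius: float
    inner_radius: float
    outer_width: float

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.arena_radius:
            raise ValueError("need 0 < inner_radius < arena_radius")
        if not np.isclose(
            self.outer_width, self.arena_radius - self.inner_radius, atol=1e-12
        ):
            raise ValueError("outer_width must equal arena_radius - inner_radius")

    @property
    def area_imbalance(self) -> float:
        """|inner area - outer area| relative to the arena area."""
        R, ri = self.arena_radius, self.inner_radius
        return abs(ri**2 - (R**2 - ri**2)) / R**2


@dataclass(frozen=True)
class ThigmoMetrics:
    """Wall-affinity metrics of one animal."""

    TTO: float          # fraction of valid time in the outer zone
    TDO: float          # fraction of path length in the outer zone
    median_dist: float  # median distance from the arena centre, mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.TTO <= 1.0 and 0.0 <= self.TDO <= 1.0):
            raise ValueError("TTO and TDO must lie in [0, 1]")


def equal_area_zones(R: float) -> ZoneSpec:
    """Equal-area zoning of a circular arena of radius ``R`` mm.

    ``inner_radius = R / sqrt(2)`` makes the inner disc and the outer
    annulus equal in area; for the default 5 mm arena this gives a
    3.54 mm inner radius and a 1.46 mm wide thigmotaxis zone.
    """
    if R <= 0:
        raise ValueError("arena radius must be positive")
    ri = R / np.sqrt(2.0)
    return ZoneSpec(arena_radius=R, inner_radius=ri, outer_width=R - ri)


def thigmo_metrics(
    traj: Trajectory, zones: ZoneSpec, inner_closed: bool = True
) -> ThigmoMetrics:
    """TTO, TDO and median centre distance for one calibrated trajectory.

    A frame is in the outer zone when its centre distance exceeds the inner
    radius (the boundary itself counts as inner by default; set
    ``inner_closed=False`` to flip). TDO assigns each step between
    consecutive valid frames to the zone of its midpoint; a trajectory
    with zero total path length reports TDO = 0 with a warning.
    """
    valid = (~traj.gap_mask) & np.isfinite(traj.x) & np.isfinite(traj.y)
    if not valid.any():
        raise ValueError("no valid frames")
    r = np.hypot(traj.x[valid], traj.y[valid])
    outer = r > zones.inner_radius if inner_closed else r >= zones.inner_radius
    tto = float(outer.sum() / outer.size)
    median_dist = float(np.median(r))

    # steps between consecutive valid frames only
    vi = np.flatnonzero(valid)
    pair = np.diff(vi) == 1
    i0 = vi[:-1][pair]
    step_len = np.hypot(traj.x[i0 + 1] - traj.x[i0], traj.y[i0 + 1] - traj.y[i0])
    mid_r = np.hypot(
        0.5 * (traj.x[i0] + traj.x[i0 + 1]), 0.5 * (traj.y[i0] + traj.y[i0 + 1])
    )
    total = step_len.sum()
    if total <= 0:
        warnings.warn("zero total path length; TDO set to 0")
        tdo = 0.0
    else:
        mid_outer = (
            mid_r > zones.inner_radius if inner_closed else mid_r >= zones.inner_radius
        )
        tdo = float(step_len[mid_outer].sum() / total)
    return ThigmoMetrics(TTO=tto, TDO=tdo, median_dist=median_dist)
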