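"""Dispersal distance from two dated populations and a geographic distance.

Two populations at different distances from the contact zone carry donor
tracts of different mean age; the difference of their dates is the diffusion
time — the generations a migrant tract needs to travel between the two sites.
Dividing the (least-cost) geographic distance by the diffusion time yields a
per-generation dispersal distance.  Confidence intervals propagate by interval
arithmetic on the component CIs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PointCI:
    """A point estimate with a 95% interval (bounds may be NaN when unknown)."""

    value: float
    lo: float = float("nan")
    hi: float = float("nan")

    def __post_init__(self) -> None:
        if (
            math.isfinite(self.lo)
            and math.isfinite(self.hi)
            and self.lo > self.hi
        ):
            raise ValueError(f"CI bounds out of order: [{self.lo}, {self.hi}]")

    @property
    def has_ci(self) -> bool:
        return math.isfinite(self.lo) and math.isfinite(self.hi)


def mean_distance(distances_km) -> float:
    """Arithmetic mean of between-site distances (km), all > 0 required."""
    distances = list(distances_km)
    if not distances:
        raise ValueError("no distances supplied")
    if any(d <= 0 for d in distances):
        raise ValueError("distances must be > 0")
    return sum(distances) / len(distances)


def diffusion_time(t_near: PointCI, t_far: PointCI) -> PointCI:
    """Difference of the far and near population dates, with interval CI.

    CI = [far.lo - near.hi, far.hi - near.lo].  A non-positive point
    difference (far population dating younger than near) is allowed but
    logged: such an estimate cannot feed a dispersal distance.
    """
    if not (math.isfinite(t_near.value) and math.isfinite(t_far.value)):
        raise ValueError("population dates must be finite")
    point = t_far.value - t_near.value
    if point <= 0:
        logger.warning(
            "diffusion time %.2f <= 0 (far population dates younger than near); "
            "unusable for dispersal",
            point,
        )
    if t_near.has_ci and t_far.has_ci:
        return PointCI(point, t_far.lo - t_near.hi, t_far.hi - t_near.lo)
    return PointCI(point)


def dispersal_distance(distance_km: float, t_diff: PointCI) -> PointCI:
    """Per-generation dispersal distance: distance / diffusion time (km/gen).

    CI = [distance/t_diff.hi, distance/t_diff.lo]; a diffusion-time CI whose
    lower bound is non-positive gives an unbounded upper dispersal bound.
    """
    if distance_km < 0:
        raise ValueError("distance must be >= 0")
    if not math.isfinite(t_diff.value) or t_diff.value <= 0:
        raise ValueError(f"diffusion time must be > 0, got {t_diff.value}")
    point = distance_km / t_diff.value
    if t_diff.has_ci:
        hi = math.inf if t_diff.lo <= 0 else distance_km / t_diff.lo
        if t_diff.lo <= 0:
            logger.warning(
                "diffusion-time CI crosses zero; dispersal upper bound unbounded"
            )
        return PointCI(point, distance_km / t_diff.hi, hi)
    return PointCI(point)


@dataclass(frozen=True)
class DispersalEstimate:
    """Full dispersal report for one pair of dated populations."""

    t_near: PointCI
    t_far: PointCI
    t_diff: PointCI
    distance_km: float
    dispersal_km_per_gen: PointCI
    usable: bool


def estimate_dispersal(
    t_near: PointCI, t_far: PointCI, distances_km
) -> DispersalEstimate:
    """Compose diffusion time and dispersal distance for a site pair.

    ``distances_km`` may hold several route distances (they are averaged,
    matching pooled samples from several far-side sites).  When the diffusion
    time is non-positive the estimate is flagged unusable and the dispersal
    distance is NaN.
    """
    distance = mean_distance(distances_km)
    t_diff = diffusion_time(t_near, t_far)
    if t_diff.value > 0:
        speed = dispersal_distance(distance, t_diff)
        usable = True
    else:
        speed = PointCI(float("nan"))
        usable = False
    return DispersalEstimate(
        t_near=t_near,
        t_far=t_far,
        t_diff=t_diff,
        distance_km=distance,
        dispersal_km_per_gen=speed,
        usable=usable,
    )
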