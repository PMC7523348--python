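"""Stay-point extraction from raw GPS trajectories.

A *stay point* is a maximal run of consecutive trajectory fixes that remain
within ``dist_thresh`` meters of the run's first fix (the anchor) for at
least ``time_thresh`` seconds.  Each stay is summarized by the unweighted
centroid of its member fixes and classified as a single-point location (SPL:
one effective spot, long dwell) or multi-point location (MPL: several nearby
sub-spots merged within one stay region) by the spatial span of its members.

Coordinates are projected from WGS84 degrees to local planar meters with a
local equirectangular projection around a reference origin -- adequate at
city scale, where the monitoring rectangles (hundreds of meters to a few
kilometers) live.  Altitude, where present in the source data, is discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import WeightedPoint

__all__ = [
    "EARTH_RADIUS_M",
    "TrajectoryPoint",
    "Trajectory",
    "StayPoint",
    "project_to_plane",
    "unproject_from_plane",
    "extract_stay_points",
    "classify_stay",
    "stays_to_pois",
    "DEFAULT_DIST_THRESH_M",
    "DEFAULT_TIME_THRESH_S",
    "DEFAULT_SPAN_THRESH_M",
]

EARTH_RADIUS_M = 6_371_000.0

#: default stay-detection thresholds (configurable everywhere they are used)
DEFAULT_DIST_THRESH_M = 200.0
DEFAULT_TIME_THRESH_S = 20.0 * 60.0
DEFAULT_SPAN_THRESH_M = 50.0


@dataclass(frozen=True)
class TrajectoryPoint:
    """One GPS fix: WGS84 degrees plus a POSIX timestamp in seconds."""

    latitude: float
    longitude: float
    timestamp: float

    def __post_init__(self) -> None:
        if not abs(self.latitude) <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not abs(self.longitude) <= 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if not math.isfinite(self.timestamp):
            raise ValueError("non-finite timestamp")


@dataclass(frozen=True)
class Trajectory:
    """A single user's time-ordered GPS track."""

    user_id: str
    points: Tuple[TrajectoryPoint, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        ts = [p.timestamp for p in self.points]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(f"trajectory {self.user_id!r}: timestamps decrease")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class StayPoint:
    """A detected stay: centroid, dwell interval, kind, and member extent."""

    centroid_x: float
    centroid_y: float
    t_arrive: float
    t_depart: float
    kind: str  # "SPL" | "MPL"
    member_index_range: Tuple[int, int]  # half-open [i, j) into the trajectory
    span: float  # diagonal of the members' bounding box, meters

    @property
    def duration(self) -> float:
        return self.t_depart - self.t_arrive


def project_to_plane(latitude, longitude, ref_lat: float, ref_lon: float):
    """Local equirectangular projection to planar meters around a reference.

    ``x = R * dlon * cos(ref_lat)``, ``y = R * dlat`` with angles in radians.
    Accepts scalars or arrays.
    """
    lat = np.radians(np.asarray(latitude, dtype=np.float64))
    lon = np.radians(np.asarray(longitude, dtype=np.float64))
    rlat = math.radians(ref_lat)
    rlon = math.radians(ref_lon)
    x = EARTH_RADIUS_M * (lon - rlon) * math.cos(rlat)
    y = EARTH_RADIUS_M * (lat - rlat)
    if np.ndim(latitude) == 0:
        return float(x), float(y)
    return x, y


def unproject_from_plane(x, y, ref_lat: float, ref_lon: float):
    """Inverse of :func:`project_to_plane` (exact near the origin)."""
    xs = np.asarray(x, dtype=np.float64)
    ys = np.asarray(y, dtype=np.float64)
    rlat = math.radians(ref_lat)
    lat = np.degrees(rlat + ys / EARTH_RADIUS_M)
    lon = np.degrees(math.radians(ref_lon) + xs / (EARTH_RADIUS_M * math.cos(rlat)))
    if np.ndim(x) == 0:
        return float(lat), float(lon)
    return lat, lon


def classify_stay(
    stay: StayPoint,
    span_thresh: float = DEFAULT_SPAN_THRESH_M,
    revisit_gap: Optional[float] = None,
) -> str:
    """Classify a stay as ``"SPL"`` or ``"MPL"`` by its member span.

    A stay whose member fixes span at most ``span_thresh`` meters is one
    effective location (SPL); a wider stay merges several nearby sub-spots
    (MPL).  ``revisit_gap`` is accepted for interface stability but the span
    rule is the classification criterion.
    """
    del revisit_gap
    return "SPL" if stay.span <= span_thresh else "MPL"


def extract_stay_points(
    traj: Trajectory,
    dist_thresh: float = DEFAULT_DIST_THRESH_M,
    time_thresh: float = DEFAULT_TIME_THRESH_S,
    span_thresh: float = DEFAULT_SPAN_THRESH_M,
    ref: Optional[Tuple[float, float]] = None,
) -> List[StayPoint]:
    """Scan a trajectory for stays using the anchor-point run rule.

    A run grows from an anchor fix while every subsequent fix stays within
    ``dist_thresh`` meters of the anchor; a run spanning at least
    ``time_thresh`` seconds becomes one stay (centroid = unweighted mean of
    the run's planar coordinates).  Runs that become stays are disjoint and
    emitted in temporal order.

    ``ref`` fixes the projection origin (defaults to the first fix).
    """
    if len(traj) == 0:
        return []
    if dist_thresh <= 0 or time_thresh <= 0:
        raise ValueError("thresholds must be positive")
    ts = np.asarray([p.timestamp for p in traj.points])
    if np.any(np.diff(ts) < 0):
        raise ValueError("non-monotone timestamps")
    if ref is None:
        ref = (traj.points[0].latitude, traj.points[0].longitude)
    lats = np.asarray([p.latitude for p in traj.points])
    lons = np.asarray([p.longitude for p in traj.points])
    xs, ys = project_to_plane(lats, lons, ref[0], ref[1])

    stays: List[StayPoint] = []
    n = len(traj)
    i = 0
    while i < n:
        # grow the run anchored at fix i
        j = i + 1
        while j < n and math.hypot(xs[j] - xs[i], ys[j] - ys[i]) <= dist_thresh:
            j += 1
        if ts[j - 1] - ts[i] >= time_thresh:
            mx, my = xs[i:j], ys[i:j]
            span = math.hypot(mx.max() - mx.min(), my.max() - my.min())
            stay = StayPoint(
                centroid_x=float(mx.mean()),
                centroid_y=float(my.mean()),
                t_arrive=float(ts[i]),
                t_depart=float(ts[j - 1]),
                kind="SPL" if span <= span_thresh else "MPL",
                member_index_range=(i, j),
                span=span,
            )
            stays.append(stay)
            i = j
        else:
            i += 1
    return stays


def stays_to_pois(
    stays: Sequence[StayPoint],
    weighting: str = "duration_minutes",
    expire_after: float = math.inf,
) -> List[WeightedPoint]:
    """Turn stays into weighted POIs for the MaxRS machinery.

    ``weighting="unit"`` gives every stay weight 1; ``"duration_minutes"``
    weighs a stay by its dwell time in minutes (longer dwells matter more).
    ``expire_after`` extends each POI's lifetime past its departure by the
    monitoring window (infinite by default, i.e. POIs never expire).
    """
    if weighting not in ("unit", "duration_minutes"):
        raise ValueError(f"unknown weighting mode: {weighting!r}")
    pois = []
    for k, s in enumerate(stays):
        w = 1.0 if weighting == "unit" else s.duration / 60.0
        pois.append(
            WeightedPoint(
                id=k,
                x=s.centroid_x,
                y=s.centroid_y,
                weight=w,
                t_arrive=s.t_arrive,
                t_expire=s.t_depart + expire_after
                if math.isfinite(expire_after)
                else math.inf,
            )
        )
    return pois
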