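"""Synthetic GeoLife-like trajectories and weighted POI streams.

Everything here emulates the study conditions of the monitoring problem so
the full pipeline is testable without any download:

* trajectories alternate dwells at hotspot locations (Gaussian GPS jitter,
  exponentially distributed dwell times) with constant-speed straight-line
  transits, sampled every 1-5 seconds like densely logged GeoLife tracks;
* point streams deliver a fixed number of weighted arrivals per tick with
  weights uniform in (0, 1000] and lifetimes equal to the monitoring
  window; coordinates are planar meters, or optionally normalized to
  [0, 1e8] like the study's preprocessed dataset;
* :func:`planted_optimum` injects a hotspot of exactly known total weight
  inside a known rectangle, giving ground truth for recovery experiments.

All randomness flows through one ``numpy`` generator seeded from
``SimConfig.seed``; the same seed reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import RectSpec, WeightedPoint
from .monitor import Tick
from .stays import Trajectory, TrajectoryPoint, unproject_from_plane

__all__ = ["SimConfig", "generate_trajectory", "generate_stream", "planted_optimum"]

#: default projection origin for emitted lat/lon (Beijing, the GeoLife home)
DEFAULT_ORIGIN = (39.9042, 116.4074)


@dataclass(frozen=True)
class SimConfig:
    """Generator knobs; defaults mirror the study conditions.

    ``hotspot_sd`` is the GPS jitter scale while dwelling (meters); 10 m is a
    typical consumer-GPS noise level and keeps dwells well inside the default
    200 m stay-detection radius.  ``arrival_rate`` is the stream generation
    rate m (points per tick); ``weight_range`` is half-open ``(lo, hi]``.
    """

    seed: int = 0
    n_hotspots: int = 8
    hotspot_centers: Optional[Tuple[Tuple[float, float], ...]] = None
    hotspot_sd: float = 10.0
    dwell_minutes: float = 30.0
    travel_speed: float = 1.4
    sample_interval: Tuple[float, float] = (1.0, 5.0)
    duration_hours: float = 2.0
    arrival_rate: int = 100
    weight_range: Tuple[float, float] = (0.0, 1000.0)
    coord_mode: str = "meters"  # "meters" | "normalized"
    background: str = "hotspots"  # "hotspots" | "uniform"
    domain_size: float = 5000.0
    tick_interval: float = 1.0
    window_ticks: int = 5
    origin: Tuple[float, float] = DEFAULT_ORIGIN

    def __post_init__(self) -> None:
        if self.n_hotspots < 1:
            raise ValueError("at least one hotspot required")
        lo, hi = self.sample_interval
        if not (0 < lo <= hi):
            raise ValueError("invalid sample_interval")
        if self.weight_range[0] < 0 or self.weight_range[1] <= self.weight_range[0]:
            raise ValueError("weight_range must be a positive half-open interval")
        if self.coord_mode not in ("meters", "normalized"):
            raise ValueError(f"unknown coord_mode {self.coord_mode!r}")
        if self.background not in ("hotspots", "uniform"):
            raise ValueError(f"unknown background mode {self.background!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def scale(self) -> float:
        """Coordinate scale factor: meters -> output units."""
        return 1e8 / self.domain_size if self.coord_mode == "normalized" else 1.0


def _hotspots(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.hotspot_centers is not None:
        hs = np.asarray(cfg.hotspot_centers, dtype=np.float64)
        if hs.shape != (cfg.n_hotspots, 2):
            raise ValueError("hotspot_centers must match n_hotspots")
        return hs
    return rng.uniform(0.0, cfg.domain_size, size=(cfg.n_hotspots, 2))


def generate_trajectory(cfg: SimConfig, return_segments: bool = False):
    """One user's GPS track alternating hotspot dwells and transits.

    Emits WGS84 fixes (projected back from planar meters around
    ``cfg.origin``) with strictly increasing timestamps sampled every
    ``sample_interval`` seconds.  With ``return_segments=True`` also returns
    the ground-truth segment list ``(kind, hotspot_index, t_start, t_end)``
    with kind ``"dwell"`` or ``"transit"`` for recovery experiments.
    """
    rng = cfg.rng()
    hotspots = _hotspots(cfg, rng)
    total = cfg.duration_hours * 3600.0
    t = 0.0
    here = int(rng.integers(cfg.n_hotspots))
    xs: List[float] = []
    ys: List[float] = []
    ts: List[float] = []

    def sample_dwell(center: np.ndarray, until: float) -> float:
        nonlocal t
        while t < until and t < total:
            jitter = rng.normal(0.0, cfg.hotspot_sd, size=2)
            xs.append(center[0] + jitter[0])
            ys.append(center[1] + jitter[1])
            ts.append(t)
            t += rng.uniform(*cfg.sample_interval)
        return t

    segments: List[Tuple[str, int, float, float]] = []
    while t < total:
        dwell = rng.exponential(cfg.dwell_minutes * 60.0)
        t_start = t
        sample_dwell(hotspots[here], t + dwell)
        segments.append(("dwell", here, t_start, min(t_start + dwell, total)))
        if t >= total:
            break
        if cfg.n_hotspots == 1:
            continue
        nxt = int(rng.integers(cfg.n_hotspots - 1))
        if nxt >= here:
            nxt += 1
        a, b = hotspots[here], hotspots[nxt]
        dist = math.hypot(b[0] - a[0], b[1] - a[1])
        travel = dist / cfg.travel_speed
        t0 = t
        while t < t0 + travel and t < total:
            frac = (t - t0) / travel
            xs.append(a[0] + frac * (b[0] - a[0]))
            ys.append(a[1] + frac * (b[1] - a[1]))
            ts.append(t)
            t += rng.uniform(*cfg.sample_interval)
        segments.append(("transit", nxt, t0, min(t0 + travel, total)))
        here = nxt

    lat0, lon0 = cfg.origin
    lats, lons = unproject_from_plane(np.asarray(xs), np.asarray(ys), lat0, lon0)
    pts = tuple(
        TrajectoryPoint(float(la), float(lo), float(tt))
        for la, lo, tt in zip(lats, lons, ts)
    )
    traj = Trajectory(user_id=f"sim{cfg.seed:03d}", points=pts)
    if return_segments:
        return traj, segments
    return traj


def _draw_points(
    cfg: SimConfig,
    rng: np.random.Generator,
    centers: np.ndarray,
    count: int,
    sd: float,
    t: float,
    start_id: int,
    inside: Optional[Tuple[float, float, float, float]] = None,
    lifetime: Optional[float] = None,
) -> List[WeightedPoint]:
    """Draw ``count`` weighted arrivals around the given hotspot centers.

    When ``inside`` is given, positions are redrawn until they fall in that
    closed rectangle (truncated Gaussian), so planted masses are countable.
    """
    lo, hi = cfg.weight_range
    life = lifetime if lifetime is not None else cfg.window_ticks * cfg.tick_interval
    scale = cfg.scale()
    uniform = inside is None and cfg.background == "uniform"
    out = []
    for k in range(count):
        c = centers[int(rng.integers(len(centers)))]
        while True:
            if uniform:
                pos = rng.uniform(0.0, cfg.domain_size, size=2)
            else:
                pos = np.clip(c + rng.normal(0.0, sd, size=2), 0.0, cfg.domain_size)
            if inside is None:
                break
            if inside[0] <= pos[0] <= inside[1] and inside[2] <= pos[1] <= inside[3]:
                break
        w = hi - rng.uniform(0.0, hi - lo)  # uniform in (lo, hi]
        out.append(
            WeightedPoint(
                id=start_id + k,
                x=float(pos[0] * scale),
                y=float(pos[1] * scale),
                weight=float(w),
                t_arrive=t,
                t_expire=t + life,
            )
        )
    return out


def generate_stream(cfg: SimConfig, n_ticks: int) -> List[Tick]:
    """A POI stream: ``arrival_rate`` weighted points per tick.

    Positions are a hotspot Gaussian mixture over the domain, weights are
    uniform in ``weight_range`` (half-open from below), and every point
    lives exactly one monitoring window.
    """
    rng = cfg.rng()
    hotspots = _hotspots(cfg, rng)
    ticks: List[Tick] = []
    next_id = 0
    for step in range(n_ticks):
        t = step * cfg.tick_interval
        arrivals = _draw_points(
            cfg, rng, hotspots, cfg.arrival_rate, cfg.hotspot_sd * 20, t, next_id
        )
        next_id += len(arrivals)
        ticks.append(Tick(timestamp=t, arrivals=tuple(arrivals)))
    return ticks


def planted_optimum(
    cfg: SimConfig,
    n_ticks: int,
    rect: RectSpec,
    planted_center: Optional[Tuple[float, float]] = None,
    planted_count: int = 50,
):
    """A stream with a known-mass hotspot planted inside a known rectangle.

    The planted points are injected on the first tick with lifetimes covering
    the whole stream, all positioned (truncated Gaussian) inside the
    rectangle of the query's dimensions centered at ``planted_center``.
    Returns ``(ticks, region, known_min_weight)`` where ``region`` is the
    planted rectangle ``(x_lo, x_hi, y_lo, y_hi)`` in output units and
    ``known_min_weight`` the exact total planted weight -- a lower bound on
    the MaxRS optimum at any tick, with equality when the background is
    empty.
    """
    rng = cfg.rng()
    hotspots = _hotspots(cfg, rng)
    if planted_center is None:
        planted_center = (cfg.domain_size / 2.0, cfg.domain_size / 2.0)
    hw, hh = rect.half_width, rect.half_height
    region_m = (
        planted_center[0] - hw,
        planted_center[0] + hw,
        planted_center[1] - hh,
        planted_center[1] + hh,
    )
    horizon = n_ticks * cfg.tick_interval
    planted = _draw_points(
        cfg,
        rng,
        np.asarray([planted_center]),
        planted_count,
        min(hw, hh) / 3.0,
        0.0,
        start_id=10_000_000,
        inside=region_m,
        lifetime=horizon + cfg.tick_interval,
    )
    known_mass = float(sum(p.weight for p in planted))

    ticks: List[Tick] = []
    next_id = 0
    for step in range(n_ticks):
        t = step * cfg.tick_interval
        arrivals = _draw_points(
            cfg, rng, hotspots, cfg.arrival_rate, cfg.hotspot_sd * 20, t, next_id
        )
        next_id += len(arrivals)
        if step == 0:
            arrivals = planted + arrivals
        ticks.append(Tick(timestamp=t, arrivals=tuple(arrivals)))
    scale = cfg.scale()
    region = tuple(v * scale for v in region_m)
    return ticks, region, known_mass
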