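"""Readers, writers, and the counter-based benchmark harness.

Formats touched:

* GeoLife PLT trajectories (read/write): 6 header lines, then rows of
  ``latitude, longitude, flag, altitude, serial_days, date, time``.  The
  altitude field is parsed and discarded (irrelevant for planar trajectory
  analysis); timestamps come from the date+time fields, interpreted as UTC.
* weighted-point CSV (``id,x,y,weight,t_arrive,t_expire``; blank expiry
  means "never").
* stream CSV (``tick,id,x,y,weight``) for the monitor, expiries assigned
  from the window length at read time.
* results as CSV, GeoJSON (Point features for stay places, Polygon features
  for placements), or newline-delimited JSON for monitor events.

The benchmark harness mirrors the parameter-sweep design of the study
(defaults n=500 position points, d=1000 m rectangles, generation rate
m=100) but measures operation counters -- overlap tests and exact-weight
evaluations -- never wall-clock time, so the complexity trends are
hardware-independent.  The recompute baseline stands in for an
instantaneous (non-incremental) solver: each tick it re-evaluates every
candidate placement of the live window by direct coverage computation.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .branchbound import ToleranceConfig, maxrs_branch_bound
from .geometry import (
    Placement,
    RectSpec,
    WeightedPoint,
    _candidate_axis,
    maxrs_planesweep,
)
from .monitor import Monitor, Tick, topk_solve
from .stays import StayPoint, Trajectory, TrajectoryPoint
from .synthetic import SimConfig, generate_stream

__all__ = [
    "read_plt",
    "write_plt",
    "read_points_csv",
    "write_points_csv",
    "read_stream_csv",
    "write_stream_csv",
    "write_results",
    "BenchmarkSpec",
    "run_benchmark",
    "recompute_baseline_tick",
]

logger = logging.getLogger("staymax")

_PLT_HEADER_LINES = 6
_PLT_HEADER = (
    "Geolife trajectory\n"
    "WGS 84\n"
    "Altitude is in Feet\n"
    "Reserved 3\n"
    "0,2,255,My Track,0,0,2,8421376\n"
    "0\n"
)
#: days from the spreadsheet epoch (1899-12-30) to the POSIX epoch
_SERIAL_EPOCH_DAYS = 25569.0


# ---------------------------------------------------------------------------
# GeoLife PLT
# ---------------------------------------------------------------------------

def read_plt(path: Union[str, Path], user_id: Optional[str] = None) -> Trajectory:
    """Parse a GeoLife PLT file into a :class:`Trajectory`.

    Malformed rows raise ``ValueError`` naming the 1-based line number;
    non-monotone timestamps are sorted with a warning rather than rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pts: List[TrajectoryPoint] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if lineno <= _PLT_HEADER_LINES:
                continue
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 7:
                raise ValueError(
                    f"{path.name}: line {lineno}: expected 7 fields, got {len(fields)}"
                )
            try:
                lat = float(fields[0])
                lon = float(fields[1])
                float(fields[3])  # altitude: parsed, then discarded
                ts = datetime.strptime(
                    f"{fields[5]} {fields[6]}", "%Y-%m-%d %H:%M:%S"
                ).replace(tzinfo=timezone.utc).timestamp()
            except ValueError as exc:
                raise ValueError(
                    f"{path.name}: line {lineno}: malformed row ({exc})"
                ) from None
            try:
                pts.append(TrajectoryPoint(lat, lon, ts))
            except ValueError as exc:
                raise ValueError(f"{path.name}: line {lineno}: {exc}") from None
    ts_list = [p.timestamp for p in pts]
    if any(b < a for a, b in zip(ts_list, ts_list[1:])):
        warnings.warn(f"{path.name}: non-monotone timestamps; sorting", stacklevel=2)
        pts.sort(key=lambda p: p.timestamp)
    return Trajectory(user_id=user_id or path.stem, points=tuple(pts))


def write_plt(traj: Trajectory, path: Union[str, Path]) -> None:
    """Write a trajectory in GeoLife PLT layout (altitude written as 0)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_PLT_HEADER)
        for p in traj.points:
            serial = p.timestamp / 86400.0 + _SERIAL_EPOCH_DAYS
            dt = datetime.fromtimestamp(p.timestamp, tz=timezone.utc)
            fh.write(
                f"{p.latitude:.6f},{p.longitude:.6f},0,0,{serial:.10f},"
                f"{dt.strftime('%Y-%m-%d')},{dt.strftime('%H:%M:%S')}\n"
            )


# ---------------------------------------------------------------------------
# point and stream CSV
# ---------------------------------------------------------------------------

def read_points_csv(path: Union[str, Path]) -> List[WeightedPoint]:
    """Read ``id,x,y,weight,t_arrive,t_expire`` rows; blank expiry = never."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    required = ["id", "x", "y", "weight", "t_arrive", "t_expire"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate ids {dupes}")
    points = []
    for row in df.itertuples(index=False):
        t_exp = float(row.t_expire) if pd.notna(row.t_expire) else math.inf
        points.append(
            WeightedPoint(
                id=row.id,
                x=float(row.x),
                y=float(row.y),
                weight=float(row.weight),
                t_arrive=float(row.t_arrive),
                t_expire=t_exp,
            )
        )
    return points


def write_points_csv(points: Sequence[WeightedPoint], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "weight", "t_arrive", "t_expire"])
        for p in points:
            w.writerow(
                [
                    p.id,
                    repr(p.x),
                    repr(p.y),
                    repr(p.weight),
                    repr(p.t_arrive),
                    "" if math.isinf(p.t_expire) else repr(p.t_expire),
                ]
            )


def read_stream_csv(
    path: Union[str, Path], window: float, tick_interval: float = 1.0
) -> List[Tick]:
    """Read ``tick,id,x,y,weight`` rows into Ticks; expiry = arrival + window."""
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    required = ["tick", "id", "x", "y", "weight"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ticks = []
    for tick_no, group in df.groupby("tick", sort=True):
        t = float(tick_no) * tick_interval
        arrivals = tuple(
            WeightedPoint(
                id=r.id, x=float(r.x), y=float(r.y), weight=float(r.weight),
                t_arrive=t, t_expire=t + window,
            )
            for r in group.itertuples(index=False)
        )
        ticks.append(Tick(timestamp=t, arrivals=arrivals))
    return ticks


def write_stream_csv(ticks: Sequence[Tick], path: Union[str, Path]) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tick", "id", "x", "y", "weight"])
        for i, tk in enumerate(ticks):
            for p in tk.arrivals:
                w.writerow([i, p.id, repr(p.x), repr(p.y), repr(p.weight)])


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def _placement_rows(placements):
    for p in placements:
        yield {
            "center_x": p.center_x,
            "center_y": p.center_y,
            "weight_sum": p.weight_sum,
            "n_covered": len(p.covered_ids),
            "label": p.label,
        }


def _stay_rows(stays):
    for s in stays:
        yield {
            "centroid_x": s.centroid_x,
            "centroid_y": s.centroid_y,
            "t_arrive": s.t_arrive,
            "t_depart": s.t_depart,
            "duration_s": s.duration,
            "kind": s.kind,
            "span_m": s.span,
        }


def write_results(
    records: Sequence,
    path: Union[str, Path],
    format: str = "csv",
    rect: Optional[RectSpec] = None,
) -> None:
    """Write placements, stays, or monitor event dicts.

    ``format`` is one of ``csv``, ``geojson``, ``ndjson``.  GeoJSON emits
    Point features for stays/SP events and Polygon features for placements
    (the placed rectangle, which needs ``rect``).
    """
    path = Path(path)
    records = list(records)
    kind = (
        "placement"
        if records and isinstance(records[0], Placement)
        else "stay"
        if records and isinstance(records[0], StayPoint)
        else "event"
    )
    if format == "csv":
        if kind == "placement":
            rows = list(_placement_rows(records))
        elif kind == "stay":
            rows = list(_stay_rows(records))
        else:
            rows = records
        df = pd.DataFrame(rows)
        if df.empty:
            headers = {
                "placement": ["center_x", "center_y", "weight_sum", "n_covered", "label"],
                "stay": ["centroid_x", "centroid_y", "t_arrive", "t_depart",
                         "duration_s", "kind", "span_m"],
                "event": ["event", "t"],
            }[kind]
            df = pd.DataFrame(columns=headers)
        df.to_csv(path, index=False)
    elif format == "geojson":
        feats = []
        for r in records:
            if isinstance(r, Placement):
                if r.is_null:
                    continue
                if rect is None:
                    geom = {"type": "Point", "coordinates": [r.center_x, r.center_y]}
                else:
                    hw, hh = rect.half_width, rect.half_height
                    ring = [
                        [r.center_x - hw, r.center_y - hh],
                        [r.center_x + hw, r.center_y - hh],
                        [r.center_x + hw, r.center_y + hh],
                        [r.center_x - hw, r.center_y + hh],
                        [r.center_x - hw, r.center_y - hh],
                    ]
                    geom = {"type": "Polygon", "coordinates": [ring]}
                props = {"weight_sum": r.weight_sum, "n_covered": len(r.covered_ids)}
            elif isinstance(r, StayPoint):
                geom = {"type": "Point", "coordinates": [r.centroid_x, r.centroid_y]}
                props = {"kind": r.kind, "duration_s": r.duration}
            else:
                geom = {"type": "Point", "coordinates": list(r.get("sp", [None, None]))}
                props = {k: v for k, v in r.items() if k != "sp"}
            feats.append({"type": "Feature", "geometry": geom, "properties": props})
        path.write_text(
            json.dumps({"type": "FeatureCollection", "features": feats}, indent=2)
        )
    elif format == "ndjson":
        with path.open("w") as fh:
            for r in records:
                fh.write(json.dumps(r) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_ndjson(path: Union[str, Path]) -> List[dict]:
    with Path(path).open() as fh:
        return [json.loads(line) for line in fh if line.strip()]


# ---------------------------------------------------------------------------
# recompute baseline + benchmark
# ---------------------------------------------------------------------------

def recompute_baseline_tick(points: Sequence[WeightedPoint], rect: RectSpec):
    """Instantaneous from-scratch MaxRS by candidate re-evaluation.

    Evaluates the covered weight of every candidate placement of the live
    window directly; returns ``(best_weight, exact_weight_evals)`` where the
    counter is the number of candidate placements evaluated -- Theta(n^2)
    for n live points, the cost an instantaneous solver pays every tick.
    """
    if not points:
        return 0.0, 0
    xs = np.asarray([p.x for p in points])
    ys = np.asarray([p.y for p in points])
    ws = np.asarray([p.weight for p in points])
    hw, hh = rect.half_width, rect.half_height
    xlo, xhi = xs - hw, xs + hw
    ylo, yhi = ys - hh, ys + hh
    best = 0.0
    evals = 0
    for cx in _candidate_axis(xs, hw):
        slab = (xlo <= cx) & (cx <= xhi)
        if not slab.any():
            continue
        ys_lo, ys_hi, ws_s = ylo[slab], yhi[slab], ws[slab]
        cys = _candidate_axis(ys[slab], hh)
        evals += cys.size
        cover = (ys_lo[None, :] <= cys[:, None]) & (cys[:, None] <= ys_hi[None, :])
        m = float((cover @ ws_s).max())
        if m > best:
            best = m
    return best, evals


@dataclass(frozen=True)
class BenchmarkSpec:
    """One parameter sweep mirroring the study's experimental design.

    ``param`` is one of ``n`` (live position count), ``d`` (rectangle side,
    meters), ``m`` (generation rate, points/tick), ``tol`` (user tolerance)
    or ``k`` (query answers).  Fixed defaults: n=500, d=1000, m=100.
    Metrics are operation counters and result weights only.
    """

    param: str
    values: Tuple[float, ...]
    seeds: Tuple[int, ...] = (0,)
    n_default: int = 500
    d_default: float = 1000.0
    m_default: int = 100
    k_default: int = 10
    measure_ticks: int = 10

    def __post_init__(self) -> None:
        if self.param not in ("n", "d", "m", "tol", "k"):
            raise ValueError(f"unknown sweep parameter {self.param!r}")
        if not self.values:
            raise ValueError("values must be non-empty")


def _bench_one(spec: BenchmarkSpec, value: float, seed: int) -> Dict[str, float]:
    n = spec.n_default
    d = spec.d_default
    m = spec.m_default
    tol = 0.0
    k = spec.k_default
    if spec.param == "n":
        n = int(value)
    elif spec.param == "d":
        d = float(value)
    elif spec.param == "m":
        m = int(value)
    elif spec.param == "tol":
        tol = float(value)
    elif spec.param == "k":
        k = int(value)
    window = max(1, round(n / m))
    rect = RectSpec(d, d)
    cfg = SimConfig(seed=seed, arrival_rate=m, window_ticks=window, domain_size=5000.0)
    warmup = window
    ticks = generate_stream(cfg, warmup + spec.measure_ticks)
    mon = Monitor(rect, k=1)
    inc_overlap = inc_exact = base_exact = 0
    live_n = 0.0
    measured = 0
    bb_min_ratio = math.inf
    for i, tk in enumerate(ticks):
        c0 = dict(mon.state.index.op_counters)
        mon.step(tk)
        if i < warmup:
            continue
        c1 = mon.state.index.op_counters
        inc_overlap += c1["overlap_tests"] - c0["overlap_tests"]
        inc_exact += c1["exact_weight_evals"] - c0["exact_weight_evals"]
        live = mon.state.index.live_points()
        live_n += len(live)
        base_w, evals = recompute_baseline_tick(live, rect)
        base_exact += evals
        inc_w = mon.state.best.weight_sum if mon.state.best else 0.0
        if not math.isclose(inc_w, base_w, rel_tol=1e-9, abs_tol=1e-9):
            raise AssertionError(
                f"backend weight mismatch: incremental {inc_w} vs recompute {base_w}"
            )
        measured += 1
        if spec.param == "tol" and measured == 1:
            bb = maxrs_branch_bound(live, rect, ToleranceConfig(tol=tol))
            bb_min_ratio = min(
                bb_min_ratio, bb.weight_sum / base_w if base_w > 0 else 1.0
            )
        if spec.param == "k" and measured == 1:
            placements = topk_solve(live, rect, k)
            bb_min_ratio = float(len(placements))
    row = {
        "param": spec.param,
        "value": value,
        "seed": seed,
        "live_n": live_n / max(measured, 1),
        "inc_overlap_per_tick": inc_overlap / max(measured, 1),
        "inc_exact_per_tick": inc_exact / max(measured, 1),
        "base_exact_per_tick": base_exact / max(measured, 1),
    }
    if spec.param == "tol":
        row["bb_weight_ratio"] = bb_min_ratio
        row["tol_floor"] = 1.0 - tol
    if spec.param == "k":
        row["n_placements"] = bb_min_ratio
    return row


def run_benchmark(spec: BenchmarkSpec, out: Optional[Union[str, Path]] = None):
    """Run a sweep; returns a DataFrame (and writes a TSV when ``out`` given).

    Both backends (incremental index and from-scratch recompute) must agree
    on the best weight at every measured tick, so counters are the only
    varying metric.
    """
    rows = [
        _bench_one(spec, v, s) for v in spec.values for s in spec.seeds
    ]
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, sep="\t", index=False)
    return df
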