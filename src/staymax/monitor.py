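"""Continuous MaxRS monitoring over a sliding window of POIs.

Per tick the monitor expires due points, inserts arrivals, and maintains the
best placement and the greedy-disjoint top-k list (solve MaxRS, remove the
covered points, repeat), with the k-th placement weight as the update
threshold.  The binding contract is step-wise exactness: after every tick
the top-k equals a from-scratch greedy solve on the live window.

Two mechanisms keep the per-tick work proportional to the update size rather
than the window size:

* a guarded *fast path*: when no expired point was covered by any top-k
  placement and every arrival's cell-neighborhood upper bound is strictly
  below the k-th weight threshold, no placement at or above the threshold
  can have changed and the top-k stands as-is;
* on the slow path, each greedy extraction re-evaluates the corresponding
  previous placement as an incumbent and restricts the plane sweep to points
  near cells whose neighborhood bound is not strictly below it (strict
  pruning preserves equal-weight optima, so ties resolve exactly as in the
  from-scratch solve).

The monitoring output is the stay place (SP): the weighted centroid of the
points covered by the current best placement.  An SP event is emitted
whenever the best placement's covered set changes or its centroid moves,
marking the previous SP obsolete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .geometry import (
    Placement,
    RectSpec,
    WeightedPoint,
    _covered_mask,
    _solve_sweep_arrays,
    centroid_of,
)
from .streamindex import GridOverlapIndex

__all__ = ["Tick", "MonitorState", "Monitor", "step", "topk_solve", "current_stay_place"]

#: centroid movement below this is treated as "the SP did not move" (units)
SP_MOVE_EPS = 1e-9


@dataclass(frozen=True)
class Tick:
    """One batch of stream updates: arrivals plus explicit departures."""

    timestamp: float
    arrivals: Tuple[WeightedPoint, ...] = ()
    departures: Tuple[object, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "arrivals", tuple(self.arrivals))
        object.__setattr__(self, "departures", tuple(self.departures))


@dataclass
class SPRecord:
    """An emitted stay place; ``obsolete_at`` is set once superseded."""

    centroid: Tuple[float, float]
    weight: float
    covered_ids: frozenset
    since: float
    obsolete_at: Optional[float] = None


def _topk_arrays(xs, ys, ws, ids, rect: RectSpec, k: int, alive=None):
    """Greedy-disjoint top-k on raw arrays; returns list of Placements."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if alive is None:
        alive = np.ones(xs.size, dtype=bool)
    else:
        alive = alive.copy()
    hw, hh = rect.half_width, rect.half_height
    out: List[Placement] = []
    for _ in range(k):
        sub = np.nonzero(alive)[0]
        if sub.size == 0:
            break
        w, cx, cy = _solve_sweep_arrays(xs[sub], ys[sub], ws[sub], rect)
        if cx is None or w <= 0.0:
            break
        mask = _covered_mask(xs[sub], ys[sub], cx, cy, hw, hh)
        covered = sub[mask]
        out.append(
            Placement(
                cx,
                cy,
                float(ws[covered].sum()),
                frozenset(ids[i] for i in covered),
            )
        )
        alive[covered] = False
    return out


def topk_solve(
    points: Sequence[WeightedPoint], rect: RectSpec, k: int
) -> List[Placement]:
    """Greedy iterative extraction of up to k disjoint MaxRS placements.

    Placements come back in extraction order with non-increasing weights;
    extraction stops early once the best remaining weight is 0.
    """
    ids = [p.id for p in points]
    xs = np.asarray([p.x for p in points])
    ys = np.asarray([p.y for p in points])
    ws = np.asarray([p.weight for p in points])
    return _topk_arrays(xs, ys, ws, ids, rect, k)


@dataclass
class MonitorState:
    """Mutable monitor state: the index, the current answers, the history."""

    index: GridOverlapIndex
    rect: RectSpec
    k: int = 1
    topk: List[Placement] = field(default_factory=list)
    threshold: float = 0.0
    history: List[SPRecord] = field(default_factory=list)
    last_timestamp: float = -math.inf
    fast_path_ticks: int = 0
    slow_path_ticks: int = 0

    @property
    def best(self) -> Optional[Placement]:
        return self.topk[0] if self.topk else None


class Monitor:
    """Drives a :class:`MonitorState` through a stream of ticks."""

    def __init__(
        self,
        rect: RectSpec,
        k: int = 1,
        cell_width: Optional[float] = None,
        cell_height: Optional[float] = None,
    ) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.state = MonitorState(
            index=GridOverlapIndex(rect, cell_width, cell_height), rect=rect, k=k
        )

    # -- helpers ------------------------------------------------------------

    def _live_arrays(self):
        idx = self.state.index
        ids = list(idx.vertices)
        xs = np.asarray([idx.vertices[i].point.x for i in ids])
        ys = np.asarray([idx.vertices[i].point.y for i in ids])
        ws = np.asarray([idx.vertices[i].point.weight for i in ids])
        homes = [idx.vertices[i].home for i in ids]
        return ids, xs, ys, ws, homes

    def _resolve(self, prev_topk: List[Placement]) -> List[Placement]:
        """Greedy top-k with strict incumbent pruning; equals the from-scratch solve."""
        st = self.state
        idx = st.index
        rect = st.rect
        hw, hh = rect.half_width, rect.half_height
        ids, xs, ys, ws, homes = self._live_arrays()
        n = xs.size
        alive = np.ones(n, dtype=bool)
        out: List[Placement] = []
        for rank in range(st.k):
            if not alive.any():
                break
            incumbent = 0.0
            if rank < len(prev_topk) and not prev_topk[rank].is_null:
                p = prev_topk[rank]
                idx.op_counters["exact_weight_evals"] += 1
                m = _covered_mask(xs, ys, p.center_x, p.center_y, hw, hh) & alive
                incumbent = max(0.0, float(ws[m].sum()))
            if incumbent > 0.0:
                pruned = idx.prunable_cells(incumbent, strict=True)
                if pruned:
                    surviving = set(idx.cells) - pruned
                    allowed = set()
                    for (i, j) in surviving:
                        for di in range(-idx._rx, idx._rx + 1):
                            for dj in range(-idx._ry, idx._ry + 1):
                                allowed.add((i + di, j + dj))
                    keep = np.fromiter(
                        (homes[i] in allowed for i in range(n)), bool, count=n
                    )
                    sub = np.nonzero(alive & keep)[0]
                else:
                    sub = np.nonzero(alive)[0]
            else:
                sub = np.nonzero(alive)[0]
            if sub.size == 0:
                break
            w, cx, cy = _solve_sweep_arrays(xs[sub], ys[sub], ws[sub], rect)
            if cx is None or w <= 0.0:
                break
            mask = _covered_mask(xs[sub], ys[sub], cx, cy, hw, hh)
            covered = sub[mask]
            out.append(
                Placement(cx, cy, float(ws[covered].sum()),
                          frozenset(ids[i] for i in covered))
            )
            alive[covered] = False
        return out

    # -- the per-tick transition -------------------------------------------

    def step(self, tick: Tick) -> List[dict]:
        """Apply one tick; returns the emitted SP / top-k events."""
        st = self.state
        if tick.timestamp < st.last_timestamp:
            raise ValueError(
                f"time regression: {tick.timestamp} < {st.last_timestamp}"
            )
        idx = st.index
        covered_by_topk: Set[object] = set()
        for p in st.topk:
            covered_by_topk |= p.covered_ids

        # 1. expiries (time-based window) + explicit departures
        due = [
            pid
            for pid, v in idx.vertices.items()
            if v.point.t_expire <= tick.timestamp
        ]
        for pid in tick.departures:
            if pid in idx and pid not in due:
                due.append(pid)
        expiry_hits_topk = any(pid in covered_by_topk for pid in due)
        for pid in due:
            idx.expire_point(pid)

        # 2. arrivals
        for p in tick.arrivals:
            idx.insert_point(p)

        # 3. fast path: the incumbent top-k provably still stands
        fast = (
            not expiry_hits_topk
            and len(st.topk) == st.k
            and st.threshold > 0.0
            and all(
                idx.neighborhood_bound(idx.vertices[p.id].home) < st.threshold
                for p in tick.arrivals
            )
        )
        prev_topk = st.topk
        prev_best = st.best
        if fast:
            st.fast_path_ticks += 1
        else:
            st.slow_path_ticks += 1
            st.topk = self._resolve(prev_topk)
            st.threshold = (
                st.topk[st.k - 1].weight_sum if len(st.topk) >= st.k else 0.0
            )

        # 4. SP / top-k events
        events: List[dict] = []
        best = st.best
        if not fast:
            if [p.weight_sum for p in prev_topk] != [p.weight_sum for p in st.topk]:
                events.append(
                    {
                        "event": "TOPK_CHANGE",
                        "t": tick.timestamp,
                        "weights": [p.weight_sum for p in st.topk],
                    }
                )
            changed = self._sp_changed(prev_best, best)
            if changed:
                if st.history and st.history[-1].obsolete_at is None:
                    st.history[-1].obsolete_at = tick.timestamp
                    events.append(
                        {
                            "event": "SP_OBSOLETE",
                            "t": tick.timestamp,
                            "sp": list(st.history[-1].centroid),
                            "weight": st.history[-1].weight,
                        }
                    )
                if best is not None:
                    sp = self._sp_of(best)
                    st.history.append(
                        SPRecord(
                            centroid=sp,
                            weight=best.weight_sum,
                            covered_ids=best.covered_ids,
                            since=tick.timestamp,
                        )
                    )
                    events.append(
                        {
                            "event": "SP_NEW",
                            "t": tick.timestamp,
                            "sp": list(sp),
                            "weight": best.weight_sum,
                            "covered": sorted(map(str, best.covered_ids)),
                        }
                    )
        st.last_timestamp = tick.timestamp
        return events

    def _sp_of(self, placement: Placement) -> Tuple[float, float]:
        pts = [
            self.state.index.vertices[pid].point
            for pid in placement.covered_ids
            if pid in self.state.index
        ]
        if not pts:
            return (placement.center_x, placement.center_y)
        return centroid_of(pts)

    def _sp_changed(self, prev: Optional[Placement], new: Optional[Placement]) -> bool:
        if prev is None and new is None:
            return False
        if (prev is None) != (new is None):
            return True
        if prev.covered_ids != new.covered_ids:
            return True
        if not self.state.history:
            return True
        sp_new = self._sp_of(new)
        sp_old = self.state.history[-1].centroid
        return math.hypot(sp_new[0] - sp_old[0], sp_new[1] - sp_old[1]) > SP_MOVE_EPS


def step(state_or_monitor, tick: Tick, rect: Optional[RectSpec] = None):
    """Functional wrapper: apply one tick, return ``(state, events)``."""
    if isinstance(state_or_monitor, Monitor):
        mon = state_or_monitor
    else:
        raise TypeError("step expects a Monitor instance")
    if rect is not None and rect != mon.state.rect:
        raise ValueError("rect must match the monitor's rectangle")
    events = mon.step(tick)
    return mon.state, events


def current_stay_place(monitor: Monitor) -> SPRecord:
    """The current SP: centroid and weight of the best placement's points."""
    st = monitor.state
    if st.best is None:
        raise ValueError("no stay place: no live points under the best placement")
    rec = st.history[-1] if st.history else None
    if rec is not None and rec.obsolete_at is None:
        return rec
    sp = monitor._sp_of(st.best)
    return SPRecord(
        centroid=sp,
        weight=st.best.weight_sum,
        covered_ids=st.best.covered_ids,
        since=st.last_timestamp,
    )
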