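"""Exact maximizing range-sum (MaxRS) solvers.

Given a set of weighted planar points (POIs) and a fixed-size axis-aligned
query rectangle, MaxRS asks for the rectangle placement that maximizes the
total weight of the points it covers.  The classic solution transforms each
point into its *dual rectangle* -- a rectangle of the query's dimensions
centered on the point -- after which a placement center ``c`` covers point
``p`` iff ``c`` lies inside ``p``'s dual rectangle.  The optimum is then the
maximum-depth (weight-accumulated) point of the dual-rectangle arrangement,
found by a plane sweep over x-events with a range-add / range-max structure
over compressed y-coordinates.

This module houses the exact solvers (a brute-force candidate enumeration
used as an oracle, and the O(n log n) plane sweep), the multi-label variant
used for joint localization + recognition, and the centroid used to report a
stay place (SP).

Boundary convention: rectangles are closed on all four edges, so a point
exactly on the boundary counts as covered.

Candidate grid
--------------
With mixed-sign weights an optimal closed placement need not touch any point
with its boundary: two negative dual rectangles can bracket an open interval
of optimal centers.  Both exact solvers therefore evaluate the same canonical
candidate grid per axis: every dual-edge coordinate (``x_i - w/2`` and
``x_i + w/2``) plus the midpoint of each pair of consecutive distinct edge
coordinates.  The weight function is piecewise constant between edges, so
this grid provably contains an optimal center, and sharing it between the
solvers makes the lexicographic tie-break (smallest ``(center_x, center_y)``)
identical across them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "WeightedPoint",
    "RectSpec",
    "Placement",
    "covered_weight",
    "dual_rectangle",
    "maxrs_bruteforce",
    "maxrs_planesweep",
    "maxrs_multilabel",
    "centroid_of",
    "BRUTEFORCE_CAP",
]

#: largest instance the brute-force oracle accepts before demanding the sweep
BRUTEFORCE_CAP = 200


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightedPoint:
    """A weighted POI: planar position, signed weight, arrival/expiry times."""

    id: object
    x: float
    y: float
    weight: float = 1.0
    t_arrive: float = 0.0
    t_expire: float = math.inf

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"point {self.id!r}: non-finite coordinates")
        if not math.isfinite(self.weight):
            raise ValueError(f"point {self.id!r}: non-finite weight")
        if not self.t_expire > self.t_arrive:
            raise ValueError(
                f"point {self.id!r}: t_expire ({self.t_expire}) must exceed "
                f"t_arrive ({self.t_arrive})"
            )


@dataclass(frozen=True)
class RectSpec:
    """Query rectangle dimensions, in the same units as point coordinates."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and math.isfinite(self.width)):
            raise ValueError(f"width must be positive and finite, got {self.width}")
        if not (self.height > 0 and math.isfinite(self.height)):
            raise ValueError(f"height must be positive and finite, got {self.height}")

    @property
    def half_width(self) -> float:
        return self.width / 2.0

    @property
    def half_height(self) -> float:
        return self.height / 2.0


@dataclass(frozen=True)
class Placement:
    """A solved rectangle placement.

    ``center_x``/``center_y`` are ``None`` for the null placement returned on
    empty or all-nonpositive input (covering nothing has weight 0, which the
    unbounded argmax can always achieve).
    """

    center_x: Optional[float]
    center_y: Optional[float]
    weight_sum: float
    covered_ids: frozenset = frozenset()
    label: Optional[int] = None

    @classmethod
    def null(cls, label: Optional[int] = None) -> "Placement":
        return cls(None, None, 0.0, frozenset(), label)

    @property
    def is_null(self) -> bool:
        return self.center_x is None


# ---------------------------------------------------------------------------
# array plumbing
# ---------------------------------------------------------------------------

def as_arrays(points: Sequence[WeightedPoint]):
    """Unpack a point collection into (ids, xs, ys, ws) numpy-friendly form."""
    ids = [p.id for p in points]
    xs = np.asarray([p.x for p in points], dtype=np.float64)
    ys = np.asarray([p.y for p in points], dtype=np.float64)
    ws = np.asarray([p.weight for p in points], dtype=np.float64)
    return ids, xs, ys, ws


def _candidate_axis(coords: np.ndarray, half: float) -> np.ndarray:
    """Canonical candidate coordinates for one axis (see module docstring)."""
    crit = np.unique(np.concatenate([coords - half, coords + half]))
    if crit.size > 1:
        mids = (crit[:-1] + crit[1:]) / 2.0
        return np.unique(np.concatenate([crit, mids]))
    return crit


def _covered_mask(xs, ys, cx, cy, hw, hh):
    """Closed membership in the dual form: consistent with the sweep events."""
    return (
        (xs - hw <= cx) & (cx <= xs + hw) & (ys - hh <= cy) & (cy <= ys + hh)
    )


# ---------------------------------------------------------------------------
# point-query operations
# ---------------------------------------------------------------------------

def covered_weight(points: Sequence[WeightedPoint], center, rect: RectSpec):
    """Total weight and ids of points inside the closed rectangle at ``center``.

    Returns ``(weight_sum, covered_ids)``.  Raises ``ValueError`` for a
    non-finite query center.
    """
    cx, cy = float(center[0]), float(center[1])
    if not (math.isfinite(cx) and math.isfinite(cy)):
        raise ValueError(f"invalid query center {center!r}")
    hw, hh = rect.half_width, rect.half_height
    total = 0.0
    ids = set()
    for p in points:
        if abs(p.x - cx) <= hw and abs(p.y - cy) <= hh:
            total += p.weight
            ids.add(p.id)
    return total, ids


def dual_rectangle(point: WeightedPoint, rect: RectSpec):
    """Closed dual rectangle of ``point``: the set of centers covering it.

    Returned as ``(x_lo, x_hi, y_lo, y_hi)``.
    """
    hw, hh = rect.half_width, rect.half_height
    return (point.x - hw, point.x + hw, point.y - hh, point.y + hh)


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def _solve_bruteforce_arrays(xs, ys, ws, rect: RectSpec):
    """Candidate-grid enumeration; returns (weight, cx, cy) or (0, None, None)."""
    n = xs.size
    hw, hh = rect.half_width, rect.half_height
    if n == 0:
        return 0.0, None, None
    xlo, xhi = xs - hw, xs + hw
    ylo, yhi = ys - hh, ys + hh
    cxs = _candidate_axis(xs, hw)
    cys = _candidate_axis(ys, hh)
    best_w, best_x, best_y = 0.0, None, None
    for cx in cxs:
        slab = (xlo <= cx) & (cx <= xhi)
        if not slab.any():
            continue
        ys_lo, ys_hi, ws_s = ylo[slab], yhi[slab], ws[slab]
        cover = (ys_lo[None, :] <= cys[:, None]) & (cys[:, None] <= ys_hi[None, :])
        sums = cover @ ws_s
        j = int(np.argmax(sums))  # first (smallest-y) maximum
        if sums[j] > best_w:
            best_w, best_x, best_y = float(sums[j]), float(cx), float(cys[j])
    return best_w, best_x, best_y


def maxrs_bruteforce(
    points: Sequence[WeightedPoint], rect: RectSpec, cap: int = BRUTEFORCE_CAP
) -> Placement:
    """Exact MaxRS by direct candidate enumeration (the independent oracle).

    Ties are broken by the lexicographically smallest ``(center_x, center_y)``
    over the canonical candidate grid.  Refuses instances larger than ``cap``
    points; use :func:`maxrs_planesweep` for those.
    """
    if len(points) > cap:
        raise ValueError(
            f"brute-force oracle capped at {cap} points (got {len(points)}); "
            "use maxrs_planesweep"
        )
    ids, xs, ys, ws = as_arrays(points)
    w, cx, cy = _solve_bruteforce_arrays(xs, ys, ws, rect)
    if cx is None:
        return Placement.null()
    mask = _covered_mask(xs, ys, cx, cy, rect.half_width, rect.half_height)
    return Placement(cx, cy, float(ws[mask].sum()),
                     frozenset(ids[i] for i in np.nonzero(mask)[0]))


# ---------------------------------------------------------------------------
# plane sweep
# ---------------------------------------------------------------------------

class _MaxAddTree:
    """Segment tree: range add, global max, leftmost argmax.

    ``mx[v] = val[v] + max(mx[children])`` where ``val`` is the pending add
    at each node; the root max is the current maximum stabbing weight.
    Padding leaves keep value 0 and sit to the right of all real leaves, so
    the leftmost-argmax descent (ties go left) never prefers them when the
    maximum is positive.
    """

    __slots__ = ("size", "val", "mx")

    def __init__(self, n: int) -> None:
        size = 1
        while size < max(n, 1):
            size <<= 1
        self.size = size
        self.val = [0.0] * (2 * size)
        self.mx = [0.0] * (2 * size)

    def add(self, lo: int, hi: int, v: float) -> None:
        """Add ``v`` on the inclusive leaf range [lo, hi]."""
        val, mx = self.val, self.mx
        l0 = lo + self.size
        r0 = hi + self.size
        l, r = l0, r0 + 1
        while l < r:
            if l & 1:
                val[l] += v
                mx[l] += v
                l += 1
            if r & 1:
                r -= 1
                val[r] += v
                mx[r] += v
            l >>= 1
            r >>= 1
        for p0 in (l0, r0):
            p = p0 >> 1
            while p >= 1:
                a, b = mx[2 * p], mx[2 * p + 1]
                mx[p] = (a if a >= b else b) + val[p]
                p >>= 1

    @property
    def root_max(self) -> float:
        return self.mx[1]

    def leftmost_argmax(self) -> int:
        node = 1
        mx = self.mx
        while node < self.size:
            node = 2 * node if mx[2 * node] >= mx[2 * node + 1] else 2 * node + 1
        return node - self.size


def _solve_sweep_arrays(xs, ys, ws, rect: RectSpec):
    """Plane-sweep MaxRS core; returns (weight, cx, cy) or (0, None, None)."""
    n = xs.size
    if n == 0:
        return 0.0, None, None
    hw, hh = rect.half_width, rect.half_height
    xlo, xhi = xs - hw, xs + hw
    ylo, yhi = ys - hh, ys + hh

    ycand = _candidate_axis(ys, hh)
    seg_lo = np.searchsorted(ycand, ylo, side="left")
    seg_hi = np.searchsorted(ycand, yhi, side="right") - 1

    xcrit = np.unique(np.concatenate([xlo, xhi]))
    by_start = np.argsort(xlo, kind="stable")
    by_end = np.argsort(xhi, kind="stable")

    tree = _MaxAddTree(ycand.size)
    best_w, best_x, best_y = 0.0, None, None
    si = ei = 0
    ngroups = xcrit.size
    for g_idx in range(ngroups):
        g = xcrit[g_idx]
        # insertions: every dual interval whose left edge sits at g
        while si < n and xlo[by_start[si]] == g:
            i = by_start[si]
            tree.add(seg_lo[i], seg_hi[i], ws[i])
            si += 1
        m = tree.root_max
        if m > best_w:
            best_w = m
            best_x = float(g)
            best_y = float(ycand[tree.leftmost_argmax()])
        # removals: intervals whose right edge sits at g
        while ei < n and xhi[by_end[ei]] == g:
            i = by_end[ei]
            tree.add(seg_lo[i], seg_hi[i], -ws[i])
            ei += 1
        if g_idx + 1 < ngroups:
            mid = (g + xcrit[g_idx + 1]) / 2.0
            if g < mid < xcrit[g_idx + 1]:
                m = tree.root_max
                if m > best_w:
                    best_w = m
                    best_x = float(mid)
                    best_y = float(ycand[tree.leftmost_argmax()])
    return best_w, best_x, best_y


def maxrs_planesweep(points: Sequence[WeightedPoint], rect: RectSpec) -> Placement:
    """Exact MaxRS via the dual-rectangle plane sweep.

    Agrees with :func:`maxrs_bruteforce` in weight and (under the shared
    candidate grid) in tie-broken placement on every input.
    """
    ids, xs, ys, ws = as_arrays(points)
    w, cx, cy = _solve_sweep_arrays(xs, ys, ws, rect)
    if cx is None:
        return Placement.null()
    mask = _covered_mask(xs, ys, cx, cy, rect.half_width, rect.half_height)
    return Placement(cx, cy, float(ws[mask].sum()),
                     frozenset(ids[i] for i in np.nonzero(mask)[0]))


# ---------------------------------------------------------------------------
# multi-label variant (joint localization + recognition)
# ---------------------------------------------------------------------------

def maxrs_multilabel(
    points: Sequence[WeightedPoint],
    scores: Sequence[Sequence[float]],
    rect: RectSpec,
    offsets: Optional[Sequence[float]] = None,
) -> Placement:
    """MaxRS over per-label partial score channels.

    ``scores[i]`` holds point ``i``'s partial score for each of ``L`` labels;
    for each label the plane sweep runs with that channel as the weights
    (plus the optional per-label additive offset), and the globally best
    (placement, label) pair wins.  Label ties go to the smallest label index.
    """
    if len(scores) != len(points):
        raise ValueError("scores must align one-to-one with points")
    sc = np.asarray(scores, dtype=np.float64)
    if sc.ndim != 2:
        raise ValueError("scores must be a 2-D (n_points x n_labels) array")
    n_labels = sc.shape[1]
    if n_labels < 1:
        raise ValueError("at least one label channel required")
    if not np.isfinite(sc).all():
        raise ValueError("scores must be finite")
    if offsets is not None and len(offsets) != n_labels:
        raise ValueError("offsets must have one entry per label")

    ids, xs, ys, _ = as_arrays(points)
    best: Optional[Placement] = None
    for lab in range(n_labels):
        ws = sc[:, lab]
        w, cx, cy = _solve_sweep_arrays(xs, ys, ws, rect)
        if offsets is not None:
            w += float(offsets[lab])
        if best is None or w > best.weight_sum:
            if cx is None:
                best = Placement(None, None, w, frozenset(), lab)
            else:
                mask = _covered_mask(xs, ys, cx, cy, rect.half_width, rect.half_height)
                best = Placement(cx, cy, w,
                                 frozenset(ids[i] for i in np.nonzero(mask)[0]), lab)
    return best


# ---------------------------------------------------------------------------
# stay-place centroid
# ---------------------------------------------------------------------------

def centroid_of(points: Sequence[WeightedPoint]):
    """Weight-weighted mean position of a point subset.

    Negative weights are excluded from the average (a stay place is a
    physical location summary and the monitored POI weights are positive);
    if no positive weight remains the unweighted mean is returned.
    """
    if len(points) == 0:
        raise ValueError("centroid of an empty subset is undefined")
    _, xs, ys, ws = as_arrays(points)
    w = np.clip(ws, 0.0, None)
    tot = w.sum()
    if tot <= 0.0:
        return float(xs.mean()), float(ys.mean())
    return float((xs * w).sum() / tot), float((ys * w).sum() / tot)
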