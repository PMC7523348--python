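"""Tolerance-bounded branch-and-bound MaxRS.

Best-first search over subspaces of candidate rectangle centers.  Each
subspace ``d`` carries an optimistic/pessimistic bound pair built from two
regions:

* ``+b`` -- the union of rectangles over all centers in ``d`` (the subspace
  expanded by the rectangle half-extents): any point a center in ``d`` can
  possibly cover lies in ``+b``;
* ``-b`` -- the intersection of those rectangles (the subspace shrunk by the
  half-extents, possibly empty): every center in ``d`` covers all of ``-b``.

upper = sum of positive weights in ``+b`` plus negative weights in ``-b``;
lower = sum of positive weights in ``-b`` plus negative weights in ``+b``,
so ``lower <= (best achievable in d) <= upper``.

A subspace is pruned when ``upper(d) * (1 - tol) <= best_found``, which makes
the returned weight ``w0`` satisfy the guarantee ``w0 >= (1 - tol) * w_opt``;
with ``tol = 0`` the search is exact and recovers the plane-sweep optimum.
Leaves (subspaces below the resolution floor) are finished by evaluating
every canonical candidate center they contain exactly.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .geometry import (
    Placement,
    RectSpec,
    WeightedPoint,
    _candidate_axis,
    _covered_mask,
    as_arrays,
)

__all__ = [
    "SearchSpace",
    "BoundPair",
    "ToleranceConfig",
    "branch",
    "bound",
    "maxrs_branch_bound",
    "BranchBoundStats",
]

#: leaf side-length floor as a fraction of the initial space's shorter side
DEFAULT_RESOLUTION_FRACTION = 2.0 ** -16


@dataclass(frozen=True)
class SearchSpace:
    """An axis-aligned interval of candidate centers."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    depth: int = 0

    def __post_init__(self) -> None:
        if self.x_lo > self.x_hi or self.y_lo > self.y_hi:
            raise ValueError("degenerate search space: lo > hi")

    @property
    def width(self) -> float:
        return self.x_hi - self.x_lo

    @property
    def height(self) -> float:
        return self.y_hi - self.y_lo

    def is_leaf(self, resolution: float) -> bool:
        return max(self.width, self.height) <= resolution


@dataclass(frozen=True)
class BoundPair:
    """Upper (+J) and lower (-J) weight bounds for a subspace."""

    upper: float
    lower: float

    def __post_init__(self) -> None:
        if self.upper < self.lower:
            raise ValueError("upper bound below lower bound")


@dataclass(frozen=True)
class ToleranceConfig:
    """User error tolerance and optional per-label bound offsets.

    ``tol`` in [0, 1): the returned weight is guaranteed to be at least
    ``(1 - tol)`` times the exact optimum.  ``per_label_offsets`` are the
    additive classifier offsets applied to both bounds when score channels
    come from margin-based models.
    """

    tol: float = 0.0
    per_label_offsets: Optional[Tuple[float, ...]] = None
    resolution: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.tol < 1.0):
            raise ValueError(f"tol must be in [0, 1), got {self.tol}")


@dataclass
class BranchBoundStats:
    """Search-effort counters (hardware-independent)."""

    nodes_expanded: int = 0
    nodes_pruned: int = 0
    leaf_evaluations: int = 0


def branch(space: SearchSpace, resolution: float = 0.0) -> Tuple[SearchSpace, SearchSpace]:
    """Split a subspace at the midpoint of its longer axis (ties split x).

    The children are disjoint up to the shared split line and union to the
    parent.  Splitting a leaf raises.
    """
    if space.is_leaf(resolution) and resolution > 0.0:
        raise ValueError("cannot branch a leaf subspace")
    d = space.depth + 1
    if space.width >= space.height:
        mid = (space.x_lo + space.x_hi) / 2.0
        return (
            SearchSpace(space.x_lo, mid, space.y_lo, space.y_hi, d),
            SearchSpace(mid, space.x_hi, space.y_lo, space.y_hi, d),
        )
    mid = (space.y_lo + space.y_hi) / 2.0
    return (
        SearchSpace(space.x_lo, space.x_hi, space.y_lo, mid, d),
        SearchSpace(space.x_lo, space.x_hi, mid, space.y_hi, d),
    )


def _bound_arrays(space, xs, ys, ws, rect, offset=0.0):
    hw, hh = rect.half_width, rect.half_height
    in_plus = (
        (xs >= space.x_lo - hw)
        & (xs <= space.x_hi + hw)
        & (ys >= space.y_lo - hh)
        & (ys <= space.y_hi + hh)
    )
    # -b is empty when the subspace is wider/taller than the rectangle
    mlo_x, mhi_x = space.x_hi - hw, space.x_lo + hw
    mlo_y, mhi_y = space.y_hi - hh, space.y_lo + hh
    if mlo_x > mhi_x or mlo_y > mhi_y:
        in_minus = np.zeros_like(in_plus)
    else:
        in_minus = (xs >= mlo_x) & (xs <= mhi_x) & (ys >= mlo_y) & (ys <= mhi_y)
    pos = ws > 0
    neg = ws < 0
    upper = ws[in_plus & pos].sum() + ws[in_minus & neg].sum() + offset
    lower = ws[in_minus & pos].sum() + ws[in_plus & neg].sum() + offset
    return float(upper), float(lower)


def bound(
    space: SearchSpace,
    points: Sequence[WeightedPoint],
    rect: RectSpec,
    cfg: ToleranceConfig = ToleranceConfig(),
) -> BoundPair:
    """Bound the best covered weight achievable by any center in ``space``."""
    _, xs, ys, ws = as_arrays(points)
    offset = 0.0
    if cfg.per_label_offsets:
        offset = float(cfg.per_label_offsets[0])
    upper, lower = _bound_arrays(space, xs, ys, ws, rect, offset)
    return BoundPair(upper=upper, lower=lower)


def _eval_candidates_in(space, cxs, cys, xs, ys, ws, rect, best):
    """Exactly evaluate every canonical candidate center inside a leaf.

    ``best`` is ``(weight, cx, cy)``; returns the updated triple and the
    number of candidate evaluations performed.
    """
    hw, hh = rect.half_width, rect.half_height
    xlo, xhi = xs - hw, xs + hw
    ylo, yhi = ys - hh, ys + hh
    ia = np.searchsorted(cxs, space.x_lo, side="left")
    ib = np.searchsorted(cxs, space.x_hi, side="right")
    ja = np.searchsorted(cys, space.y_lo, side="left")
    jb = np.searchsorted(cys, space.y_hi, side="right")
    best_w, best_x, best_y = best
    evals = 0
    for cx in cxs[ia:ib]:
        slab = (xlo <= cx) & (cx <= xhi)
        if not slab.any():
            continue
        ys_lo, ys_hi, ws_s = ylo[slab], yhi[slab], ws[slab]
        for cy in cys[ja:jb]:
            evals += 1
            w = float(ws_s[(ys_lo <= cy) & (cy <= ys_hi)].sum())
            if w > best_w or (
                w == best_w
                and best_x is not None
                and (cx, cy) < (best_x, best_y)
            ):
                best_w, best_x, best_y = w, float(cx), float(cy)
    return (best_w, best_x, best_y), evals


def maxrs_branch_bound(
    points: Sequence[WeightedPoint],
    rect: RectSpec,
    cfg: ToleranceConfig = ToleranceConfig(),
    stats: Optional[BranchBoundStats] = None,
) -> Placement:
    """Branch-and-bound MaxRS with the (1 - tol) quality guarantee."""
    ids, xs, ys, ws = as_arrays(points)
    if xs.size == 0:
        return Placement.null()
    hw, hh = rect.half_width, rect.half_height
    root = SearchSpace(
        float(xs.min() - hw),
        float(xs.max() + hw),
        float(ys.min() - hh),
        float(ys.max() + hh),
    )
    resolution = cfg.resolution
    if resolution is None:
        resolution = max(
            min(root.width, root.height) * DEFAULT_RESOLUTION_FRACTION,
            np.finfo(np.float64).tiny,
        )
    keep = 1.0 - cfg.tol
    offset = float(cfg.per_label_offsets[0]) if cfg.per_label_offsets else 0.0
    cxs = _candidate_axis(xs, hw)
    cys = _candidate_axis(ys, hh)
    if stats is None:
        stats = BranchBoundStats()

    best_w, best_x, best_y = 0.0, None, None

    def n_candidates(space: SearchSpace) -> int:
        # the optimum always sits on the canonical candidate grid, so a
        # subspace matters only through the candidates it contains
        nx = np.searchsorted(cxs, space.x_hi, side="right") - np.searchsorted(
            cxs, space.x_lo, side="left"
        )
        ny = np.searchsorted(cys, space.y_hi, side="right") - np.searchsorted(
            cys, space.y_lo, side="left"
        )
        return int(nx) * int(ny)

    leaf_candidate_cap = 32  # evaluate directly below this many candidates

    heap = []
    counter = 0
    up0, _ = _bound_arrays(root, xs, ys, ws, rect, offset)
    heapq.heappush(heap, (-up0, counter, root))
    while heap:
        neg_up, _, space = heapq.heappop(heap)
        upper = -neg_up
        if upper * keep <= best_w:
            stats.nodes_pruned += 1
            # best-first order: nothing later on the heap can do better
            break
        stats.nodes_expanded += 1
        # probe the candidate nearest the node center for an early incumbent
        px = cxs[min(np.searchsorted(cxs, (space.x_lo + space.x_hi) / 2.0), cxs.size - 1)]
        py = cys[min(np.searchsorted(cys, (space.y_lo + space.y_hi) / 2.0), cys.size - 1)]
        w_probe = float(ws[_covered_mask(xs, ys, px, py, hw, hh)].sum())
        if w_probe > best_w:
            best_w, best_x, best_y = w_probe, float(px), float(py)
        if space.is_leaf(resolution) or n_candidates(space) <= leaf_candidate_cap:
            stats.leaf_evaluations += 1
            (best_w, best_x, best_y), _ = _eval_candidates_in(
                space, cxs, cys, xs, ys, ws, rect, (best_w, best_x, best_y)
            )
            continue
        for child in branch(space):
            if n_candidates(child) == 0:
                continue
            up, _ = _bound_arrays(child, xs, ys, ws, rect, offset)
            if up * keep <= best_w:
                stats.nodes_pruned += 1
                continue
            counter += 1
            heapq.heappush(heap, (-up, counter, child))

    if best_x is None:
        return Placement.null()
    mask = _covered_mask(xs, ys, best_x, best_y, hw, hh)
    return Placement(
        best_x,
        best_y,
        float(ws[mask].sum()),
        frozenset(ids[i] for i in np.nonzero(mask)[0]),
    )
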