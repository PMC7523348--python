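# Methods

## Problem and model

The package monitors a GPS-logged mobile subject (in the motivating
epidemiological setting, an asymptomatic patient moving through a community)
and continuously reports their *stay place* (SP).  The pipeline has three
stages:

1. **Stay extraction.** Raw WGS84 fixes are projected to local planar meters
   and scanned for stays: maximal runs of fixes within `dist_thresh` of the
   run's first fix (the anchor) lasting at least `time_thresh`.  Each stay is
   summarized by its centroid and dwell time and classified SPL (one
   effective spot) or MPL (several nearby sub-spots) by the spatial span of
   its member fixes.  Stays become weighted points of interest (POIs), with
   unit or dwell-proportional weights.
2. **Maximizing range-sum (MaxRS).** Given weighted POIs `p(i) = {x, y, w}`
   and a fixed-size axis-aligned rectangle `r` (default 1000 x 1000 m), find
   the placement maximizing the covered weight `Σ_{p in r} w(p)`.  The SP is
   the weight-weighted centroid of the covered points.
3. **Continuous monitoring.** Over a sliding window of streaming POIs, the
   best placement and the greedy-disjoint top-k list are maintained
   incrementally, with SP events emitted whenever the answer changes.

## Exact solvers and the candidate grid

The exact solvers use the dual transform: each point becomes a rectangle of
the query's dimensions centered on it, and a center covers the point iff it
lies in that dual rectangle (closed on all four edges, so touching counts).
The optimum is a maximum-weight stabbing point of the dual arrangement,
found by an x-sweep with a range-add/range-max segment tree over compressed
y-coordinates (O(n log n)); the brute-force oracle evaluates every candidate
center directly.

With mixed-sign weights the textbook candidate set — centers putting a point
on the rectangle's left/bottom edge — is incomplete: two negative dual
rectangles can bracket an optimal *open* interval touched by no point
boundary.  Both solvers therefore share one canonical per-axis grid: all
dual-edge coordinates `x_i ± w/2` plus the midpoint of each consecutive
pair.  The covered weight is piecewise constant between edges, so this grid
always contains an optimum, and sharing it makes the lexicographic tie-break
(smallest `(center_x, center_y)`, then smallest label) identical across
solvers.  Empty or all-nonpositive input yields the *null placement* with
weight 0 — covering nothing is always feasible for an argmax over the plane.

Numerical policy: inside the solvers, membership is evaluated in the dual
form (`x − w/2 ≤ c ≤ x + w/2`) on the same float arrays the sweep events are
built from, so the tree value, the reported covered set, and the oracle are
mutually consistent; the reported `weight_sum` is recomputed as one
vectorized sum over the covered mask.  Solver-vs-solver tests use integer
coordinates (exact in binary floating point); real-weight comparisons use a
1e-9 relative tolerance.

## Branch and bound

The approximate solver searches subspaces of candidate centers best-first by
upper bound.  For subspace `d`, the `+b` region (subspace expanded by the
rectangle half-extents) contains everything any center in `d` could cover,
and the `-b` region (subspace shrunk by the same margins) is covered by
every center.  Bounds: upper = positive weights in `+b` plus negative in
`-b`; lower = positive in `-b` plus negative in `+b`, giving
`lower ≤ best-in-d ≤ upper`.  Optional per-label offsets shift both bounds
when score channels come from margin-based classifiers.  A subspace is
pruned when `upper(d) · (1 − tol) ≤ best_found`, which yields the guarantee
`w0 ≥ (1 − tol) · w_opt`; at `tol = 0` the search is exact.

Branching splits the longer axis at its midpoint (ties split x).  Because
an optimum always lies on the canonical candidate grid, a node containing
at most 32 grid candidates is finished by evaluating them all exactly, and
candidate-free nodes are discarded; a geometric resolution floor
(`min-side / 2^16` of the initial space, configurable) is kept as a backstop
for degenerate inputs.  Each expanded node also probes the candidate nearest
its center, so a strong incumbent exists long before the first leaf.

## Grid + overlap-graph index

Live POIs are vertices carrying their dual rectangles; edges join
overlapping duals and are oriented old → new by insertion order.  A uniform
grid (cell size = rectangle size by default) localizes updates: a vertex
registers in every cell its dual intersects (at most 4 cells at the default
size), and an insertion tests overlap only against residents of those cells,
never the whole vertex set.  Expiry removes the vertex, its registrations,
and all incident edges — a covering computation must never count expired
points, so edges do not outlive their endpoints.  All work is metered in
`op_counters` (overlap tests, exact-weight evaluations); complexity claims
are audited on these counters, never wall clocks.

Each vertex has one *home* cell (the cell containing the point), and each
cell keeps the positive-weight sum of its home residents.  A placement
centered in cell `c` can only cover points whose home cell lies in `c`'s
3x3 neighborhood (for the default cell size), so the neighborhood sum is an
admissible upper bound for pruning cells that cannot beat an incumbent.

## Continuous monitoring

The per-tick contract is *step-wise exactness*: after expiries and arrivals,
the stored top-k must equal a from-scratch greedy solve (solve MaxRS, remove
covered points, repeat up to k times; stop at weight 0) on the live window.
Greedy-disjoint extraction makes the k answers and the k-th weight threshold
well defined.

Two mechanisms avoid full recomputation without breaking the contract:

* **Fast path.** If no expired or departed point was covered by any top-k
  placement, the list is full, and every arrival's cell-neighborhood bound
  is strictly below the k-th weight threshold, then no placement at or above
  the threshold can have changed (any placement covering an arrival is
  bounded by that arrival's neighborhood sum), so the top-k stands.  The
  strict inequality means ties cannot sneak past the guard.
* **Pruned re-solve.** Otherwise each greedy rank re-evaluates the previous
  placement at that rank as an incumbent lower bound, prunes cells whose
  neighborhood bound is *clearly below* it, and sweeps only points homed in
  or adjacent to surviving cells.  Pruning uses a strict comparison with a
  1e-9 relative epsilon: a cell whose bound merely *equals* the incumbent
  (up to summation-order rounding) is never pruned, so equal-weight optima
  — and therefore tie-breaks — resolve exactly as in the from-scratch
  solve.  Since any placement at least as good as the incumbent lies in a
  surviving cell and covers only subset points, the restricted sweep returns
  the exact optimum of the remaining live points.

SP events: one `SP_NEW`/`SP_OBSOLETE` pair whenever the best placement's
covered set changes or its centroid moves by more than 1e-9; the history
retains obsolete SPs.  The window is time-based (`t_expire` per point, set
to one window length by the generators) with explicit departures supported
for replay.

## Synthetic study conditions

The generator emulates densely logged GeoLife-like data so no download is
ever needed:

* trajectories alternate dwells (Gaussian jitter around a hotspot,
  exponential dwell times) with constant-speed straight transits, sampled
  every 1–5 s; altitude is never synthesized because the analysis discards
  it.  `hotspot_sd` defaults to 10 m — a typical consumer-GPS noise scale,
  comfortably inside the 200 m stay radius;
* streams deliver `arrival_rate` (default m = 100) weighted points per tick,
  weights uniform in (0, 1000], lifetimes equal to the monitoring window;
  coordinates are planar meters over a 5 km community, optionally rescaled
  to [0, 1e8] to mirror normalized preprocessing.  Positions are clipped to
  the domain (the monitored community is bounded);
* `planted_optimum` injects a truncated-Gaussian hotspot of exactly known
  total weight inside a known rectangle of the query's dimensions, so
  recovery experiments have countable ground truth.  Recovery experiments
  use the `background="uniform"` mode, which makes "background density per
  rectangle area" well defined; the default hotspot-mixture background can
  concentrate arbitrary mass in one neighborhood and is the harder, realistic
  setting.

What the generator does *not* emulate: road networks, GPS outages and
multipath bursts, heteroscedastic urban noise, correlated multi-user
traces.  Passing tests therefore demonstrate algorithmic correctness under
idealized mobility, not robustness to real-world GPS pathologies.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| rectangle | 1000 x 1000 m | monitored neighborhood size |
| `dist_thresh` | 200 m | stay-run radius around the anchor fix |
| `time_thresh` | 20 min | minimum dwell for a stay |
| `span_thresh` | 50 m | SPL/MPL member-span boundary |
| `tol` | 0 | approximation slack, `w0 ≥ (1 − tol) w_opt` |
| k | 1 | disjoint top placements maintained |
| window | 5 ticks | stream lifetime of a POI |
| m | 100 /tick | stream generation rate |

The stay thresholds are configurable because "a long time at one spot" is a
study-design choice, not a constant of nature; the defaults are common GPS
stay-point practice.

## Problem sizes used in tests

Solver-equivalence and guarantee audits run hundreds of instances at
n ≤ 60, where the brute-force oracle is fast and exhaustive.  The streaming
audit runs 1,000 ticks at the study defaults (m = 100/tick, 5-tick window,
about 500 live points, d = 1000 m, k = 10) with a from-scratch shadow solve
every tick.  Complexity trends sweep live n over {100, 250, 500, 750, 1000}
by holding m = 50 and varying the window, fitting log-log slopes of per-tick
counters.  Planted-hotspot recovery uses 100 seeded runs of 7 ticks at
m = 30.  These sizes make the full pipeline auditable end to end while the
counters — not wall clocks — carry the complexity claims.

## Known limitations

* The equirectangular projection is city-scale; continental trajectories
  need a proper geodesic treatment.
* Greedy-disjoint top-k is one reasonable semantics; overlapping-top-k or
  diversity-constrained variants would need a different threshold argument.
* Per-label partial scores are accepted as input; training the classifiers
  that would produce them is out of scope.
* The fast-path guard is conservative: it re-solves whenever an arrival
  *could* matter, trading some speed for the exactness contract.
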