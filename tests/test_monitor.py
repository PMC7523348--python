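"""Continuous monitoring: step-wise exactness, top-k, fast path, SP events."""

import math

import numpy as np
import pytest

from staymax import (
    Monitor,
    RectSpec,
    SimConfig,
    Tick,
    WeightedPoint,
    current_stay_place,
    generate_stream,
    maxrs_bruteforce,
    maxrs_planesweep,
    step,
    topk_solve,
)

from conftest import allpairs_overlap_graph, make_instance


def weights_of(placements):
    return [p.weight_sum for p in placements]


class TestTopkSolve:
    def test_k1_reduces_to_planesweep(self, rng, rect4):
        pts = make_instance(rng, 30, weight_lo=1, weight_hi=9)
        assert topk_solve(pts, rect4, 1)[0].weight_sum == (
            maxrs_planesweep(pts, rect4).weight_sum
        )

    def test_two_separated_clusters(self, rect4):
        pts = [
            WeightedPoint(0, 0, 0, 6.0),
            WeightedPoint(1, 1, 0, 4.0),
            WeightedPoint(2, 100, 100, 6.0),
        ]
        got = weights_of(topk_solve(pts, rect4, 2))
        assert got == [10.0, 6.0]

    def test_matches_bruteforce_with_removal(self, rng, rect4):
        for _ in range(10):
            pts = make_instance(rng, 30, weight_lo=0, weight_hi=9)
            got = weights_of(topk_solve(pts, rect4, 5))
            remaining = list(pts)
            want = []
            for _ in range(5):
                best = maxrs_bruteforce(remaining, rect4)
                if best.is_null or best.weight_sum <= 0:
                    break
                want.append(best.weight_sum)
                remaining = [p for p in remaining if p.id not in best.covered_ids]
            assert got == want

    def test_weights_non_increasing(self, rng, rect4):
        pts = make_instance(rng, 40, weight_lo=0, weight_hi=9)
        got = weights_of(topk_solve(pts, rect4, 6))
        assert all(a >= b for a, b in zip(got, got[1:]))

    def test_k_below_one_rejected(self, rect4):
        with pytest.raises(ValueError):
            topk_solve([], rect4, 0)


class TestStep:
    def test_empty_window_empty_tick(self, rect1000):
        mon = Monitor(rect1000, k=2)
        events = mon.step(Tick(timestamp=0.0))
        assert events == [] and mon.state.best is None

    def test_additive_arrival_inside_best(self, rect1000):
        mon = Monitor(rect1000, k=1)
        mon.step(
            Tick(0.0, arrivals=(
                WeightedPoint(0, 100.0, 100.0, 10.0, 0.0, math.inf),
                WeightedPoint(1, 200.0, 100.0, 7.0, 0.0, math.inf),
            ))
        )
        before = mon.state.best.weight_sum
        mon.step(
            Tick(1.0, arrivals=(
                WeightedPoint(2, 150.0, 100.0, 5.0, 1.0, math.inf),
            ))
        )
        assert mon.state.best.weight_sum == before + 5.0

    def test_time_regression_rejected(self, rect1000):
        mon = Monitor(rect1000)
        mon.step(Tick(5.0))
        with pytest.raises(ValueError, match="regression"):
            mon.step(Tick(4.0))

    def test_stepwise_oracle_equivalence(self, rect1000):
        # the binding contract: after every tick the top-k weights equal a
        # from-scratch greedy solve, and the graph equals an all-pairs rebuild
        cfg = SimConfig(seed=11, arrival_rate=20, window_ticks=4, domain_size=4000.0)
        stream = generate_stream(cfg, 120)
        mon = Monitor(rect1000, k=3)
        for i, tk in enumerate(stream):
            mon.step(tk)
            live = mon.state.index.live_points()
            want = weights_of(topk_solve(live, rect1000, 3))
            got = weights_of(mon.state.topk)
            assert got == pytest.approx(want, rel=1e-9)
            if i % 30 == 0:
                order = {p.id: mon.state.index.vertices[p.id].seq for p in live}
                assert mon.state.index.edge_set() == allpairs_overlap_graph(
                    live, rect1000, order
                )

    def test_fast_path_triggers_and_stays_exact(self, rect1000):
        rng = np.random.default_rng(5)
        mon = Monitor(rect1000, k=1)
        heavy = tuple(
            WeightedPoint(i, float(rng.uniform(0, 400)), float(rng.uniform(0, 400)),
                          100.0, 0.0, math.inf)
            for i in range(5)
        )
        mon.step(Tick(0.0, arrivals=heavy))
        for t in range(1, 30):
            # light arrivals far from the incumbent, expiring much later
            arrivals = tuple(
                WeightedPoint(
                    f"l{t}_{j}",
                    float(rng.uniform(8000, 12000)),
                    float(rng.uniform(8000, 12000)),
                    0.5,
                    float(t),
                    1e9,
                )
                for j in range(3)
            )
            mon.step(Tick(float(t), arrivals=arrivals))
            live = mon.state.index.live_points()
            want = maxrs_planesweep(live, rect1000).weight_sum
            assert mon.state.best.weight_sum == pytest.approx(want, rel=1e-9)
        assert mon.state.fast_path_ticks > 0

    def test_threshold_admissibility_shadowed(self, rect1000):
        # the fast path must never skip an update that changes the top-k
        cfg = SimConfig(seed=23, arrival_rate=10, window_ticks=6, domain_size=3000.0)
        stream = generate_stream(cfg, 80)
        mon = Monitor(rect1000, k=2)
        for tk in stream:
            mon.step(tk)
            live = mon.state.index.live_points()
            want = weights_of(topk_solve(live, rect1000, 2))
            assert weights_of(mon.state.topk) == pytest.approx(want, rel=1e-9)

    def test_explicit_departures(self, rect1000):
        mon = Monitor(rect1000, k=1)
        mon.step(Tick(0.0, arrivals=(
            WeightedPoint(0, 0.0, 0.0, 5.0, 0.0, math.inf),
            WeightedPoint(1, 10.0, 0.0, 3.0, 0.0, math.inf),
        )))
        assert mon.state.best.weight_sum == 8.0
        mon.step(Tick(1.0, departures=(0,)))
        assert mon.state.best.weight_sum == 3.0

    def test_functional_wrapper(self, rect1000):
        mon = Monitor(rect1000)
        state, events = step(mon, Tick(0.0), rect1000)
        assert state is mon.state and events == []


class TestStayPlace:
    def test_single_live_point(self, rect1000):
        mon = Monitor(rect1000)
        mon.step(Tick(0.0, arrivals=(WeightedPoint(0, 7.0, 9.0, 2.0, 0.0, math.inf),)))
        sp = current_stay_place(mon)
        assert sp.centroid == (7.0, 9.0) and sp.weight == 2.0

    def test_symmetric_pair_midpoint(self, rect1000):
        mon = Monitor(rect1000)
        mon.step(Tick(0.0, arrivals=(
            WeightedPoint(0, 0.0, 0.0, 1.0, 0.0, math.inf),
            WeightedPoint(1, 100.0, 0.0, 1.0, 0.0, math.inf),
        )))
        assert current_stay_place(mon).centroid == (50.0, 0.0)

    def test_no_live_points_rejected(self, rect1000):
        with pytest.raises(ValueError, match="no"):
            current_stay_place(Monitor(rect1000))

    def test_sp_events_mark_obsolete(self, rect1000):
        mon = Monitor(rect1000, k=1)
        e1 = mon.step(Tick(0.0, arrivals=(
            WeightedPoint(0, 0.0, 0.0, 5.0, 0.0, 2.0),
        )))
        assert [e["event"] for e in e1] == ["TOPK_CHANGE", "SP_NEW"]
        e2 = mon.step(Tick(5.0, arrivals=(
            WeightedPoint(1, 3000.0, 3000.0, 4.0, 5.0, math.inf),
        )))
        kinds = [e["event"] for e in e2]
        assert "SP_OBSOLETE" in kinds and "SP_NEW" in kinds
        assert mon.state.history[0].obsolete_at == 5.0
        assert mon.state.history[-1].centroid == (3000.0, 3000.0)

    def test_sp_tracks_drifting_hotspot(self, rect1000):
        # a hotspot of dominating weight drifts; the SP follows within the
        # rectangle half-diagonal at every tick
        rng = np.random.default_rng(3)
        mon = Monitor(rect1000, k=1)
        half_diag = math.hypot(500.0, 500.0)
        for t in range(40):
            cx = 500.0 + 100.0 * t
            hot = tuple(
                WeightedPoint(
                    f"h{t}_{j}",
                    float(cx + rng.uniform(-100, 100)),
                    float(1000 + rng.uniform(-100, 100)),
                    50.0,
                    float(t),
                    t + 3.0,
                )
                for j in range(6)
            )
            noise = tuple(
                WeightedPoint(
                    f"n{t}_{j}",
                    float(rng.uniform(0, 8000)),
                    float(rng.uniform(0, 8000)),
                    1.0,
                    float(t),
                    t + 3.0,
                )
                for j in range(10)
            )
            mon.step(Tick(float(t), arrivals=hot + noise))
            sp = current_stay_place(mon)
            assert math.hypot(sp.centroid[0] - cx, sp.centroid[1] - 1000.0) <= half_diag
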