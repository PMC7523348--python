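"""Grid + overlap-graph index: locality, rebuild equivalence, pruning."""

import math

import numpy as np
import pytest
from shapely.geometry import box

from staymax import (
    GridOverlapIndex,
    RectSpec,
    WeightedPoint,
    cell_of,
    overlap_region,
    overlaps,
)

from conftest import allpairs_overlap_graph


def random_point(rng, pid, domain=5000.0, wlo=0.0, whi=1000.0):
    return WeightedPoint(
        pid,
        float(rng.uniform(0, domain)),
        float(rng.uniform(0, domain)),
        float(whi - rng.uniform(0, whi - wlo)),
    )


class TestCellOf:
    def test_origin(self):
        assert cell_of(0.0, 0.0, 1000.0, 1000.0) == (0, 0)

    def test_half_open_boundary(self):
        assert cell_of(999.999, 1000.0, 1000.0, 1000.0) == (0, 1)

    def test_negative_floor(self):
        assert cell_of(-1.0, -1.0, 1000.0, 1000.0) == (-1, -1)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            cell_of(math.inf, 0.0, 1000.0, 1000.0)


class TestOverlaps:
    def test_touching_edges_overlap(self):
        assert overlaps((0, 2, 0, 2), (2, 4, 0, 2))
        assert overlap_region((0, 2, 0, 2), (2, 4, 0, 2)) == (2, 2, 0, 2)

    def test_disjoint(self):
        assert not overlaps((0, 1, 0, 1), (3, 4, 3, 4))
        assert overlap_region((0, 1, 0, 1), (3, 4, 3, 4)) is None

    def test_against_shapely(self, rng):
        for _ in range(300):
            a = sorted(rng.uniform(0, 10, 2)) + sorted(rng.uniform(0, 10, 2))
            b = sorted(rng.uniform(0, 10, 2)) + sorted(rng.uniform(0, 10, 2))
            ra = (a[0], a[1], a[2], a[3])
            rb = (b[0], b[1], b[2], b[3])
            sa = box(ra[0], ra[2], ra[1], ra[3])
            sb = box(rb[0], rb[2], rb[1], rb[3])
            assert overlaps(ra, rb) == sa.intersects(sb)
            region = overlap_region(ra, rb)
            if region is not None:
                inter = sa.intersection(sb)
                assert inter.bounds == pytest.approx(
                    (region[0], region[2], region[1], region[3])
                )


class TestInsertExpire:
    def test_insert_into_empty(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        rep = idx.insert_point(WeightedPoint(0, 10.0, 10.0, 5.0))
        assert len(idx) == 1 and idx.n_edges == 0
        assert rep.inserted == {0} and rep.new_edges == ()

    def test_nearby_insert_creates_one_edge(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(0, 100.0, 100.0, 1.0))
        rep = idx.insert_point(WeightedPoint(1, 600.0, 100.0, 1.0))
        assert rep.new_edges == ((0, 1),)
        assert idx.n_edges == 1

    def test_duplicate_id_rejected(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(0, 0.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="duplicate"):
            idx.insert_point(WeightedPoint(0, 9.0, 9.0, 1.0))

    def test_expire_inverts_insert(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(0, 10.0, 10.0, 5.0))
        idx.expire_point(0)
        assert len(idx) == 0 and idx.n_edges == 0 and not idx.cells

    def test_expire_edge_endpoint(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(0, 100.0, 100.0, 1.0))
        idx.insert_point(WeightedPoint(1, 300.0, 100.0, 1.0))
        assert idx.n_edges == 1
        idx.expire_point(0)
        assert idx.n_edges == 0 and len(idx) == 1

    def test_unknown_id_rejected(self, rect1000):
        with pytest.raises(ValueError, match="unknown"):
            GridOverlapIndex(rect1000).expire_point(42)

    def test_500_inserts_match_allpairs_rebuild(self, rng, rect1000):
        idx = GridOverlapIndex(rect1000)
        pts = [random_point(rng, i) for i in range(500)]
        for p in pts:
            idx.insert_point(p)
        order = {p.id: idx.vertices[p.id].seq for p in pts}
        assert idx.edge_set() == allpairs_overlap_graph(pts, rect1000, order)
        assert idx.op_counters["overlap_tests"] < 500 * 499 // 2

    def test_interleaved_ops_match_rebuild(self, rng, rect1000):
        idx = GridOverlapIndex(rect1000)
        live = {}
        nid = 0
        for _ in range(1000):
            if live and rng.random() < 0.45:
                pid = sorted(live)[int(rng.integers(len(live)))]
                idx.expire_point(pid)
                del live[pid]
            else:
                p = random_point(rng, nid)
                idx.insert_point(p)
                live[nid] = p
                nid += 1
        order = {pid: idx.vertices[pid].seq for pid in live}
        assert idx.edge_set() == allpairs_overlap_graph(
            list(live.values()), rect1000, order
        )

    def test_locality_with_default_cells(self, rng, rect1000):
        # with cell size = rect size a dual rectangle spans <= 4 cells
        idx = GridOverlapIndex(rect1000)
        for i in range(200):
            idx.insert_point(random_point(rng, i))
        for v in idx.vertices.values():
            assert len(v.cells) <= 4

    def test_cell_weight_conservation(self, rng, rect1000):
        idx = GridOverlapIndex(rect1000)
        live = {}
        for i in range(300):
            p = random_point(rng, i, wlo=-100.0)
            idx.insert_point(p)
            live[i] = p
        for i in range(0, 300, 3):
            idx.expire_point(i)
            del live[i]
        # each vertex counted once via its home cell
        total = sum(c.positive_weight_sum for c in idx.cells.values())
        assert total == pytest.approx(sum(max(p.weight, 0.0) for p in live.values()))
        for c in idx.cells.values():
            assert c.positive_weight_sum == pytest.approx(
                sum(max(live[pid].weight, 0.0) for pid in c.home_ids), abs=1e-9
            )

    def test_edges_point_old_to_new(self, rng, rect1000):
        idx = GridOverlapIndex(rect1000)
        for i in range(100):
            idx.insert_point(random_point(rng, i, domain=2000.0))
        for (old, new) in idx.edge_set():
            assert idx.vertices[old].seq < idx.vertices[new].seq


class TestPruning:
    def test_best_zero_prunes_nothing(self, rng, rect1000):
        idx = GridOverlapIndex(rect1000)
        for i in range(50):
            idx.insert_point(random_point(rng, i))
        assert idx.prunable_cells(0.0) == set()

    def test_isolated_light_cell_pruned(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(0, 500.0, 500.0, 5.0))
        idx.insert_point(WeightedPoint(1, 20500.0, 20500.0, 50.0))
        pruned = idx.prunable_cells(10.0)
        assert idx.vertices[0].home in pruned
        assert idx.vertices[1].home not in pruned

    def test_strict_keeps_equal_weight_cells(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(0, 500.0, 500.0, 10.0))
        assert idx.vertices[0].home in idx.prunable_cells(10.0)
        assert idx.vertices[0].home not in idx.prunable_cells(10.0, strict=True)

    def test_negative_incumbent_rejected(self, rect1000):
        with pytest.raises(ValueError):
            GridOverlapIndex(rect1000).prunable_cells(-1.0)


class TestNeighbourhoodTable:
    def test_empty(self, rect1000):
        assert GridOverlapIndex(rect1000).neighbourhood_table() == []

    def test_chain_of_three(self, rect1000):
        idx = GridOverlapIndex(rect1000)
        idx.insert_point(WeightedPoint(1, 0.0, 0.0, 1.0))
        idx.insert_point(WeightedPoint(2, 900.0, 0.0, 1.0))
        idx.insert_point(WeightedPoint(3, 1800.0, 0.0, 1.0))
        rows = idx.neighbourhood_table()
        assert rows[0] == (1, ("e1",), (2,))
        assert rows[1] == (2, ("e2",), (3,))
        assert rows[2] == (3, None, None)

    def test_seven_vertex_pattern(self, rect1000):
        # seven vertices where 1 overlaps 2 and 3 (first two edges), a chain
        # continues 2-3, 3-4, 4-5, 4-6, 6-7, and 7 is the null sink
        idx = GridOverlapIndex(rect1000)
        y = 0.0
        coords = {
            1: (0.0, 0.0),
            2: (900.0, 0.0),
            3: (450.0, 900.0),
            4: (450.0, 1850.0),
            5: (1400.0, 1850.0),
            6: (-500.0, 1850.0),
            7: (-1450.0, 1850.0),
        }
        for pid in range(1, 8):
            x, y = coords[pid]
            idx.insert_point(WeightedPoint(pid, x, y, 1.0))
        rows = {r[0]: r for r in idx.neighbourhood_table()}
        assert rows[1][1] == ("e1", "e2")
        assert rows[1][2] == (2, 3)
        assert rows[7] == (7, None, None)
        assert 4 in rows[3][2]
        assert set(rows[4][2]) == {5, 6}
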