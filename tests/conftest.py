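"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from staymax import RectSpec, WeightedPoint


def make_instance(rng, n, coord_hi=30, weight_lo=-5, weight_hi=10, integer=True):
    """A random MaxRS instance on an integer (or real) coordinate lattice.

    Integer coordinates keep every boundary comparison exact in floats, so
    solver agreement can be asserted bit-for-bit.
    """
    pts = []
    for i in range(n):
        if integer:
            x = float(rng.integers(0, coord_hi))
            y = float(rng.integers(0, coord_hi))
            w = float(rng.integers(weight_lo, weight_hi + 1))
        else:
            x = float(rng.uniform(0, coord_hi))
            y = float(rng.uniform(0, coord_hi))
            w = float(rng.uniform(weight_lo, weight_hi))
        pts.append(WeightedPoint(i, x, y, w))
    return pts


def allpairs_overlap_graph(points, rect, order):
    """Independent all-pairs overlap-graph oracle (old -> new edges).

    ``order`` maps point id -> insertion sequence number.
    """
    hw, hh = rect.half_width, rect.half_height
    edges = set()
    for a, b in itertools.combinations(points, 2):
        if abs(a.x - b.x) <= rect.width and abs(a.y - b.y) <= rect.height:
            # dual rectangles intersect iff centers are within (w, h)
            pair = (a.id, b.id) if order[a.id] < order[b.id] else (b.id, a.id)
            edges.add(pair)
    return edges


@pytest.fixture
def rect4():
    return RectSpec(4.0, 4.0)


@pytest.fixture
def rect1000():
    return RectSpec(1000.0, 1000.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
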