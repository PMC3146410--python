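import numpy as np
import pytest

from accessineq import (
    DemandBlock,
    Facility,
    RoadClass,
    RoadSegment,
    build_network,
)


@pytest.fixture
def square_segments():
    """Four segments forming a closed 1 km square loop."""
    c = [(0.0, 0.0), (1000.0, 0.0), (1000.0, 1000.0), (0.0, 1000.0)]
    return [
        RoadSegment(f"s{i}", c[i], c[(i + 1) % 4], RoadClass.OTHER) for i in range(4)
    ]


@pytest.fixture
def triangle_network():
    """3-4-5 right triangle; every edge is the same road class.

    Nodes: 0 = (0,0), 1 = (0,4000), 2 = (3000,0); the hypotenuse
    (node 1 - node 2) has length exactly 5000 m.
    """
    segs = [
        RoadSegment("leg3", (0.0, 0.0), (3000.0, 0.0), RoadClass.OTHER),
        RoadSegment("leg4", (0.0, 0.0), (0.0, 4000.0), RoadClass.OTHER),
        RoadSegment("hyp5", (3000.0, 0.0), (0.0, 4000.0), RoadClass.OTHER),
    ]
    return build_network(segs, snap_tolerance=0.0)


@pytest.fixture
def toll_vs_local_network():
    """Two parallel routes between the same endpoints.

    A 8000 m toll road (6.0 min at 80 km/h) against a 7000 m local road
    (10.5 min at 40 km/h): the faster route is the longer one.
    """
    segs = [
        RoadSegment("toll_a", (0.0, 0.0), (4000.0, 1000.0), RoadClass.TOLL, length_m=4000.0),
        RoadSegment("toll_b", (4000.0, 1000.0), (7000.0, 0.0), RoadClass.TOLL, length_m=4000.0),
        RoadSegment("loc_a", (0.0, 0.0), (3500.0, -500.0), RoadClass.OTHER, length_m=3500.0),
        RoadSegment("loc_b", (3500.0, -500.0), (7000.0, 0.0), RoadClass.OTHER, length_m=3500.0),
    ]
    return build_network(segs, snap_tolerance=0.0)


@pytest.fixture
def line_network():
    """Ten collinear nodes 1 km apart (a simple corridor)."""
    segs = [
        RoadSegment(f"e{i}", (i * 1000.0, 0.0), ((i + 1) * 1000.0, 0.0), RoadClass.OTHER)
        for i in range(9)
    ]
    return build_network(segs, snap_tolerance=0.0)


def weighted_mean_difference_bruteforce(x, w):
    """O(n^2) double-sum oracle for the relative mean difference."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    W = w.sum()
    num = float((np.abs(x[:, None] - x[None, :]) * (w[:, None] * w[None, :])).sum())
    return num / (W * W) / float(np.average(x, weights=w))


def make_blocks(coords, pops=None):
    pops = pops if pops is not None else [1] * len(coords)
    return [
        DemandBlock(f"B{i}", (float(x), float(y)), float(p))
        for i, ((x, y), p) in enumerate(zip(coords, pops))
    ]


def make_facilities(coords):
    return [
        Facility(f"F{i}", (float(x), float(y))) for i, (x, y) in enumerate(coords)
    ]
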