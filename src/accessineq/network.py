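"""Routable road networks with a road-class speed model.

A road network is built from class-attributed line segments in a planar
projected coordinate system (meters).  Travel speed depends only on the
road class of each segment: 80 km/h on toll roads, 60 km/h on national or
principal local roads, and 40 km/h on all other roads (legal speed limits
for car travel).  Shortest paths can be weighted either by network
distance or by travel time; both totals are reported for the chosen path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .errors import InputError, UnreachableError

logger = logging.getLogger(__name__)

Coord = tuple[float, float]


class RoadClass(str, Enum):
    """Road classification driving the speed model."""

    TOLL = "toll"
    NATIONAL_OR_PRINCIPAL = "national_or_principal"
    OTHER = "other"


#: Legal speed limits by road class, km/h.
DEFAULT_SPEEDS_KMH: dict[RoadClass, float] = {
    RoadClass.TOLL: 80.0,
    RoadClass.NATIONAL_OR_PRINCIPAL: 60.0,
    RoadClass.OTHER: 40.0,
}


@dataclass(frozen=True)
class SpeedTable:
    """Mapping road class -> speed in km/h; all speeds must be positive."""

    speeds: dict[RoadClass, float] = field(
        default_factory=lambda: dict(DEFAULT_SPEEDS_KMH)
    )

    def __post_init__(self) -> None:
        for cls in RoadClass:
            if cls not in self.speeds:
                raise InputError(f"speed table is missing road class {cls.value!r}")
        for cls, v in self.speeds.items():
            if not (v > 0) or not math.isfinite(v):
                raise InputError(
                    f"speed for road class {RoadClass(cls).value!r} must be a "
                    f"positive finite number, got {v!r}"
                )

    def speed(self, road_class: RoadClass | str) -> float:
        return self.speeds[RoadClass(road_class)]

    def scaled(self, factor: float) -> "SpeedTable":
        """Return a copy with every speed multiplied by ``factor``."""
        if not factor > 0:
            raise InputError("speed scale factor must be positive")
        return SpeedTable({c: v * factor for c, v in self.speeds.items()})


@dataclass(frozen=True)
class RoadSegment:
    """One undirected road segment between two planar endpoints (meters).

    ``length_m`` defaults to the Euclidean endpoint distance; an explicit
    length may exceed it (curved roads digitized as chords).
    """

    segment_id: str
    a: Coord
    b: Coord
    road_class: RoadClass = RoadClass.OTHER
    length_m: float | None = None

    def __post_init__(self) -> None:
        for p in (self.a, self.b):
            if not all(math.isfinite(c) for c in p):
                raise InputError(
                    f"segment {self.segment_id!r} has non-finite coordinates {p}"
                )
        if self.a == self.b:
            raise InputError(f"segment {self.segment_id!r} has identical endpoints")
        object.__setattr__(self, "road_class", RoadClass(self.road_class))
        if self.length_m is None:
            object.__setattr__(self, "length_m", euclidean(self.a, self.b))
        if not (self.length_m > 0) or not math.isfinite(self.length_m):
            raise InputError(
                f"segment {self.segment_id!r} length must be positive, "
                f"got {self.length_m!r}"
            )


def euclidean(a: Coord, b: Coord) -> float:
    return math.hypot(a[0] - b[0], a[1] - b[1])


def segment_travel_time(length_m: float, speed_kmh: float) -> float:
    """Travel time in minutes along a segment of ``length_m`` meters.

    time [min] = (length [km] / speed [km/h]) * 60.
    A 100 m segment at 60 km/h takes 0.1 minutes (6 seconds).
    """
    if length_m < 0:
        raise InputError(f"length must be nonnegative, got {length_m}")
    if not speed_kmh > 0:
        raise InputError(f"speed must be positive, got {speed_kmh}")
    return (length_m / 1000.0) / speed_kmh * 60.0


class RoadNetwork:
    """Undirected routable graph over snapped segment endpoints.

    Nodes are integers ordered lexicographically by coordinate; each node
    carries its planar position, each edge its length in meters and road
    class.  Connected components are labelled at build time so that
    unreachable origin-destination pairs can be diagnosed cheaply.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph
        comps = sorted(nx.connected_components(graph), key=min)
        self._component: dict[int, int] = {}
        for label, comp in enumerate(comps):
            for n in comp:
                self._component[n] = label
        self.n_components = len(comps)
        ids = sorted(graph.nodes)
        self._node_ids = np.asarray(ids, dtype=np.int64)
        self._positions = np.array(
            [graph.nodes[n]["pos"] for n in ids], dtype=float
        ).reshape(-1, 2)
        self._tree = cKDTree(self._positions) if len(ids) else None

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_position(self, node: int) -> Coord:
        return tuple(self.graph.nodes[node]["pos"])

    def component_of(self, node: int) -> int:
        return self._component[node]

    def nodes(self) -> list[int]:
        return list(self._node_ids)

    @property
    def positions(self) -> np.ndarray:
        """(n_nodes, 2) array of node coordinates, row i = node id i."""
        return self._positions


def build_network(
    segments: Sequence[RoadSegment], snap_tolerance: float = 0.5
) -> RoadNetwork:
    """Assemble a :class:`RoadNetwork`, merging endpoints within tolerance.

    Endpoints closer than ``snap_tolerance`` meters are collapsed to a
    single node (union-find over close pairs); the merged node takes the
    lexicographically smallest coordinate of its cluster, so construction
    is deterministic.  Segments whose two endpoints merge into the same
    node are dropped, and of parallel duplicate edges the shortest is kept.
    """
    segments = list(segments)
    if not segments:
        raise InputError("cannot build a network from an empty segment list")
    if snap_tolerance < 0:
        raise InputError("snap_tolerance must be nonnegative")

    pts = np.array([c for s in segments for c in (s.a, s.b)], dtype=float)
    if not np.all(np.isfinite(pts)):
        raise InputError("segment endpoints contain non-finite coordinates")

    # Union-find over endpoints within tolerance.
    parent = list(range(len(pts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if snap_tolerance > 0:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(snap_tolerance):
            union(i, j)
    # Exactly coincident endpoints always merge, even at tolerance 0.
    seen: dict[Coord, int] = {}
    for i, p in enumerate(map(tuple, pts)):
        if p in seen:
            union(seen[p], i)
        else:
            seen[p] = i

    # Representative coordinate per cluster: lexicographic minimum.
    rep_coord: dict[int, Coord] = {}
    for i in range(len(pts)):
        r = find(i)
        c = (float(pts[i, 0]), float(pts[i, 1]))
        if r not in rep_coord or c < rep_coord[r]:
            rep_coord[r] = c

    ordered = sorted(set(rep_coord.values()))
    node_id = {c: k for k, c in enumerate(ordered)}

    g = nx.Graph()
    for c in ordered:
        g.add_node(node_id[c], pos=c)

    n_loops = 0
    for k, seg in enumerate(segments):
        u = node_id[rep_coord[find(2 * k)]]
        v = node_id[rep_coord[find(2 * k + 1)]]
        if u == v:
            n_loops += 1
            continue
        if g.has_edge(u, v) and g.edges[u, v]["length_m"] <= seg.length_m:
            continue
        g.add_edge(
            u,
            v,
            length_m=float(seg.length_m),
            road_class=seg.road_class,
            segment_id=seg.segment_id,
        )
    if n_loops:
        logger.info("dropped %d segments collapsed by endpoint snapping", n_loops)

    net = RoadNetwork(g)
    logger.info(
        "built network: %d nodes, %d edges, %d connected component(s)",
        len(net),
        net.n_edges,
        net.n_components,
    )
    return net


def _edge_weight(
    weight: str, speeds: SpeedTable
) -> Callable[[int, int, dict], float]:
    if weight == "distance":
        return lambda u, v, d: d["length_m"]
    if weight == "time":
        return lambda u, v, d: segment_travel_time(
            d["length_m"], speeds.speed(d["road_class"])
        )
    raise InputError(f"weight must be 'distance' or 'time', got {weight!r}")


def path_metrics(
    network: RoadNetwork, path: Sequence[int], speeds: SpeedTable | None = None
) -> tuple[float, float]:
    """Total (distance_km, time_min) along a node path."""
    speeds = speeds or SpeedTable()
    dist_m = 0.0
    time_min = 0.0
    for u, v in zip(path[:-1], path[1:]):
        d = network.graph.edges[u, v]
        dist_m += d["length_m"]
        time_min += segment_travel_time(d["length_m"], speeds.speed(d["road_class"]))
    return dist_m / 1000.0, time_min


def shortest_path(
    network: RoadNetwork,
    src: int,
    dst: int,
    weight: str = "distance",
    speeds: SpeedTable | None = None,
) -> tuple[list[int], float, float]:
    """Shortest path between two nodes under the chosen weight.

    Returns ``(path, distance_km, time_min)`` where both totals are
    measured along the single returned path (so a time-weighted query
    still reports the distance actually driven, and vice versa).
    """
    speeds = speeds or SpeedTable()
    for n in (src, dst):
        if n not in network.graph:
            raise InputError(f"node {n} is not in the network")
    if network.component_of(src) != network.component_of(dst):
        raise UnreachableError(
            f"nodes {src} and {dst} lie in different connected components "
            f"({network.component_of(src)} vs {network.component_of(dst)})",
            unreachable=[src, dst],
        )
    if src == dst:
        return [src], 0.0, 0.0
    wf = _edge_weight(weight, speeds)
    path = nx.dijkstra_path(network.graph, src, dst, weight=wf)
    dist_km, time_min = path_metrics(network, path, speeds)
    return path, dist_km, time_min


def snap_point(network: RoadNetwork, point: Coord) -> int:
    """Nearest network node to a planar point; ties -> lowest node id."""
    if len(network) == 0:
        raise InputError("cannot snap to an empty network")
    assert network._tree is not None
    d, idx = network._tree.query(np.asarray(point, dtype=float))
    # Resolve exact/near ties deterministically by lowest node id.
    candidates = network._tree.query_ball_point(
        np.asarray(point, dtype=float), d * (1.0 + 1e-12) + 1e-12
    )
    best = min(candidates) if candidates else int(idx)
    return int(network._node_ids[best])


def snap_points(network: RoadNetwork, points: Iterable[Coord]) -> list[int]:
    return [snap_point(network, p) for p in points]
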