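"""Nearest-facility assignment and access-time vectors.

Every demand block (a census block represented by its centroid, weighted
by its child population) is assigned to the facility that minimizes the
chosen shortest-path weight over the road network.  All facilities are
candidates regardless of region membership: a child crosses an
administrative boundary if the nearest facility lies outside.  The result
carries, per block, the nearest facility, the network distance and the
travel time, forming the weighted sample (x_i, w_i) on which the
inequality statistics are computed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import InputError, UnreachableError
from .inequality import WeightedSample
from .network import (
    Coord,
    RoadNetwork,
    SpeedTable,
    _edge_weight,
    path_metrics,
    snap_point,
)

logger = logging.getLogger(__name__)

ACCESS_COLUMNS = ["block_id", "facility_id", "distance_km", "time_min", "population"]


@dataclass(frozen=True)
class DemandBlock:
    """Block centroid with a nonnegative child-population weight."""

    block_id: str
    centroid: Coord
    population: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.centroid):
            raise InputError(f"block {self.block_id!r} has non-finite centroid")
        if not (self.population >= 0):
            raise InputError(
                f"block {self.block_id!r} population must be >= 0, "
                f"got {self.population!r}"
            )


@dataclass(frozen=True)
class Facility:
    """A care facility at a planar location.

    ``in_target_region`` is filled in by the CSR driver when facilities
    are partitioned against a region polygon; it is not an input field.
    """

    facility_id: str
    location: Coord
    in_target_region: bool | None = None

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.location):
            raise InputError(f"facility {self.facility_id!r} has non-finite location")


@dataclass
class AccessResult:
    """Per-block nearest-facility assignment.

    ``frame`` has columns block_id, facility_id, distance_km, time_min,
    population.  ``statistic`` names the column used as the access
    variable x_i downstream ("time_min" for network travel time,
    "distance_km" when running in straight-line mode).
    """

    frame: pd.DataFrame
    statistic: str = "time_min"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ACCESS_COLUMNS if c not in self.frame.columns]
        if missing:
            raise InputError(f"access table is missing columns {missing}")
        if self.statistic not in ("time_min", "distance_km"):
            raise InputError(f"unknown access statistic {self.statistic!r}")

    def sample(self) -> WeightedSample:
        """Weighted access sample; zero-population blocks are excluded."""
        mask = self.frame["population"].to_numpy(dtype=float) > 0
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("excluding %d zero-population blocks from statistics", n_dropped)
        return WeightedSample(
            values=self.frame.loc[mask, self.statistic].to_numpy(dtype=float),
            weights=self.frame.loc[mask, "population"].to_numpy(dtype=float),
        )

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, statistic: str = "time_min") -> "AccessResult":
        return cls(frame=pd.read_csv(path, float_precision="round_trip"), statistic=statistic)


def _sorted_facilities(facilities: list[Facility]) -> list[Facility]:
    return sorted(facilities, key=lambda f: str(f.facility_id))


def assign_nearest(
    network: RoadNetwork,
    blocks: list[DemandBlock],
    facilities: list[Facility],
    weight: str = "distance",
    speeds: SpeedTable | None = None,
) -> AccessResult:
    """Assign each block to its nearest facility over the road network.

    Block centroids and facilities are snapped to their nearest network
    node before routing.  The nearest facility minimizes the chosen edge
    weight ("distance" by default; "time" optional); exact ties go to the
    lowest facility id.  Blocks from which no facility is reachable raise
    :class:`UnreachableError` listing the offending block ids.
    """
    if not facilities:
        raise InputError("at least one facility is required")
    if not any(b.population > 0 for b in blocks):
        raise InputError("at least one block with population > 0 is required")
    speeds = speeds or SpeedTable()
    facs = _sorted_facilities(facilities)
    wf = _edge_weight(weight, speeds)

    fac_nodes = [snap_point(network, f.location) for f in facs]
    block_nodes = [snap_point(network, b.centroid) for b in blocks]

    # One Dijkstra per facility gives facility->node costs for every node.
    cost_maps = [
        nx.single_source_dijkstra_path_length(network.graph, fn, weight=wf)
        for fn in fac_nodes
    ]

    rows = []
    unreachable: list[str] = []
    for b, bn in zip(blocks, block_nodes):
        best_cost = math.inf
        best_i = -1
        for i, cm in enumerate(cost_maps):
            c = cm.get(bn)
            if c is not None and c < best_cost:
                best_cost = c
                best_i = i
        if best_i < 0:
            unreachable.append(b.block_id)
            continue
        fn = fac_nodes[best_i]
        if fn == bn:
            dist_km, time_min = 0.0, 0.0
        else:
            path = nx.dijkstra_path(network.graph, bn, fn, weight=wf)
            dist_km, time_min = path_metrics(network, path, speeds)
        rows.append((b.block_id, facs[best_i].facility_id, dist_km, time_min, b.population))

    if unreachable:
        raise UnreachableError(
            f"{len(unreachable)} block(s) cannot reach any facility on the "
            f"network: {unreachable[:10]}" + (" ..." if len(unreachable) > 10 else ""),
            unreachable=unreachable,
        )
    frame = pd.DataFrame(rows, columns=ACCESS_COLUMNS)
    return AccessResult(
        frame=frame,
        statistic="time_min",
        meta={"weight": weight, "metric": "network"},
    )


def assign_nearest_euclidean(
    blocks: list[DemandBlock], facilities: list[Facility]
) -> AccessResult:
    """Straight-line variant: nearest facility by Euclidean distance.

    The access statistic is the distance in kilometers (``time_min`` is
    left NaN); used for fast exploration and for the theoretical
    arrangement examples where access is defined by distance.
    """
    if not facilities:
        raise InputError("at least one facility is required")
    if not any(b.population > 0 for b in blocks):
        raise InputError("at least one block with population > 0 is required")
    facs = _sorted_facilities(facilities)
    bxy = np.array([b.centroid for b in blocks], dtype=float).reshape(-1, 2)
    fxy = np.array([f.location for f in facs], dtype=float).reshape(-1, 2)
    dm = cdist(bxy, fxy)
    # argmin returns the first (lowest-id, since sorted) minimizer on ties
    idx = dm.argmin(axis=1)
    rows = [
        (
            b.block_id,
            facs[i].facility_id,
            dm[k, i] / 1000.0,
            np.nan,
            b.population,
        )
        for k, (b, i) in enumerate(zip(blocks, idx))
    ]
    frame = pd.DataFrame(rows, columns=ACCESS_COLUMNS)
    return AccessResult(frame=frame, statistic="distance_km", meta={"metric": "euclidean"})


def mean_access_time(result: AccessResult) -> float:
    """Population-weighted mean of the access statistic.

    This is the area mean travel time in minutes: the sum of each child's
    travel time to the nearest facility divided by the total child
    population (in straight-line mode, the mean access distance in km).
    """
    return result.sample().mean
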