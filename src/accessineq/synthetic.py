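"""Self-contained synthetic study scenarios.

Generates the three ingredients every analysis needs — a grid road
network, demand blocks with skewed population weights, and a facility
layout — inside a square region, so the whole pipeline is testable
without any external geodata.  Facility arrangements mirror the
theoretical patterns used to motivate standardization:

* ``regular``   — facilities on a centered lattice, demand spread uniformly;
* ``clustered`` — facilities at Gaussian cluster centers with the demand
  drawn around them (towns with their own clinics);
* ``circular``  — demand on a ring with a single central facility, the
  ideal equidistant layout where inequality vanishes in straight-line mode;
* ``random``    — facilities drawn from CSR itself, the null layout used
  for calibration checks (mean R over replicates should be about 1).

Block populations are i.i.d. log-normal rounded up to integers >= 1,
emulating the right-skewed child counts of census blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from shapely.geometry import box

from .access import DemandBlock, Facility
from .csr import Region
from .errors import InputError
from .network import RoadClass, RoadNetwork, RoadSegment, build_network

ARRANGEMENTS = ("regular", "clustered", "circular", "random")

#: class_rule presets: every 5th grid line is a faster principal road
def principal_every_k(k: int = 5) -> Callable[[int, int, str], RoadClass]:
    def rule(i: int, j: int, orientation: str) -> RoadClass:
        line = j if orientation == "h" else i
        return RoadClass.NATIONAL_OR_PRINCIPAL if line % k == 0 else RoadClass.OTHER

    return rule


@dataclass
class ScenarioSpec:
    """Parameters of one synthetic study scenario.

    ``extent`` is the side of the square region in meters; the road grid
    has ``grid_nx`` x ``grid_ny`` nodes spanning the region.  Population
    counts are log-normal(mu, sigma) rounded to integers >= 1.
    """

    arrangement: str = "random"
    n_blocks: int = 100
    n_facilities: int = 10
    extent: float = 20000.0
    pop_mu: float = 3.0
    pop_sigma: float = 1.0
    grid_nx: int = 11
    grid_ny: int = 11
    seed: int = 0
    class_rule: Callable[[int, int, str], RoadClass] | None = None
    n_clusters: int = 3
    cluster_sd: float | None = None

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise InputError(
                f"arrangement must be one of {ARRANGEMENTS}, got {self.arrangement!r}"
            )
        if self.n_blocks < 1 or self.n_facilities < 1:
            raise InputError("n_blocks and n_facilities must be >= 1")
        if self.arrangement == "circular" and self.n_facilities != 1:
            raise InputError("circular arrangement uses exactly one central facility")
        if not self.extent > 0:
            raise InputError("extent must be positive")
        if self.pop_sigma < 0:
            raise InputError("pop_sigma must be >= 0")
        if self.grid_nx < 2 or self.grid_ny < 2:
            raise InputError("grid dimensions must be >= 2")


@dataclass
class Scenario:
    """A generated study area: region, road network, blocks, facilities."""

    region: Region
    network: RoadNetwork
    blocks: list[DemandBlock]
    facilities: list[Facility]
    spec: ScenarioSpec = field(repr=False, default=None)


def make_grid_network(
    nx_nodes: int,
    ny_nodes: int,
    spacing: float,
    class_rule: Callable[[int, int, str], RoadClass] | None = None,
) -> RoadNetwork:
    """Rectangular lattice network: nx*ny nodes, 2*nx*ny - nx - ny edges.

    ``class_rule(i, j, orientation)`` maps a segment (grid indices of its
    lower-left node, "h" or "v") to a road class; default: all "other".
    """
    if nx_nodes < 2 or ny_nodes < 2:
        raise InputError("grid dimensions must be >= 2")
    if not spacing > 0:
        raise InputError("spacing must be positive")
    rule = class_rule or (lambda i, j, o: RoadClass.OTHER)
    # shared coordinate arrays so adjacent segments meet bit-exactly
    xs = [i * spacing for i in range(nx_nodes)]
    ys = [j * spacing for j in range(ny_nodes)]
    segments: list[RoadSegment] = []
    for j in range(ny_nodes):
        for i in range(nx_nodes):
            if i + 1 < nx_nodes:
                segments.append(
                    RoadSegment(
                        f"h_{i}_{j}", (xs[i], ys[j]), (xs[i + 1], ys[j]), rule(i, j, "h")
                    )
                )
            if j + 1 < ny_nodes:
                segments.append(
                    RoadSegment(
                        f"v_{i}_{j}", (xs[i], ys[j]), (xs[i], ys[j + 1]), rule(i, j, "v")
                    )
                )
    return build_network(segments, snap_tolerance=0.0)


def _lognormal_counts(rng: np.random.Generator, n: int, mu: float, sigma: float):
    pops = np.rint(rng.lognormal(mean=mu, sigma=sigma, size=n))
    return np.maximum(pops, 1.0).astype(int)


def make_scenario(spec: ScenarioSpec) -> Scenario:
    """Generate a reproducible scenario from its spec (seeded)."""
    rng = np.random.default_rng(spec.seed)
    L = spec.extent
    region = Region(
        region_id=f"synthetic_{spec.arrangement}_{spec.seed}",
        polygon=box(0.0, 0.0, L, L),
    )
    spacing = L / (spec.grid_nx - 1) if spec.grid_nx >= spec.grid_ny else L / (
        spec.grid_ny - 1
    )
    network = make_grid_network(spec.grid_nx, spec.grid_ny, spacing, spec.class_rule)

    if spec.arrangement == "regular":
        fac_xy = _centered_lattice(spec.n_facilities, L)
        blk_xy = rng.uniform(0.0, L, size=(spec.n_blocks, 2))
    elif spec.arrangement == "clustered":
        # towns: both demand and facilities scatter around shared centers,
        # so some towns end up without a nearby facility
        sd = spec.cluster_sd if spec.cluster_sd is not None else L / 20.0
        centers = rng.uniform(0.15 * L, 0.85 * L, size=(spec.n_clusters, 2))
        bw = rng.integers(0, spec.n_clusters, size=spec.n_blocks)
        blk_xy = centers[bw] + rng.normal(0.0, sd, size=(spec.n_blocks, 2))
        blk_xy = np.clip(blk_xy, 0.0, L)
        fw = rng.integers(0, spec.n_clusters, size=spec.n_facilities)
        fac_xy = centers[fw] + rng.normal(0.0, sd, size=(spec.n_facilities, 2))
        fac_xy = np.clip(fac_xy, 0.0, L)
    elif spec.arrangement == "circular":
        center = float(round(L / 2.0))
        blk_xy = _ring_points(spec.n_blocks, center, L)
        fac_xy = np.array([[center, center]])
    else:  # random: facilities are themselves a CSR draw
        fac_xy = rng.uniform(0.0, L, size=(spec.n_facilities, 2))
        blk_xy = rng.uniform(0.0, L, size=(spec.n_blocks, 2))

    pops = _lognormal_counts(rng, spec.n_blocks, spec.pop_mu, spec.pop_sigma)
    width = len(str(spec.n_blocks))
    blocks = [
        DemandBlock(f"B{k:0{width}d}", (float(x), float(y)), int(p))
        for k, ((x, y), p) in enumerate(zip(blk_xy, pops))
    ]
    fwidth = len(str(spec.n_facilities))
    facilities = [
        Facility(f"F{k:0{fwidth}d}", (float(x), float(y)))
        for k, (x, y) in enumerate(fac_xy)
    ]
    return Scenario(
        region=region, network=network, blocks=blocks, facilities=facilities, spec=spec
    )


#: radius with many circle lattice points: 5525^2 = 5^4 * 13^2 * 17^2
_RING_RADIUS = 5525


def _ring_points(n: int, center: float, extent: float) -> np.ndarray:
    """n points exactly equidistant from (center, center).

    Uses integer lattice points on the circle x^2 + y^2 = R^2 (R chosen
    with many representations as a sum of two squares), halved as needed
    to fit the region.  Offsets, their squares and the squared distances
    are then all exact in floating point, so every point is at the *same*
    floating-point distance from the center and the D = 0 limit of the
    central-facility layout holds exactly, not just to rounding error.
    """
    sols = []
    for a in range(_RING_RADIUS + 1):
        b2 = _RING_RADIUS**2 - a * a
        b = math.isqrt(b2)
        if b * b == b2:
            sols.append((a, b))
    offsets = sorted(
        {s for a, b in sols for s in ((a, b), (-a, b), (a, -b), (-a, -b))},
        key=lambda p: math.atan2(p[1], p[0]),
    )
    scale = 1.0
    while _RING_RADIUS * scale > 0.45 * extent and scale > 2.0**-20:
        scale *= 0.5  # power-of-two scaling preserves exactness
    pts = np.array(
        [offsets[k % len(offsets)] for k in range(n)], dtype=float
    ) * scale
    return pts + center


def _centered_lattice(n: int, extent: float) -> np.ndarray:
    """First n points of a near-square lattice centered in the region."""
    rows = max(1, int(math.floor(math.sqrt(n))))
    cols = int(math.ceil(n / rows))
    xs = (np.arange(cols) + 1.0) / (cols + 1.0) * extent
    ys = (np.arange(rows) + 1.0) / (rows + 1.0) * extent
    pts = [(x, y) for y in ys for x in xs]
    return np.array(pts[:n], dtype=float)
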