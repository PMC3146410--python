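"""Monte Carlo standardization of D under complete spatial randomness.

The inequality D of access times depends on the background geography: the
same facility layout produces different D over dispersed versus clustered
demand.  To compare regions, the observed D is divided by its expectation
D_bar under complete spatial randomness (CSR) of the facilities: the
facilities inside the target region are repeatedly relocated uniformly at
random over the region polygon (their count fixed), facilities outside
the region stay put, blocks keep their positions, and D is recomputed for
the region's children each time.  D_bar is the mean of the simulated D
values pooled with the observed one (99 replicates + 1 observed = 100 by
default), and the standardized ratio is R = D / D_bar.

Because demand locations are conditioned on, relocating a *fixed* number
of facilities uniformly is the CSR process conditional on the observed
count N(A) (the binomial process); the intensity lambda = N(A)/|A| is
implied, never estimated.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .access import (
    AccessResult,
    DemandBlock,
    Facility,
    assign_nearest,
    assign_nearest_euclidean,
)
from .errors import DegenerateRegionError, InputError
from .inequality import WeightedSample, relative_mean_difference
from .network import RoadNetwork, SpeedTable

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """A planar region polygon (meters) over which facilities relocate."""

    region_id: str
    polygon: BaseGeometry

    def __post_init__(self) -> None:
        if self.polygon is None or self.polygon.is_empty:
            raise DegenerateRegionError(f"region {self.region_id!r} has empty geometry")
        if not self.polygon.is_valid:
            raise DegenerateRegionError(f"region {self.region_id!r} polygon is invalid")
        if not self.area_m2 > 0:
            raise DegenerateRegionError(f"region {self.region_id!r} has zero area")

    @property
    def area_m2(self) -> float:
        return float(self.polygon.area)

    @property
    def area_km2(self) -> float:
        return self.area_m2 / 1e6

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Closed containment test (boundary points count as inside)."""
        return shapely.intersects_xy(self.polygon, x, y)


@dataclass
class CSRConfig:
    """Settings for one CSR standardization run.

    ``n_reps`` relocation replicates (default 99, pooled with the observed
    case to average over 100 values); ``weight`` is the nearest-facility
    criterion on the network ("distance" per the default definition of
    nearest); ``metric`` chooses network routing or the fast straight-line
    mode; relocated facilities are snapped to the nearest network node
    before routing (``snap_relocated``, recorded in output metadata).
    """

    n_reps: int = 99
    seed: int = 0
    weight: str = "distance"
    metric: str = "network"
    snap_relocated: bool = True

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InputError("n_reps must be >= 1")
        if self.weight not in ("distance", "time"):
            raise InputError(f"weight must be 'distance' or 'time', got {self.weight!r}")
        if self.metric not in ("network", "euclidean"):
            raise InputError(
                f"metric must be 'network' or 'euclidean', got {self.metric!r}"
            )


@dataclass
class CSRResult:
    """Observed D, the simulated D distribution, D_bar and R for a region."""

    region_id: str
    d_observed: float
    simulated: np.ndarray
    d_bar: float
    ratio: float
    n_reps: int
    seed: int
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region_id": self.region_id,
            "d_observed": self.d_observed,
            "simulated": [float(v) for v in self.simulated],
            "d_bar": self.d_bar,
            "ratio": self.ratio,
            "n_reps": self.n_reps,
            "seed": self.seed,
            **self.meta,
        }


def sample_csr_points(region: Region, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n i.i.d. uniform points on the region polygon.

    Rejection sampling from the bounding box; returns an (n, 2) array.
    """
    if n < 0:
        raise InputError("number of points must be nonnegative")
    if n == 0:
        return np.empty((0, 2), dtype=float)
    minx, miny, maxx, maxy = region.polygon.bounds
    if not (maxx > minx and maxy > miny):
        raise DegenerateRegionError(
            f"region {region.region_id!r} has a degenerate bounding box"
        )
    # acceptance rate = area / bbox area; guard against sliver polygons
    rate = region.area_m2 / ((maxx - minx) * (maxy - miny))
    out = np.empty((n, 2), dtype=float)
    filled = 0
    while filled < n:
        m = max(int((n - filled) / max(rate, 1e-6) * 1.5), 64)
        xs = rng.uniform(minx, maxx, size=m)
        ys = rng.uniform(miny, maxy, size=m)
        ok = shapely.contains_xy(region.polygon, xs, ys)
        take = min(int(ok.sum()), n - filled)
        out[filled : filled + take, 0] = xs[ok][:take]
        out[filled : filled + take, 1] = ys[ok][:take]
        filled += take
    return out


def standardized_ratio(d_observed: float, d_bar: float) -> float:
    """R = D / D_bar, the inequality standardized for background geography."""
    if not d_bar > 0:
        raise InputError(f"D_bar must be positive, got {d_bar!r}")
    return d_observed / d_bar


def _region_rng(seed: int, region_id: str) -> np.random.Generator:
    """Independent stream per region: seed combined with a region-id hash."""
    tag = zlib.crc32(str(region_id).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


def _access_for(
    network: RoadNetwork | None,
    blocks: list[DemandBlock],
    facilities: list[Facility],
    speeds: SpeedTable,
    config: CSRConfig,
) -> AccessResult:
    if config.metric == "euclidean":
        return assign_nearest_euclidean(blocks, facilities)
    if network is None:
        raise InputError("network metric requires a road network")
    return assign_nearest(network, blocks, facilities, weight=config.weight, speeds=speeds)


def _d_of(result: AccessResult) -> float:
    return relative_mean_difference(result.sample())


def simulate_expected_D(
    network: RoadNetwork | None,
    blocks: list[DemandBlock],
    facilities: list[Facility],
    region: Region,
    speeds: SpeedTable | None = None,
    config: CSRConfig | None = None,
) -> CSRResult:
    """Estimate D_bar by CSR relocation and return the standardized ratio.

    Steps per replicate: facilities are split into inside/outside the
    region polygon; the inside ones are relocated by a uniform draw over
    the polygon (count preserved) while outside ones keep their observed
    locations; each block inside the region is assigned to its nearest
    facility among ALL facilities; D is computed over the region's blocks.
    After ``n_reps`` replicates the simulated D values are pooled with the
    observed D and averaged into D_bar; R = D_observed / D_bar.
    """
    speeds = speeds or SpeedTable()
    config = config or CSRConfig()

    fx = np.array([f.location[0] for f in facilities], dtype=float)
    fy = np.array([f.location[1] for f in facilities], dtype=float)
    inside_mask = region.contains_xy(fx, fy)
    inside = [f for f, m in zip(facilities, inside_mask) if m]
    outside = [f for f, m in zip(facilities, inside_mask) if not m]
    if not inside:
        raise InputError(
            f"region {region.region_id!r} contains no facilities to relocate"
        )

    bx = np.array([b.centroid[0] for b in blocks], dtype=float)
    by = np.array([b.centroid[1] for b in blocks], dtype=float)
    bmask = region.contains_xy(bx, by)
    blocks_in = [b for b, m in zip(blocks, bmask) if m and b.population > 0]
    if not blocks_in:
        raise InputError(f"region {region.region_id!r} contains no populated blocks")

    tagged = [
        Facility(f.facility_id, f.location, in_target_region=bool(m))
        for f, m in zip(facilities, inside_mask)
    ]
    d_obs = _d_of(_access_for(network, blocks_in, tagged, speeds, config))

    rng = _region_rng(config.seed, region.region_id)
    sims = np.empty(config.n_reps, dtype=float)
    for rep in range(config.n_reps):
        pts = sample_csr_points(region, len(inside), rng)
        relocated = [
            Facility(f.facility_id, (float(x), float(y)), in_target_region=True)
            for f, (x, y) in zip(inside, pts)
        ]
        candidates = relocated + outside
        try:
            sims[rep] = _d_of(_access_for(network, blocks_in, candidates, speeds, config))
        except Exception as exc:
            raise type(exc)(f"replicate {rep}: {exc}") from exc

    d_bar = float(np.mean(np.concatenate([sims, [d_obs]])))
    result = CSRResult(
        region_id=region.region_id,
        d_observed=float(d_obs),
        simulated=sims,
        d_bar=d_bar,
        ratio=standardized_ratio(d_obs, d_bar),
        n_reps=config.n_reps,
        seed=config.seed,
        meta={
            "weight": config.weight,
            "metric": config.metric,
            "snap_relocated": bool(config.snap_relocated and config.metric == "network"),
            "n_inside": len(inside),
            "n_outside": len(outside),
        },
    )
    logger.info(
        "region %s: D=%.4f D_bar=%.4f R=%.4f (%d reps)",
        region.region_id,
        result.d_observed,
        result.d_bar,
        result.ratio,
        config.n_reps,
    )
    return result


def rank_table(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ascending ranks by raw D and by the standardized ratio.

    Ties share the lowest rank.  Expects columns ``D`` and ``ratio``.
    """
    if df.empty:
        raise InputError("no results to rank")
    out = df.copy()
    out["rank_D"] = out["D"].rank(method="min", ascending=True).astype(int)
    out["rank_ratio"] = out["ratio"].rank(method="min", ascending=True).astype(int)
    return out


def rank_regions(results: list[CSRResult]) -> pd.DataFrame:
    """Tabulate per-region D, D_bar and R with both rank columns."""
    if not results:
        raise InputError("no results to rank")
    df = pd.DataFrame(
        {
            "region_id": [r.region_id for r in results],
            "D": [r.d_observed for r in results],
            "D_bar": [r.d_bar for r in results],
            "ratio": [r.ratio for r in results],
        }
    )
    return rank_table(df)
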