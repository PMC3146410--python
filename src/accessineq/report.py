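"""End-to-end pipeline driver and summary tables.

``run_analysis`` reads blocks, facilities, the road network and region
polygons, computes per-region access times, the inequality D, the CSR
expectation D_bar and the standardized ratio R, and writes one summary
row per region plus a pooled whole-area row (which gets mean time and D
but no D_bar/R: standardization is defined per region).  Per-block
assignments and a full JSON sidecar (simulated D vectors, seeds,
versions) are written alongside for audit.

Quantile convention: the weighted quantiles treat a block of weight w as
w identical children and apply linear order-statistic interpolation on
that conceptually exploded sample, so integer-weighted results match the
unweighted computation on the exploded vector exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .access import AccessResult, assign_nearest, assign_nearest_euclidean, mean_access_time
from .csr import CSRConfig, CSRResult, rank_table, simulate_expected_D
from .errors import InputError
from .inequality import inequality_summary
from .io import read_blocks, read_facilities, read_network, read_regions
from .network import RoadClass, SpeedTable

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """File paths and settings for one full analysis run."""

    blocks: str
    facilities: str
    regions: str
    network: str | None = None
    out_dir: str = "."
    n_reps: int = 99
    seed: int = 0
    weight: str = "distance"
    metric: str = "network"
    snap_tolerance: float = 0.5
    speeds: SpeedTable = field(default_factory=SpeedTable)
    assume_planar: bool = False

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise InputError("n_reps must be >= 1")
        paths = [self.blocks, self.facilities, self.regions]
        if self.metric == "network":
            if self.network is None:
                raise InputError("network metric requires a road network file")
            paths.append(self.network)
        for p in paths:
            if not Path(p).exists():
                raise InputError(f"input file does not exist: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` configuration file.

    Recognized keys are the :class:`RunConfig` fields plus
    ``speed.<road_class>`` overrides in km/h.  Lines starting with ``#``
    are comments.
    """
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InputError(f"{path}: cannot parse config line {raw!r}")
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()

    speeds = dict((c, SpeedTable().speed(c)) for c in RoadClass)
    for cls in RoadClass:
        key = f"speed.{cls.value}"
        if key in kv:
            speeds[cls] = float(kv.pop(key))

    def pop(key, cast, default):
        return cast(kv.pop(key)) if key in kv else default

    cfg = RunConfig(
        blocks=kv.pop("blocks"),
        facilities=kv.pop("facilities"),
        regions=kv.pop("regions"),
        network=kv.pop("network", None),
        out_dir=pop("out_dir", str, "."),
        n_reps=pop("n_reps", int, 99),
        seed=pop("seed", int, 0),
        weight=pop("weight", str, "distance"),
        metric=pop("metric", str, "network"),
        snap_tolerance=pop("snap_tolerance", float, 0.5),
        speeds=SpeedTable(speeds),
        assume_planar=pop("assume_planar", lambda s: s.lower() in ("1", "true", "yes"), False),
    )
    if kv:
        raise InputError(f"{path}: unknown config keys {sorted(kv)}")
    return cfg


SUMMARY_COLUMNS = [
    "region_id",
    "population",
    "n_facilities",
    "pop_per_facility",
    "area_km2",
    "mean_time_min",
    "D",
    "D_bar",
    "ratio",
    "rank_D",
    "rank_ratio",
    "n_reps",
    "seed",
]


def run_analysis(config: RunConfig):
    """Run the full standardization pipeline; returns (summary, access, sidecar).

    Writes ``access.csv`` (per-block assignments over the whole study
    area), ``summary.csv`` (per-region rows + pooled TOTAL row, 3 decimal
    places) and ``sidecar.json`` (full precision, simulated D vectors)
    into ``config.out_dir``.
    """
    blocks = read_blocks(config.blocks, config.assume_planar)
    facilities = read_facilities(config.facilities, config.assume_planar)
    regions = read_regions(config.regions, config.assume_planar)
    network = None
    if config.metric == "network":
        network = read_network(
            config.network, config.snap_tolerance, assume_planar=config.assume_planar
        )
    logger.info(
        "run: %d blocks, %d facilities, %d regions, seed %d, %d reps",
        len(blocks),
        len(facilities),
        len(regions),
        config.seed,
        config.n_reps,
    )

    # pooled whole-area access + D (all blocks, all facilities)
    if config.metric == "network":
        access = assign_nearest(
            network, blocks, facilities, weight=config.weight, speeds=config.speeds
        )
    else:
        access = assign_nearest_euclidean(blocks, facilities)

    csr_cfg = CSRConfig(
        n_reps=config.n_reps,
        seed=config.seed,
        weight=config.weight,
        metric=config.metric,
    )
    results: list[CSRResult] = []
    rows = []
    for region in regions:
        res = simulate_expected_D(
            network, blocks, facilities, region, config.speeds, csr_cfg
        )
        results.append(res)
        in_blocks = [
            b
            for b in blocks
            if region.contains_xy(
                np.array([b.centroid[0]]), np.array([b.centroid[1]])
            )[0]
        ]
        fx = np.array([f.location[0] for f in facilities])
        fy = np.array([f.location[1] for f in facilities])
        n_fac = int(region.contains_xy(fx, fy).sum())
        pop = float(sum(b.population for b in in_blocks))
        if config.metric == "network":
            reg_access = assign_nearest(
                network, in_blocks, facilities, weight=config.weight, speeds=config.speeds
            )
        else:
            reg_access = assign_nearest_euclidean(in_blocks, facilities)
        rows.append(
            {
                "region_id": region.region_id,
                "population": pop,
                "n_facilities": n_fac,
                "pop_per_facility": pop / n_fac if n_fac else float("nan"),
                "area_km2": region.area_km2,
                "mean_time_min": mean_access_time(reg_access),
                "D": res.d_observed,
                "D_bar": res.d_bar,
                "ratio": res.ratio,
                "n_reps": config.n_reps,
                "seed": config.seed,
            }
        )

    summary = rank_table(pd.DataFrame(rows))

    pooled = inequality_summary(access.sample())
    n_fac_total = len(facilities)
    pop_total = float(sum(b.population for b in blocks))
    total_row = {
        "region_id": "TOTAL",
        "population": pop_total,
        "n_facilities": n_fac_total,
        "pop_per_facility": pop_total / n_fac_total,
        "area_km2": float(sum(r.area_km2 for r in regions)),
        "mean_time_min": pooled.mean,
        "D": pooled.D,
        "D_bar": np.nan,
        "ratio": np.nan,
        "rank_D": pd.NA,
        "rank_ratio": pd.NA,
        "n_reps": config.n_reps,
        "seed": config.seed,
    }
    summary = pd.concat([summary, pd.DataFrame([total_row])], ignore_index=True)
    summary = summary[SUMMARY_COLUMNS]

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    access.to_csv(out / "access.csv")
    summary.to_csv(out / "summary.csv", index=False, float_format="%.3f")
    sidecar = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "n_reps": config.n_reps,
        "weight": config.weight,
        "metric": config.metric,
        "regions": [r.to_dict() for r in results],
        "pooled": {
            "mean": pooled.mean,
            "D": pooled.D,
            "gini": pooled.gini,
            "n_effective": pooled.n_effective,
        },
    }
    (out / "sidecar.json").write_text(json.dumps(sidecar, indent=2))
    return summary, access, sidecar


# ------------------------------------------------------ weighted summary

def weighted_quantile(
    values: np.ndarray, weights: np.ndarray, q: float | np.ndarray
) -> np.ndarray:
    """Quantiles of the conceptually exploded sample (weights = counts).

    Linear interpolation between order statistics of the exploded sample
    of size N = sum(w); equals ``np.quantile`` on the exploded vector for
    integer weights.  Non-integer weights are rounded to the nearest
    count (a warning-free convenience; weights are populations here).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0 or not weights.sum() > 0:
        raise InputError("cannot compute quantiles of an empty/zero-weight sample")
    mask = weights > 0
    values, weights = values[mask], weights[mask]
    counts = np.rint(weights).astype(np.int64)
    counts = np.maximum(counts, 1)
    order = np.argsort(values, kind="stable")
    x = values[order]
    c = np.cumsum(counts[order])
    N = int(c[-1])

    def order_stat(k: np.ndarray) -> np.ndarray:  # k is 1-based
        idx = np.searchsorted(c, k, side="left")
        return x[idx]

    q = np.atleast_1d(np.asarray(q, dtype=float))
    h = (N - 1) * q  # 0-based fractional position
    lo = np.floor(h).astype(np.int64)
    frac = h - lo
    xlo = order_stat(lo + 1)
    xhi = order_stat(np.minimum(lo + 2, N))
    return xlo + frac * (xhi - xlo)


@dataclass(frozen=True)
class FiveNumberSummary:
    """Weighted box-plot summary of access times."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    minimum: float
    maximum: float
    outliers: np.ndarray

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def travel_time_summary(result: AccessResult) -> FiveNumberSummary:
    """Box-plot statistics of the access sample: median, quartiles,
    whiskers at 1.5 x IQR beyond the quartiles, and the outliers beyond
    the whiskers (weighted by population)."""
    s = result.sample()
    q1, med, q3 = weighted_quantile(s.values, s.weights, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = s.values[(s.values >= lo_fence) & (s.values <= hi_fence)]
    outliers = np.sort(s.values[(s.values < lo_fence) | (s.values > hi_fence)])
    whisker_lo = float(inside.min()) if inside.size else float(med)
    whisker_hi = float(inside.max()) if inside.size else float(med)
    return FiveNumberSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=whisker_lo,
        whisker_hi=whisker_hi,
        minimum=float(s.values.min()),
        maximum=float(s.values.max()),
        outliers=outliers,
    )
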