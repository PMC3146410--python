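"""Readers and writers for the study inputs and outputs.

Supported formats are deliberately plain: CSV tables and GeoJSON
FeatureCollections (points for blocks/facilities, LineStrings for road
segments, Polygon/MultiPolygon for regions).  All coordinates must be in
a planar projected system in meters; inputs whose coordinates all fit in
the lat/lon envelope are rejected as likely geographic, since planar
Euclidean math on degrees is meaningless at these scales.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .access import DemandBlock, Facility
from .csr import Region
from .errors import GeographicCoordinateError, InputError
from .network import RoadClass, RoadNetwork, RoadSegment, build_network

#: common vendor spellings of the three road classes
DEFAULT_CLASS_ALIASES: dict[str, RoadClass] = {
    "toll": RoadClass.TOLL,
    "toll_road": RoadClass.TOLL,
    "highway": RoadClass.TOLL,
    "national_or_principal": RoadClass.NATIONAL_OR_PRINCIPAL,
    "national": RoadClass.NATIONAL_OR_PRINCIPAL,
    "principal": RoadClass.NATIONAL_OR_PRINCIPAL,
    "other": RoadClass.OTHER,
    "local": RoadClass.OTHER,
}


def _check_planar(coords: np.ndarray, assume_planar: bool = False) -> None:
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    if coords.size == 0 or assume_planar:
        return
    if not np.all(np.isfinite(coords)):
        raise InputError("input contains non-finite coordinates")
    x, y = coords[:, 0], coords[:, 1]
    if np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0):
        raise GeographicCoordinateError(
            "all coordinates fit inside the lat/lon envelope "
            "(|x| <= 180, |y| <= 90): this looks like geographic degrees. "
            "Project the data to a planar system in meters, or pass "
            "assume_planar=True if the coordinates really are meters."
        )


def _is_geojson(path: str | Path) -> bool:
    return str(path).lower().endswith((".geojson", ".json"))


# ---------------------------------------------------------------- blocks

def read_blocks(path: str | Path, assume_planar: bool = False) -> list[DemandBlock]:
    """Blocks from CSV ``block_id,x,y,population`` or GeoJSON points."""
    if _is_geojson(path):
        feats = _load_features(path)
        blocks = [
            DemandBlock(
                block_id=str(f["properties"]["block_id"]),
                centroid=_point_coords(f),
                population=float(f["properties"]["population"]),
            )
            for f in feats
        ]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        _require_columns(df, ["block_id", "x", "y", "population"], path)
        blocks = [
            DemandBlock(str(r.block_id), (float(r.x), float(r.y)), float(r.population))
            for r in df.itertuples()
        ]
    _check_planar(np.array([b.centroid for b in blocks]), assume_planar)
    return blocks


def write_blocks_csv(blocks: Iterable[DemandBlock], path: str | Path) -> None:
    pd.DataFrame(
        [(b.block_id, b.centroid[0], b.centroid[1], b.population) for b in blocks],
        columns=["block_id", "x", "y", "population"],
    ).to_csv(path, index=False)


# ------------------------------------------------------------ facilities

def read_facilities(path: str | Path, assume_planar: bool = False) -> list[Facility]:
    """Facilities from CSV ``facility_id,x,y[,region_id]`` or GeoJSON points."""
    if _is_geojson(path):
        feats = _load_features(path)
        facs = [
            Facility(str(f["properties"]["facility_id"]), _point_coords(f))
            for f in feats
        ]
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        _require_columns(df, ["facility_id", "x", "y"], path)
        facs = [
            Facility(str(r.facility_id), (float(r.x), float(r.y)))
            for r in df.itertuples()
        ]
    _check_planar(np.array([f.location for f in facs]), assume_planar)
    return facs


def write_facilities_csv(facilities: Iterable[Facility], path: str | Path) -> None:
    pd.DataFrame(
        [(f.facility_id, f.location[0], f.location[1]) for f in facilities],
        columns=["facility_id", "x", "y"],
    ).to_csv(path, index=False)


# --------------------------------------------------------------- network

def read_network(
    path: str | Path,
    snap_tolerance: float = 0.5,
    class_aliases: dict[str, RoadClass] | None = None,
    assume_planar: bool = False,
) -> RoadNetwork:
    """Road network from GeoJSON LineStrings or an edge-list CSV.

    CSV columns: ``seg_id,ax,ay,bx,by,length_m,road_class`` (length_m may
    be empty, in which case the Euclidean endpoint distance is used).
    GeoJSON LineStrings with more than two vertices are split into their
    constituent two-point segments; the ``road_class`` property is mapped
    through the alias table.
    """
    aliases = dict(DEFAULT_CLASS_ALIASES)
    if class_aliases:
        aliases.update({k.lower(): RoadClass(v) for k, v in class_aliases.items()})

    segments: list[RoadSegment] = []
    if _is_geojson(path):
        for f in _load_features(path):
            geom = f.get("geometry") or {}
            if geom.get("type") != "LineString":
                raise InputError(
                    f"{path}: expected LineString features, got {geom.get('type')!r}"
                )
            cls = _map_class(f["properties"].get("road_class"), aliases, path)
            sid = str(f["properties"].get("seg_id", f["properties"].get("segment_id", len(segments))))
            coords = geom["coordinates"]
            for k, (a, b) in enumerate(zip(coords[:-1], coords[1:])):
                segments.append(
                    RoadSegment(f"{sid}.{k}" if len(coords) > 2 else sid,
                                (float(a[0]), float(a[1])),
                                (float(b[0]), float(b[1])),
                                cls)
                )
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        _require_columns(df, ["seg_id", "ax", "ay", "bx", "by", "road_class"], path)
        for r in df.itertuples():
            length = getattr(r, "length_m", None)
            length = None if length is None or pd.isna(length) else float(length)
            segments.append(
                RoadSegment(
                    str(r.seg_id),
                    (float(r.ax), float(r.ay)),
                    (float(r.bx), float(r.by)),
                    _map_class(r.road_class, aliases, path),
                    length_m=length,
                )
            )
    if not segments:
        raise InputError(f"{path}: no road segments found")
    _check_planar(
        np.array([c for s in segments for c in (s.a, s.b)]), assume_planar
    )
    return build_network(segments, snap_tolerance=snap_tolerance)


def write_network_csv(network: RoadNetwork, path: str | Path) -> None:
    rows = []
    for u, v, d in network.graph.edges(data=True):
        (ax, ay), (bx, by) = network.node_position(u), network.node_position(v)
        rows.append(
            (d["segment_id"], ax, ay, bx, by, d["length_m"], RoadClass(d["road_class"]).value)
        )
    pd.DataFrame(
        rows, columns=["seg_id", "ax", "ay", "bx", "by", "length_m", "road_class"]
    ).to_csv(path, index=False)


def _map_class(raw, aliases: dict[str, RoadClass], path) -> RoadClass:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        raise InputError(f"{path}: road segment missing road_class")
    key = str(raw).strip().lower()
    if key not in aliases:
        raise InputError(
            f"{path}: unknown road_class {raw!r}; known values: {sorted(aliases)}"
        )
    return aliases[key]


# --------------------------------------------------------------- regions

def read_regions(path: str | Path, assume_planar: bool = False) -> list[Region]:
    """Regions from a GeoJSON FeatureCollection of (Multi)Polygons."""
    feats = _load_features(path)
    regions = []
    for k, f in enumerate(feats):
        geom = shape(f["geometry"])
        rid = str(f.get("properties", {}).get("region_id", k))
        _check_planar(np.array(geom.bounds).reshape(2, 2), assume_planar)
        regions.append(Region(region_id=rid, polygon=geom))
    if not regions:
        raise InputError(f"{path}: no region features found")
    return regions


def write_region_geojson(region: Region, path: str | Path) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"region_id": region.region_id},
                "geometry": mapping(region.polygon),
            }
        ],
    }
    Path(path).write_text(json.dumps(fc))


# --------------------------------------------------------------- helpers

def _load_features(path: str | Path) -> list[dict]:
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection" or "features" not in data:
        raise InputError(f"{path}: not a GeoJSON FeatureCollection")
    return data["features"]


def _point_coords(feature: dict):
    geom = feature.get("geometry") or {}
    if geom.get("type") != "Point":
        raise InputError(f"expected Point geometry, got {geom.get('type')!r}")
    x, y = geom["coordinates"][:2]
    return (float(x), float(y))


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
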