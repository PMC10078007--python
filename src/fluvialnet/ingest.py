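"""Reading and writing the river, road, facility and routable layers.

Line layers are exchanged as GeoJSON FeatureCollections in WGS84 (EPSG:4326);
facility lists as CSV with columns ``facility_id, lon, lat``. Attribute names
in the routable layer are capped at 10 characters (the DBF field-name limit)
so the schema transfers unchanged to an ESRI shapefile attribute table; the
long-name to short-name map is :data:`ROUTABLE_FIELD_NAMES` and is stable.

Floats are written with 6 decimal places (sub-metre coordinate precision), so
a write/read round trip reproduces every layer to that precision.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import fields as dc_fields
from typing import Any

import pandas as pd

from .attributes import NOT_NAVIGABLE, OsmRoutableRecord
from .model import (
    Facility,
    RiverSegment,
    RoadEdge,
    ValidationError,
    validate_facilities,
    validate_river_segments,
    validate_road_edges,
)

FLOAT_DECIMALS = 6

#: canonical attribute name -> GeoJSON/DBF property name for the river layer.
#: Override (e.g. with HydroRIVERS column names) via the ``field_map``
#: argument of :func:`read_river_layer`.
DEFAULT_RIVER_FIELD_MAP = {
    "seg_id": "seg_id",
    "next_down": "next_down",
    "length_km": "length_km",
    "discharge_avg": "dis_av_cms",
    "flow_regime_class": "flow_reg",
    "stream_speed_class": "stream_cls",
}

#: convenience field map for raw HydroRIVERS + GloRiC attribute names
HYDRORIVERS_FIELD_MAP = {
    "seg_id": "HYRIV_ID",
    "next_down": "NEXT_DOWN",
    "length_km": "LENGTH_KM",
    "discharge_avg": "DIS_AV_CMS",
    "flow_regime_class": "Class_flow",
    "stream_speed_class": "Class_vel",
}

DEFAULT_ROAD_FIELD_MAP = {
    "osm_id": "osm_id",
    "fclass": "fclass",
    "name": "name",
    "oneway": "oneway",
    "maxspeed_kmh": "maxspeed",
}

#: OsmRoutableRecord field -> DBF-legal (<= 10 char) property name.
ROUTABLE_FIELD_NAMES = {
    "seg_id": "seg_id",
    "fclass": "fclass",
    "from_node": "from_node",
    "to_node": "to_node",
    "length_km": "length_km",
    "oneway": "oneway",
    "maxspeed_kmh": "maxspeed",
    "avgspeed_kmh": "avgspeed",
    "stream_speed_kmh": "stream_kmh",
    "tt_down_h": "tt_down_h",
    "tt_up_h": "tt_up_h",
    "flow_regime_class": "flow_reg",
    "discharge_avg": "discharge",
    "navigable": "navigable",
    "foot_access": "foot",
    "width_limit": "width_lim",
    "weight_limit": "weight_lim",
    "height_limit": "height_lim",
    "bridge": "bridge",
    "tunnel": "tunnel",
    "lanes": "lanes",
    "electricity": "electric",
}
assert all(len(v) <= 10 for v in ROUTABLE_FIELD_NAMES.values())
assert len(set(ROUTABLE_FIELD_NAMES.values())) == len(ROUTABLE_FIELD_NAMES)


class UnsupportedFormatError(ValueError):
    """The path extension names a format this build cannot read or write."""


def _check_geojson_path(path: str | os.PathLike) -> None:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in (".geojson", ".json"):
        raise UnsupportedFormatError(
            f"unsupported extension {ext!r}: line layers are exchanged as GeoJSON "
            "(.geojson/.json); convert shapefiles externally (e.g. ogr2ogr)"
        )


def _round(x: float) -> float:
    return round(float(x), FLOAT_DECIMALS)


def _round_coords(coords: list[tuple[float, float]]) -> list[list[float]]:
    return [[_round(lon), _round(lat)] for lon, lat in coords]


def _read_feature_collection(path: str | os.PathLike) -> list[dict]:
    _check_geojson_path(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"layer file not found: {path}")
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")
    return data.get("features", [])


def _write_feature_collection(features: list[dict], path: str | os.PathLike) -> None:
    _check_geojson_path(path)
    payload = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def _line_coords(feature: dict, owner: str) -> list[tuple[float, float]]:
    geom = feature.get("geometry") or {}
    if geom.get("type") != "LineString":
        raise ValidationError(f"{owner}: expected LineString geometry, got {geom.get('type')!r}")
    return [(float(lon), float(lat)) for lon, lat in geom["coordinates"]]


def _get_prop(props: dict, field_map: dict, key: str, owner: str) -> Any:
    name = field_map[key]
    if name not in props:
        raise ValidationError(f"{owner}: mapped field {name!r} (for {key!r}) missing")
    return props[name]


def read_river_layer(
    path: str | os.PathLike, field_map: dict[str, str] | None = None
) -> list[RiverSegment]:
    """Read and validate a river hydrography layer from GeoJSON.

    ``field_map`` maps the canonical attribute names (keys of
    :data:`DEFAULT_RIVER_FIELD_MAP`) to the property names used in the file;
    pass :data:`HYDRORIVERS_FIELD_MAP` for raw HydroRIVERS/GloRiC exports.
    Raises :class:`ValidationError` naming the offending segment on any
    invariant violation (dangling ``next_down``, linkage cycle, bad geometry).
    """
    fmap = dict(DEFAULT_RIVER_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    segments = []
    for i, feat in enumerate(_read_feature_collection(path)):
        props = feat.get("properties") or {}
        owner = f"feature {i}"
        seg = RiverSegment(
            seg_id=int(_get_prop(props, fmap, "seg_id", owner)),
            next_down=int(_get_prop(props, fmap, "next_down", owner)),
            geometry=_line_coords(feat, owner),
            length_km=float(_get_prop(props, fmap, "length_km", owner)),
            discharge_avg=float(_get_prop(props, fmap, "discharge_avg", owner)),
            flow_regime_class=_get_prop(props, fmap, "flow_regime_class", owner),
            stream_speed_class=int(_get_prop(props, fmap, "stream_speed_class", owner)),
        )
        segments.append(seg)
    validate_river_segments(segments)
    return segments


def write_river_layer(
    segments: list[RiverSegment], path: str | os.PathLike,
    field_map: dict[str, str] | None = None,
) -> None:
    fmap = dict(DEFAULT_RIVER_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    features = []
    for s in segments:
        props = {
            fmap["seg_id"]: s.seg_id,
            fmap["next_down"]: s.next_down,
            fmap["length_km"]: _round(s.length_km),
            fmap["discharge_avg"]: _round(s.discharge_avg),
            fmap["flow_regime_class"]: s.flow_regime_class,
            fmap["stream_speed_class"]: s.stream_speed_class,
        }
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "LineString", "coordinates": _round_coords(s.geometry)},
        })
    _write_feature_collection(features, path)


def read_roads_layer(path: str | os.PathLike) -> list[RoadEdge]:
    """Read a GeoFabrik-style routable road layer from GeoJSON.

    The ``oneway`` flag is normalised from either the GeoFabrik (B/F/T) or the
    raw OSM (no/yes/-1) dialect.
    """
    edges = []
    for i, feat in enumerate(_read_feature_collection(path)):
        props = feat.get("properties") or {}
        owner = f"feature {i}"
        edges.append(RoadEdge(
            osm_id=str(props.get("osm_id", i)),
            fclass=str(props.get("fclass", "unclassified")),
            geometry=_line_coords(feat, owner),
            oneway=props.get("oneway", "B"),
            maxspeed_kmh=float(props.get("maxspeed", 0) or 0),
            length_km=float(props.get("length_km", 0) or 0),
            name=str(props.get("name", "") or ""),
        ))
    validate_road_edges(edges)
    return edges


def write_roads_layer(edges: list[RoadEdge], path: str | os.PathLike) -> None:
    features = []
    for e in edges:
        features.append({
            "type": "Feature",
            "properties": {
                "osm_id": e.osm_id,
                "fclass": e.fclass,
                "name": e.name,
                "oneway": {"both": "B", "forward": "F", "reverse": "T"}[e.oneway],
                "maxspeed": _round(e.maxspeed_kmh),
                "length_km": _round(e.length_km),
            },
            "geometry": {"type": "LineString", "coordinates": _round_coords(e.geometry)},
        })
    _write_feature_collection(features, path)


def read_facilities(path: str | os.PathLike) -> list[Facility]:
    """Read a facility point list from CSV (facility_id, lon, lat)."""
    if not os.path.exists(path):
        raise FileNotFoundError(f"facility file not found: {path}")
    df = pd.read_csv(path)
    for col in ("facility_id", "lon", "lat"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    facilities = [
        Facility(str(r.facility_id), float(r.lon), float(r.lat))
        for r in df.itertuples(index=False)
    ]
    validate_facilities(facilities)
    return facilities


def write_facilities(facilities: list[Facility], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [(f.facility_id, _round(f.lon), _round(f.lat)) for f in facilities],
        columns=["facility_id", "lon", "lat"],
    ).to_csv(path, index=False)


_RECORD_FIELDS = {f.name for f in dc_fields(OsmRoutableRecord)}
assert set(ROUTABLE_FIELD_NAMES) == _RECORD_FIELDS - {"geometry"}


def write_routable_layer(records: list[OsmRoutableRecord], path: str | os.PathLike) -> None:
    """Write routable river records as GeoJSON with the DBF-safe schema.

    An infinite upstream travel time (impassable direction) is stored as JSON
    ``null`` and restored to the sentinel on read. An empty record list still
    yields a valid layer carrying the full schema in a ``schema`` member.
    """
    features = []
    for rec in records:
        props: dict[str, Any] = {}
        for long_name, short_name in ROUTABLE_FIELD_NAMES.items():
            value = getattr(rec, long_name)
            if isinstance(value, float):
                value = None if math.isinf(value) else _round(value)
            props[short_name] = value
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "LineString", "coordinates": _round_coords(rec.geometry)},
        })
    _check_geojson_path(path)
    payload = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": "urn:ogc:def:crs:OGC:1.3:CRS84"}},
        "schema": list(ROUTABLE_FIELD_NAMES.values()),
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_routable_layer(path: str | os.PathLike) -> list[OsmRoutableRecord]:
    records = []
    for i, feat in enumerate(_read_feature_collection(path)):
        props = feat.get("properties") or {}
        owner = f"feature {i}"
        kwargs: dict[str, Any] = {"geometry": _line_coords(feat, owner)}
        for long_name, short_name in ROUTABLE_FIELD_NAMES.items():
            if short_name not in props:
                raise ValidationError(f"{owner}: routable field {short_name!r} missing")
            kwargs[long_name] = props[short_name]
        if kwargs["tt_up_h"] is None:
            kwargs["tt_up_h"] = NOT_NAVIGABLE
        records.append(OsmRoutableRecord(**kwargs))
    return records
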