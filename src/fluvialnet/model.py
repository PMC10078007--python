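"""Domain types for the three input layers and their validation rules.

The river layer follows the HydroSHEDS/HydroRIVERS convention: each segment
is a polyline digitised upstream-to-downstream, carrying a unique segment id
and the id of the next segment downstream (0 at a basin outlet). Hydrological
class attributes (flow-regime variability, stream-velocity class, average
discharge) follow the GloRiC convention. Roads follow the GeoFabrik routable
shapefile schema; facilities are plain WGS84 points.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .geo import polyline_length_km

Coord = tuple[float, float]

#: accepted flow-regime variability levels, low to high seasonal variability
FLOW_REGIME_LEVELS = ("low", "medium", "high")

ONEWAY_BOTH = "both"
ONEWAY_FORWARD = "forward"
ONEWAY_REVERSE = "reverse"

# GeoFabrik uses B/F/T, raw OSM uses no/yes/-1; both dialects are accepted.
_ONEWAY_CODES = {
    "b": ONEWAY_BOTH, "no": ONEWAY_BOTH, "0": ONEWAY_BOTH, "": ONEWAY_BOTH,
    "both": ONEWAY_BOTH, "none": ONEWAY_BOTH,
    "f": ONEWAY_FORWARD, "yes": ONEWAY_FORWARD, "1": ONEWAY_FORWARD,
    "true": ONEWAY_FORWARD, "forward": ONEWAY_FORWARD,
    "t": ONEWAY_REVERSE, "-1": ONEWAY_REVERSE, "reverse": ONEWAY_REVERSE,
}


class ValidationError(ValueError):
    """A layer violated an invariant; the message names the offending ids."""


def decode_oneway(raw: object) -> str:
    """Normalise a GeoFabrik ('B'/'F'/'T') or raw OSM ('no'/'yes'/'-1') oneway flag."""
    if raw is None:
        return ONEWAY_BOTH
    key = str(raw).strip().lower()
    try:
        return _ONEWAY_CODES[key]
    except KeyError:
        raise ValidationError(f"unrecognised oneway code {raw!r}") from None


@dataclass
class RiverSegment:
    """One hydrography polyline with downstream linkage and GloRiC-style classes."""

    seg_id: int
    next_down: int  # 0 = basin outlet
    geometry: list[Coord]  # (lon, lat), digitised upstream -> downstream
    length_km: float
    discharge_avg: float  # long-term average discharge, m^3/s
    flow_regime_class: object  # source regime code; see attributes.classify_flow_regime
    stream_speed_class: int  # GloRiC velocity class (small integer)

    def __post_init__(self) -> None:
        if self.length_km is None or self.length_km <= 0:
            # HydroSHEDS ships lengths; fall back to geodesic recomputation
            self.length_km = polyline_length_km(self.geometry)


@dataclass
class RoadEdge:
    """One GeoFabrik-schema road polyline."""

    osm_id: str
    fclass: str
    geometry: list[Coord]
    oneway: str = ONEWAY_BOTH
    maxspeed_kmh: float = 0.0  # 0 = unknown
    length_km: float = 0.0
    name: str = ""

    def __post_init__(self) -> None:
        self.oneway = decode_oneway(self.oneway)
        if self.length_km is None or self.length_km <= 0:
            self.length_km = polyline_length_km(self.geometry)


@dataclass
class Facility:
    """A point of interest (e.g. a community health centre) in WGS84."""

    facility_id: str
    lon: float
    lat: float


def _check_coords(geometry: list[Coord], owner: str, errors: list[str]) -> None:
    if len(geometry) < 2:
        errors.append(f"{owner}: geometry has {len(geometry)} vertex(es), need >= 2")
        return
    for lon, lat in geometry:
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            errors.append(f"{owner}: coordinate ({lon}, {lat}) outside WGS84 range")
            return


def validate_river_segments(segments: list[RiverSegment]) -> None:
    """Check all river-layer invariants, raising ValidationError on the first batch.

    Checks: unique positive seg_id; next_down is 0 or an existing id and never
    self-referential; geometry well formed with in-range coordinates; positive
    length; non-negative discharge; and an acyclic downstream linkage (the
    network must be a forest of trees rooted at outlets).
    """
    errors: list[str] = []
    ids = [s.seg_id for s in segments]
    id_set = set(ids)
    if len(id_set) != len(ids):
        seen, dups = set(), set()
        for i in ids:
            (dups if i in seen else seen).add(i)
        errors.append(f"duplicate seg_id(s): {sorted(dups)}")
    for s in segments:
        owner = f"segment {s.seg_id}"
        if s.seg_id <= 0:
            errors.append(f"{owner}: seg_id must be positive")
        if s.next_down == s.seg_id:
            errors.append(f"{owner}: next_down points at itself")
        elif s.next_down != 0 and s.next_down not in id_set:
            errors.append(f"{owner}: dangling next_down reference {s.next_down}")
        _check_coords(s.geometry, owner, errors)
        if s.length_km <= 0:
            errors.append(f"{owner}: length_km must be > 0, got {s.length_km}")
        if s.discharge_avg < 0:
            errors.append(f"{owner}: discharge_avg must be >= 0, got {s.discharge_avg}")
    if not errors:
        for cyc in find_downstream_cycles(segments):
            errors.append(f"cycle in downstream linkage: {cyc}")
    if errors:
        raise ValidationError("; ".join(errors))


def find_downstream_cycles(segments: list[RiverSegment]) -> list[list[int]]:
    """Return every cycle in the next_down relation (each reported once)."""
    down = {s.seg_id: s.next_down for s in segments}
    state: dict[int, int] = {}  # 0 visiting, 1 done
    cycles: list[list[int]] = []
    for start in down:
        if state.get(start) == 1:
            continue
        path: list[int] = []
        cur = start
        while cur != 0 and cur in down and state.get(cur) is None:
            state[cur] = 0
            path.append(cur)
            cur = down[cur]
        if cur != 0 and cur in down and state.get(cur) == 0:
            cycles.append(path[path.index(cur):])
        for v in path:
            state[v] = 1
    return cycles


def validate_road_edges(edges: list[RoadEdge]) -> None:
    errors: list[str] = []
    for e in edges:
        owner = f"road {e.osm_id}"
        _check_coords(e.geometry, owner, errors)
        if e.maxspeed_kmh < 0:
            errors.append(f"{owner}: maxspeed_kmh must be >= 0")
        if e.length_km <= 0:
            errors.append(f"{owner}: length_km must be > 0")
    if errors:
        raise ValidationError("; ".join(errors))


def validate_facilities(facilities: list[Facility]) -> None:
    errors: list[str] = []
    ids = [f.facility_id for f in facilities]
    if len(set(ids)) != len(ids):
        errors.append("duplicate facility ids")
    for f in facilities:
        if not (-180.0 <= f.lon <= 180.0 and -90.0 <= f.lat <= 90.0):
            errors.append(f"facility {f.facility_id}: coordinate outside WGS84 range")
    if errors:
        raise ValidationError("; ".join(errors))
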