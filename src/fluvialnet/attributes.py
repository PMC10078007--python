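"""Transport attributes for river segments and OSM-schema record emission.

A river segment becomes routable once it carries: a vessel speed model, the
water stream speed for its velocity class, direction-dependent travel times
(the boat travels at boat speed plus the stream speed downstream and minus it
upstream), a navigability flag derived from a discharge filter, and the
remaining fields of the GeoFabrik routable road schema. Road-only fields
(bridge, tunnel, lanes, electricity) are kept for schema compatibility but
flagged "do not apply"; vessel size limits are unrestricted because large
Amazon-type rivers impose no practical width/weight/height constraint.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import ONEWAY_BOTH, FLOW_REGIME_LEVELS, RiverSegment, ValidationError

#: sentinel for schema fields that are meaningless for rivers
DO_NOT_APPLY = "do_not_apply"
#: sentinel for vessel size limits (no restriction applied)
UNRESTRICTED = "unrestricted"
#: sentinel travel time for an impassable direction
NOT_NAVIGABLE = math.inf

DOWNSTREAM = "downstream"
UPSTREAM = "upstream"

#: default water speed (km/h) per GloRiC-style velocity class. The directional
#: plus/minus mechanism is fixed; these magnitudes are a modelling default and
#: fully overridable via configuration.
DEFAULT_STREAM_SPEED_TABLE: dict[int, float] = {1: 0.5, 2: 1.5, 3: 3.0}

#: default mapping from source flow-regime codes to the three-level enum
DEFAULT_FLOW_REGIME_MAP: dict[object, str] = {
    1: "low", 2: "medium", 3: "high",
    "1": "low", "2": "medium", "3": "high",
    "low": "low", "medium": "medium", "high": "high",
}


@dataclass(frozen=True)
class BoatProfile:
    """Speed model for a standard motorised boat.

    The 18.52 km/h average is the navigation speed of a typical Amazon
    riverboat; 37 km/h is the ceiling reached by small boats with powerful
    engines. ``min_effective_speed_kmh`` floors the upstream speed so a strong
    current never yields a zero or negative speed (set the upstream mode to
    ``"block"`` in :func:`to_osm_records` to mark such segments impassable
    upstream instead).
    """

    avg_speed_kmh: float = 18.52
    max_speed_kmh: float = 37.0
    min_effective_speed_kmh: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_effective_speed_kmh <= self.avg_speed_kmh <= self.max_speed_kmh):
            raise ValueError(
                "require 0 < min_effective <= avg <= max, got "
                f"{self.min_effective_speed_kmh} / {self.avg_speed_kmh} / {self.max_speed_kmh}"
            )


def validate_stream_speed_table(table: dict[int, float]) -> None:
    """Water speeds must be non-negative and non-decreasing in class index."""
    if any(v < 0 for v in table.values()):
        raise ValueError("stream speeds must be >= 0")
    ordered = [table[k] for k in sorted(table)]
    if any(b < a for a, b in zip(ordered, ordered[1:])):
        raise ValueError("stream speed table must be non-decreasing in class index")


def effective_speed(profile: BoatProfile, stream_kmh: float, direction: str) -> float:
    """Boat-over-ground speed in km/h for one travel direction.

    Downstream the stream carries the boat (avg + stream); upstream it opposes
    it (avg - stream, floored at the profile's minimum effective speed).
    """
    if stream_kmh < 0:
        raise ValueError(f"stream speed must be >= 0, got {stream_kmh}")
    if direction == DOWNSTREAM:
        return profile.avg_speed_kmh + stream_kmh
    if direction == UPSTREAM:
        return max(profile.avg_speed_kmh - stream_kmh, profile.min_effective_speed_kmh)
    raise ValueError(f"direction must be 'downstream' or 'upstream', got {direction!r}")


def stream_speed_for(segment: RiverSegment, table: dict[int, float] | None = None) -> float:
    table = DEFAULT_STREAM_SPEED_TABLE if table is None else table
    try:
        return table[segment.stream_speed_class]
    except KeyError:
        raise ValidationError(
            f"segment {segment.seg_id}: stream speed class "
            f"{segment.stream_speed_class!r} not in table {sorted(table)}"
        ) from None


def segment_travel_times(
    segment: RiverSegment,
    profile: BoatProfile | None = None,
    table: dict[int, float] | None = None,
) -> tuple[float, float]:
    """(downstream, upstream) travel time in hours for one segment."""
    profile = profile or BoatProfile()
    stream = stream_speed_for(segment, table)
    tt_down = segment.length_km / effective_speed(profile, stream, DOWNSTREAM)
    tt_up = segment.length_km / effective_speed(profile, stream, UPSTREAM)
    return tt_down, tt_up


def classify_flow_regime(code: object, mapping: dict[object, str] | None = None) -> str:
    """Map a source flow-regime code to the low/medium/high variability enum."""
    mapping = DEFAULT_FLOW_REGIME_MAP if mapping is None else mapping
    try:
        level = mapping[code]
    except (KeyError, TypeError):
        raise ValidationError(f"unknown flow regime code {code!r}") from None
    if level not in FLOW_REGIME_LEVELS:
        raise ValidationError(f"flow regime map sends {code!r} to invalid level {level!r}")
    return level


def navigability_filter(
    segments: list[RiverSegment], min_discharge_cms: float
) -> list[RiverSegment]:
    """Segments whose average discharge meets the navigability threshold.

    Discharge is the practical proxy for river size: larger rivers have a
    larger chance of being navigable. Segments below the threshold are not
    deleted from the layer; record emission flags them ``navigable = False``.
    """
    if min_discharge_cms < 0:
        raise ValueError(f"min_discharge_cms must be >= 0, got {min_discharge_cms}")
    return [s for s in segments if s.discharge_avg >= min_discharge_cms]


@dataclass
class OsmRoutableRecord:
    """One river edge in the GeoFabrik routable schema plus river extensions.

    Rivers are emitted bidirectional (``oneway = both``) with asymmetric
    per-direction travel times; ``tt_up_h`` is infinite when the upstream
    direction is impassable under the "block" upstream mode.
    """

    seg_id: int
    fclass: str
    from_node: int
    to_node: int
    geometry: list[tuple[float, float]]
    length_km: float
    oneway: str
    maxspeed_kmh: float
    avgspeed_kmh: float
    stream_speed_kmh: float
    tt_down_h: float
    tt_up_h: float
    flow_regime_class: str
    discharge_avg: float
    navigable: bool
    foot_access: bool = False
    width_limit: str = UNRESTRICTED
    weight_limit: str = UNRESTRICTED
    height_limit: str = UNRESTRICTED
    bridge: str = DO_NOT_APPLY
    tunnel: str = DO_NOT_APPLY
    lanes: str = DO_NOT_APPLY
    electricity: str = DO_NOT_APPLY


def to_osm_records(
    segments: list[RiverSegment],
    incidences: dict[int, tuple[int, int]],
    profile: BoatProfile | None = None,
    table: dict[int, float] | None = None,
    regime_map: dict[object, str] | None = None,
    min_discharge_cms: float = 0.0,
    fclass: str = "waterway_river",
    upstream_mode: str = "floor",
    apply_stream_speed: bool = True,
) -> list[OsmRoutableRecord]:
    """Emit one routable record per river segment.

    ``incidences`` maps seg_id to its (from_node, to_node) junction ids as
    produced by :func:`fluvialnet.topology.build_junctions`. ``upstream_mode``
    is ``"floor"`` (upstream speed floored at the profile minimum) or
    ``"block"`` (upstream impassable when the stream meets or exceeds the boat
    speed). With ``apply_stream_speed = False`` the stream speed column is
    still emitted but travel times use the bare boat speed in both directions.
    """
    profile = profile or BoatProfile()
    if table is not None:
        validate_stream_speed_table(table)
    if upstream_mode not in ("floor", "block"):
        raise ValueError(f"upstream_mode must be 'floor' or 'block', got {upstream_mode!r}")
    navigable_ids = {s.seg_id for s in navigability_filter(segments, min_discharge_cms)}

    records = []
    for seg in segments:
        stream = stream_speed_for(seg, table)
        eff_stream = stream if apply_stream_speed else 0.0
        tt_down = seg.length_km / effective_speed(profile, eff_stream, DOWNSTREAM)
        if upstream_mode == "block" and eff_stream >= profile.avg_speed_kmh:
            tt_up = NOT_NAVIGABLE
        else:
            tt_up = seg.length_km / effective_speed(profile, eff_stream, UPSTREAM)
        from_node, to_node = incidences[seg.seg_id]
        records.append(
            OsmRoutableRecord(
                seg_id=seg.seg_id,
                fclass=fclass,
                from_node=from_node,
                to_node=to_node,
                geometry=list(seg.geometry),
                length_km=seg.length_km,
                oneway=ONEWAY_BOTH,
                maxspeed_kmh=profile.max_speed_kmh,
                avgspeed_kmh=profile.avg_speed_kmh,
                stream_speed_kmh=stream,
                tt_down_h=tt_down,
                tt_up_h=tt_up,
                flow_regime_class=classify_flow_regime(seg.flow_regime_class, regime_map),
                discharge_avg=seg.discharge_avg,
                navigable=seg.seg_id in navigable_ids,
            )
        )
    return records
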