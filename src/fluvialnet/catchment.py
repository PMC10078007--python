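"""Facility catchment areas and the three-scenario coverage comparison.

A catchment area is the part of the transport network reachable from a
facility within a travel-time threshold. The facility is first snapped to its
nearest graph node within a snapping tolerance (facilities beyond it get no
catchment — real facility registries always contain off-network points); a
single-source shortest-time pass then marks each directed edge as fully
reached (both endpoints within the threshold) or partially reached (the
leftover time budget at the entry node, as a fraction of the edge's travel
time), and the catchment polygon is the buffered union of the reached edge
geometry. Buffered reach, rather than a convex or alpha hull, avoids claiming
coverage across terrain the network never touches.

The coverage comparison rebuilds the graph under three scenarios —
roads-only, rivers-only, and combined — and counts the facilities with a
catchment under each, mirroring how adding navigable rivers to a road network
extends healthcare coverage into road-disconnected territory.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, mapping
from shapely.ops import substring, unary_union

from .attributes import OsmRoutableRecord
from .geo import haversine_km_many, meters_to_degrees
from .graph import TransportGraph, build_graph, reach_times
from .model import Facility, RoadEdge

logger = logging.getLogger(__name__)

SCENARIO_ROADS = "roads"
SCENARIO_RIVERS = "rivers"
SCENARIO_COMBINED = "combined"
SCENARIOS = (SCENARIO_ROADS, SCENARIO_RIVERS, SCENARIO_COMBINED)

DEFAULT_MAX_SNAP_M = 2000.0
DEFAULT_BUFFER_M = 250.0


@dataclass
class CatchmentResult:
    """Per-facility, per-scenario service area."""

    facility_id: str
    scenario: str
    snapped_node: str | None
    snap_distance_m: float | None
    threshold_h: float
    reached_edges: dict[tuple[str, str], float] = field(default_factory=dict)
    polygon: object = None  # shapely geometry; empty when no catchment

    @property
    def has_catchment(self) -> bool:
        return self.snapped_node is not None and bool(self.reached_edges)


@dataclass
class CoverageComparison:
    """Facility-coverage counts under the three network scenarios."""

    n_facilities: int
    n_roads: int
    n_rivers: int
    n_combined: int
    newly_covered: set[str]  # covered in combined but not in roads-only
    pct_increase: float | None  # 100 * (n_combined - n_roads) / n_roads
    results: dict[str, dict[str, CatchmentResult]] = field(default_factory=dict)


def snap_facility(
    graph: TransportGraph, facility: Facility, max_snap_m: float = DEFAULT_MAX_SNAP_M
) -> tuple[str, float] | None:
    """Nearest graph node within ``max_snap_m`` (geodesic), or None."""
    nodes = list(graph.g.nodes)
    if not nodes:
        return None
    lons = np.array([graph.g.nodes[n]["lon"] for n in nodes])
    lats = np.array([graph.g.nodes[n]["lat"] for n in nodes])
    d_m = haversine_km_many(facility.lon, facility.lat, lons, lats) * 1000.0
    j = int(np.argmin(d_m))
    if d_m[j] <= max_snap_m:
        return nodes[j], float(d_m[j])
    return None


def service_area(
    graph: TransportGraph,
    facility: Facility,
    threshold_h: float,
    max_snap_m: float = DEFAULT_MAX_SNAP_M,
    buffer_m: float = DEFAULT_BUFFER_M,
    scenario: str = SCENARIO_COMBINED,
) -> CatchmentResult:
    """Travel-time catchment of one facility on one scenario graph."""
    if threshold_h <= 0:
        raise ValueError(f"threshold_h must be > 0, got {threshold_h}")
    snap = snap_facility(graph, facility, max_snap_m)
    if snap is None:
        return CatchmentResult(facility.facility_id, scenario, None, None,
                               threshold_h, {}, _empty_polygon())
    node, dist_m = snap
    times = reach_times(graph, node)  # full pass; partial edges need entry times
    reached: dict[tuple[str, str], float] = {}
    pieces = []
    buf_deg = meters_to_degrees(buffer_m)
    for u, v, data in graph.g.edges(data=True):
        t_u = times.get(u)
        if t_u is None or t_u > threshold_h:
            continue
        t_edge = data["time_h"]
        line = LineString(data["geometry"])
        if t_u + t_edge <= threshold_h:
            frac = 1.0
            pieces.append(line)
        else:
            frac = (threshold_h - t_u) / t_edge
            if frac <= 0:
                continue
            pieces.append(substring(line, 0.0, frac, normalized=True))
        key = (u, v)
        reached[key] = max(reached.get(key, 0.0), frac)
    if not reached:
        return CatchmentResult(facility.facility_id, scenario, node, dist_m,
                               threshold_h, {}, _empty_polygon())
    poly = unary_union([p.buffer(buf_deg) for p in pieces])
    return CatchmentResult(facility.facility_id, scenario, node, dist_m,
                           threshold_h, reached, poly)


def _empty_polygon():
    return Point(0.0, 0.0).buffer(0.0)  # empty geometry


def compare_scenarios(
    river_records: list[OsmRoutableRecord] | None,
    road_edges: list[RoadEdge] | None,
    facilities: list[Facility],
    threshold_h: float,
    max_snap_m: float = DEFAULT_MAX_SNAP_M,
    buffer_m: float = DEFAULT_BUFFER_M,
    connector_tolerance_m: float | None = None,
    walk_speed_kmh: float | None = None,
    default_road_speed_kmh: float | None = None,
    scenarios: tuple[str, ...] = SCENARIOS,
) -> CoverageComparison:
    """Catchment counts under roads-only / rivers-only / combined scenarios.

    Each scenario graph is rebuilt from its own layers. ``pct_increase`` is
    the relative coverage gain of the combined network over roads alone,
    ``100 * (n_combined - n_roads) / n_roads``; it is None when no facility is
    road-covered (or the roads scenario was not run).
    """
    graph_kwargs = {}
    if connector_tolerance_m is not None:
        graph_kwargs["connector_tolerance_m"] = connector_tolerance_m
    if walk_speed_kmh is not None:
        graph_kwargs["walk_speed_kmh"] = walk_speed_kmh
    if default_road_speed_kmh is not None:
        graph_kwargs["default_road_speed_kmh"] = default_road_speed_kmh

    layer_sets = {
        SCENARIO_ROADS: dict(road_edges=road_edges),
        SCENARIO_RIVERS: dict(river_records=river_records),
        SCENARIO_COMBINED: dict(river_records=river_records, road_edges=road_edges),
    }
    results: dict[str, dict[str, CatchmentResult]] = {}
    covered: dict[str, set[str]] = {}
    for scen in scenarios:
        layers = {k: v for k, v in layer_sets[scen].items() if v}
        if not layers:
            results[scen] = {
                f.facility_id: CatchmentResult(f.facility_id, scen, None, None,
                                               threshold_h, {}, _empty_polygon())
                for f in facilities
            }
            covered[scen] = set()
            continue
        graph = build_graph(**layers, **graph_kwargs)
        res = {
            f.facility_id: service_area(graph, f, threshold_h, max_snap_m,
                                        buffer_m, scenario=scen)
            for f in facilities
        }
        results[scen] = res
        covered[scen] = {fid for fid, r in res.items() if r.has_catchment}
        logger.info("scenario %-8s: %d/%d facilities covered",
                    scen, len(covered[scen]), len(facilities))

    n_roads = len(covered.get(SCENARIO_ROADS, set()))
    n_rivers = len(covered.get(SCENARIO_RIVERS, set()))
    n_combined = len(covered.get(SCENARIO_COMBINED, set()))
    newly = covered.get(SCENARIO_COMBINED, set()) - covered.get(SCENARIO_ROADS, set())
    pct = 100.0 * (n_combined - n_roads) / n_roads if n_roads > 0 else None
    return CoverageComparison(
        n_facilities=len(facilities),
        n_roads=n_roads, n_rivers=n_rivers, n_combined=n_combined,
        newly_covered=newly, pct_increase=pct, results=results,
    )


def export_catchments_geojson(results: list[CatchmentResult], path: str) -> None:
    """One polygon feature per facility x scenario (empty ones are skipped)."""
    features = []
    for r in results:
        if not r.has_catchment:
            continue
        features.append({
            "type": "Feature",
            "properties": {
                "fac_id": r.facility_id,
                "scenario": r.scenario,
                "thresh_h": r.threshold_h,
                "snap_node": r.snapped_node,
                "snap_m": round(r.snap_distance_m, 1),
            },
            "geometry": mapping(r.polygon),
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def export_summary_csv(comparison: CoverageComparison, path: str) -> None:
    rows = []
    for scen, res in comparison.results.items():
        for fid, r in res.items():
            rows.append((fid, scen, r.has_catchment,
                         r.snapped_node or "", r.snap_distance_m))
    pd.DataFrame(rows, columns=["facility_id", "scenario", "has_catchment",
                                "snapped_node", "snap_distance_m"]).to_csv(
        path, index=False)
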