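"""Directed, travel-time-weighted multimodal transport graph.

River records contribute two directed edges per segment (downstream and
upstream travel time, asymmetric whenever the stream speed is positive);
roads contribute edges weighted by length over speed, honouring one-way
flags; and walking connector edges couple each road node to its nearest
river node within a tolerance, symmetric by construction. Scenario graphs
(roads-only, rivers-only, combined) are built independently rather than by
masking a master graph, so each scenario is reproducible in isolation.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .attributes import OsmRoutableRecord
from .geo import haversine_km, meters_to_degrees
from .model import ONEWAY_BOTH, ONEWAY_FORWARD, ONEWAY_REVERSE, RoadEdge

logger = logging.getLogger(__name__)

UNREACHABLE = math.inf

MODE_RIVER = "river"
MODE_ROAD = "road"
MODE_CONNECTOR = "connector"

DEFAULT_CONNECTOR_TOLERANCE_M = 500.0
DEFAULT_WALK_SPEED_KMH = 5.0
DEFAULT_ROAD_SPEED_KMH = 40.0

# node-merge grid for road endpoints (same trick as junction clustering)
_ROAD_SNAP_M = 1.0


@dataclass
class TransportGraph:
    """A directed multimodal graph; ``g`` is the underlying networkx DiGraph.

    Node attributes: ``lon``, ``lat``, ``mode``. Edge attributes: ``time_h``
    (the routing weight), ``length_km``, ``mode`` and ``ref`` (source segment
    or OSM id). River nodes are named ``r<junction id>``, road nodes ``w<i>``.
    """

    g: nx.DiGraph
    n_connectors: int = 0

    def node_coord(self, node: str) -> tuple[float, float]:
        d = self.g.nodes[node]
        return d["lon"], d["lat"]

    def nodes_by_mode(self, mode: str) -> list[str]:
        return [n for n, d in self.g.nodes(data=True) if d["mode"] == mode]


def _add_river_edges(g: nx.DiGraph, records: list[OsmRoutableRecord]) -> None:
    for rec in records:
        if not rec.navigable:
            continue
        u, v = f"r{rec.from_node}", f"r{rec.to_node}"
        up, down = rec.geometry[0], rec.geometry[-1]
        g.add_node(u, lon=up[0], lat=up[1], mode=MODE_RIVER)
        g.add_node(v, lon=down[0], lat=down[1], mode=MODE_RIVER)
        g.add_edge(u, v, time_h=rec.tt_down_h, length_km=rec.length_km,
                   mode=MODE_RIVER, ref=rec.seg_id, geometry=list(rec.geometry))
        if math.isfinite(rec.tt_up_h):
            g.add_edge(v, u, time_h=rec.tt_up_h, length_km=rec.length_km,
                       mode=MODE_RIVER, ref=rec.seg_id,
                       geometry=list(reversed(rec.geometry)))


def _add_road_edges(g: nx.DiGraph, edges: list[RoadEdge], default_speed: float) -> None:
    cell = meters_to_degrees(_ROAD_SNAP_M)
    key_of: dict[tuple[int, int], str] = {}

    def node_for(coord: tuple[float, float]) -> str:
        key = (round(coord[0] / cell), round(coord[1] / cell))
        if key not in key_of:
            key_of[key] = name = f"w{len(key_of)}"
            g.add_node(name, lon=coord[0], lat=coord[1], mode=MODE_ROAD)
        return key_of[key]

    for e in edges:
        u, v = node_for(e.geometry[0]), node_for(e.geometry[-1])
        speed = e.maxspeed_kmh if e.maxspeed_kmh > 0 else default_speed
        t = e.length_km / speed
        if e.oneway in (ONEWAY_BOTH, ONEWAY_FORWARD):
            g.add_edge(u, v, time_h=t, length_km=e.length_km, mode=MODE_ROAD,
                       ref=e.osm_id, geometry=list(e.geometry))
        if e.oneway in (ONEWAY_BOTH, ONEWAY_REVERSE):
            g.add_edge(v, u, time_h=t, length_km=e.length_km, mode=MODE_ROAD,
                       ref=e.osm_id, geometry=list(reversed(e.geometry)))


def _add_connectors(g: nx.DiGraph, tolerance_m: float, walk_speed_kmh: float) -> int:
    """Link each road node to its nearest river node within tolerance (walking)."""
    road = [n for n, d in g.nodes(data=True) if d["mode"] == MODE_ROAD]
    river = [n for n, d in g.nodes(data=True) if d["mode"] == MODE_RIVER]
    if not road or not river:
        return 0
    rlon = np.array([g.nodes[n]["lon"] for n in river])
    rlat = np.array([g.nodes[n]["lat"] for n in river])
    count = 0
    from .geo import haversine_km_many

    for n in road:
        lon, lat = g.nodes[n]["lon"], g.nodes[n]["lat"]
        d_km = haversine_km_many(lon, lat, rlon, rlat)
        j = int(np.argmin(d_km))
        if d_km[j] * 1000.0 <= tolerance_m:
            other = river[j]
            t = float(d_km[j]) / walk_speed_kmh
            geom = [(lon, lat), (g.nodes[other]["lon"], g.nodes[other]["lat"])]
            g.add_edge(n, other, time_h=t, length_km=float(d_km[j]),
                       mode=MODE_CONNECTOR, ref=f"{n}-{other}", geometry=geom)
            g.add_edge(other, n, time_h=t, length_km=float(d_km[j]),
                       mode=MODE_CONNECTOR, ref=f"{other}-{n}",
                       geometry=list(reversed(geom)))
            count += 1
    return count


def build_graph(
    river_records: list[OsmRoutableRecord] | None = None,
    road_edges: list[RoadEdge] | None = None,
    connector_tolerance_m: float = DEFAULT_CONNECTOR_TOLERANCE_M,
    walk_speed_kmh: float = DEFAULT_WALK_SPEED_KMH,
    default_road_speed_kmh: float = DEFAULT_ROAD_SPEED_KMH,
) -> TransportGraph:
    """Assemble the directed travel-time graph for one scenario.

    At least one layer must be given. Non-navigable river records are
    excluded. When both layers are present, walking connectors are created
    between each road node and its nearest river node within
    ``connector_tolerance_m``; if none qualifies the layers stay disjoint and
    a warning is logged (not an error — archipelago-like geographies do this).
    """
    if not river_records and not road_edges:
        raise ValueError("at least one of river_records / road_edges is required")
    g = nx.DiGraph()
    if river_records:
        _add_river_edges(g, river_records)
    if road_edges:
        _add_road_edges(g, road_edges, default_road_speed_kmh)
    n_conn = 0
    if river_records and road_edges:
        n_conn = _add_connectors(g, connector_tolerance_m, walk_speed_kmh)
        if n_conn == 0:
            logger.warning("no road-river connector found within %.0f m; "
                           "layers remain disjoint", connector_tolerance_m)
        else:
            logger.info("created %d road-river connector pairs", n_conn)
    bad = [(u, v) for u, v, t in g.edges(data="time_h") if not t > 0]
    if bad:
        raise ValueError(f"non-positive edge times on {bad[:5]}")
    return TransportGraph(g=g, n_connectors=n_conn)


def shortest_time(graph: TransportGraph, origin: str, dest: str) -> float:
    """Minimal travel time in hours, or the ``inf`` sentinel when unreachable."""
    if origin not in graph.g:
        raise KeyError(f"unknown origin node {origin!r}")
    if dest not in graph.g:
        raise KeyError(f"unknown destination node {dest!r}")
    try:
        return nx.dijkstra_path_length(graph.g, origin, dest, weight="time_h")
    except nx.NetworkXNoPath:
        return UNREACHABLE


def reach_times(graph: TransportGraph, origin: str, cutoff_h: float | None = None) -> dict[str, float]:
    """Single-source shortest times from ``origin`` (optionally truncated)."""
    if origin not in graph.g:
        raise KeyError(f"unknown origin node {origin!r}")
    return nx.single_source_dijkstra_path_length(
        graph.g, origin, cutoff=cutoff_h, weight="time_h")


def export_edge_list(graph: TransportGraph, path: str) -> None:
    """Write the directed edge list (from, to, time_h, mode, ref) as CSV."""
    import pandas as pd

    rows = [(u, v, d["time_h"], d["mode"], d["ref"])
            for u, v, d in graph.g.edges(data=True)]
    pd.DataFrame(rows, columns=["from", "to", "time_h", "mode", "ref"]).to_csv(
        path, index=False)
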