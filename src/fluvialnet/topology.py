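"""Junction reconstruction: the connectivity the hydrography layer omits.

HydroSHEDS-style layers state *which* segment is next downstream but not
*where* segments meet. This module recovers the junction coordinates: segment
endpoints are clustered on a tolerance grid, each cluster becomes one node,
and every segment is assigned its upstream (``from``) and downstream (``to``)
node — the per-segment origin-destination matrix that makes the layer
routable.

Clustering rounds coordinates to the tolerance grid (default 1 m) rather than
greedy nearest-neighbour merging, so the result is independent of segment
order. Hydrography endpoints are grid-snapped at source, so exact coordinate
matches dominate and the tolerance only absorbs float jitter; two genuinely
coincident endpoints that straddle a grid-cell boundary would not merge, which
the diagnostic report surfaces as a linkage mismatch.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from .geo import haversine_km, meters_to_degrees, polyline_length_km
from .model import Coord, RiverSegment, find_downstream_cycles

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE_M = 1.0


@dataclass(frozen=True)
class JunctionNode:
    """A reconstructed river-connection coordinate."""

    node_id: int
    lon: float
    lat: float
    degree: int  # number of incident segment endpoints


@dataclass(frozen=True)
class SegmentIncidence:
    """A segment's upstream and downstream junction assignment."""

    seg_id: int
    from_node: int  # upstream end
    to_node: int  # downstream end


def extract_endpoints(segment: RiverSegment) -> tuple[Coord, Coord]:
    """(upstream, downstream) endpoint of a segment.

    Geometry is digitised upstream-to-downstream, so these are simply the
    first and last vertices.
    """
    if len(segment.geometry) < 2:
        raise ValueError(f"segment {segment.seg_id}: degenerate geometry")
    return segment.geometry[0], segment.geometry[-1]


def _grid_key(coord: Coord, cell_deg: float) -> tuple[int, int]:
    return (round(coord[0] / cell_deg), round(coord[1] / cell_deg))


def build_junctions(
    segments: list[RiverSegment], tolerance_m: float = DEFAULT_TOLERANCE_M
) -> tuple[list[JunctionNode], list[SegmentIncidence]]:
    """Cluster segment endpoints into junction nodes and assign incidences.

    Node ids are assigned in lexicographic (lon, lat) order of the cluster
    coordinate (the mean of member endpoints), so identical input yields
    identical ids regardless of segment order. Node degree counts incident
    segment endpoints, hence the degree sum is exactly twice the segment count.
    """
    cell_deg = meters_to_degrees(tolerance_m)
    clusters: dict[tuple[int, int], list[Coord]] = {}
    endpoint_keys: dict[int, tuple[tuple[int, int], tuple[int, int]]] = {}
    for seg in segments:
        up, down = extract_endpoints(seg)
        ku, kd = _grid_key(up, cell_deg), _grid_key(down, cell_deg)
        clusters.setdefault(ku, []).append(up)
        clusters.setdefault(kd, []).append(down)
        endpoint_keys[seg.seg_id] = (ku, kd)

    coords = {
        key: (
            sum(c[0] for c in pts) / len(pts),
            sum(c[1] for c in pts) / len(pts),
        )
        for key, pts in clusters.items()
    }
    ordered = sorted(coords, key=lambda k: coords[k])
    node_of_key = {key: i for i, key in enumerate(ordered)}

    nodes = [
        JunctionNode(node_of_key[k], coords[k][0], coords[k][1], len(clusters[k]))
        for k in ordered
    ]
    incidences = [
        SegmentIncidence(seg.seg_id, node_of_key[endpoint_keys[seg.seg_id][0]],
                         node_of_key[endpoint_keys[seg.seg_id][1]])
        for seg in segments
    ]
    return nodes, incidences


@dataclass
class TopologyReport:
    """Diagnostics from :func:`validate_topology`; empty fields mean a clean network."""

    cycles: list[list[int]] = field(default_factory=list)
    n_components: int = 0
    linkage_mismatches: list[tuple[int, int]] = field(default_factory=list)  # (seg, next_down)
    n_outlets: int = 0

    @property
    def is_clean(self) -> bool:
        return not self.cycles and not self.linkage_mismatches


def validate_topology(
    segments: list[RiverSegment],
    incidences: list[SegmentIncidence] | None = None,
    tolerance_m: float = DEFAULT_TOLERANCE_M,
) -> TopologyReport:
    """Report cycles, connected components and linkage/geometry mismatches.

    A linkage mismatch is a pair where ``next_down(s) = t`` but the downstream
    endpoint of ``s`` shares no junction node with ``t`` and does not lie on
    ``t``'s polyline within tolerance (a mid-segment confluence; see
    :func:`split_midsegment_confluences`).
    """
    if incidences is None:
        _, incidences = build_junctions(segments, tolerance_m)
    inc = {i.seg_id: i for i in incidences}
    by_id = {s.seg_id: s for s in segments}
    report = TopologyReport(cycles=find_downstream_cycles(segments))
    report.n_outlets = sum(1 for s in segments if s.next_down == 0)

    tol_km = tolerance_m / 1000.0
    for s in segments:
        if s.next_down == 0 or s.next_down not in by_id:
            continue
        t = by_id[s.next_down]
        it, is_ = inc[t.seg_id], inc[s.seg_id]
        if is_.to_node in (it.from_node, it.to_node):
            continue
        end = s.geometry[-1]
        if _point_to_polyline_km(end, t.geometry) > tol_km:
            report.linkage_mismatches.append((s.seg_id, s.next_down))

    # components of the undirected junction graph
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in incidences:
        parent[find(i.from_node)] = find(i.to_node)
    report.n_components = len({find(n) for n in parent})
    if report.linkage_mismatches:
        logger.warning("%d next_down pairs do not share a junction node",
                       len(report.linkage_mismatches))
    return report


def _point_to_polyline_km(point: Coord, polyline: list[Coord]) -> float:
    """Distance from a point to a polyline, km (local planar approximation)."""
    lat0 = math.radians(point[1])
    kx = 111.32 * math.cos(lat0)  # km per degree lon at this latitude
    ky = 111.32
    px, py = point[0] * kx, point[1] * ky
    best = math.inf
    for (x1, y1), (x2, y2) in zip(polyline, polyline[1:]):
        ax, ay = x1 * kx, y1 * ky
        bx, by = x2 * kx, y2 * ky
        dx, dy = bx - ax, by - ay
        denom = dx * dx + dy * dy
        t = 0.0 if denom == 0 else max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / denom))
        qx, qy = ax + t * dx, ay + t * dy
        best = min(best, math.hypot(px - qx, py - qy))
    return best


def split_midsegment_confluences(
    segments: list[RiverSegment], tolerance_m: float = DEFAULT_TOLERANCE_M
) -> list[RiverSegment]:
    """Split segments that receive a tributary in their interior.

    When ``next_down(s) = t`` but the downstream endpoint of ``s`` touches the
    interior of ``t``'s polyline, routing needs a junction there: ``t`` is cut
    at the touch point into an upstream child (keeping ``t``'s id) and a
    downstream child (a fresh id), lengths prorated by arc length and all
    other attributes inherited; ``s`` and the upstream child both drain into
    the downstream child. Returns a new segment list; input is not modified.
    """
    by_id = {s.seg_id: s for s in segments}
    tol_km = tolerance_m / 1000.0
    next_id = max(by_id) + 1

    # collect interior touch points per target segment
    touches: dict[int, list[int]] = {}
    for s in segments:
        t = by_id.get(s.next_down)
        if t is None:
            continue
        end = s.geometry[-1]
        d_from = haversine_km(end[0], end[1], t.geometry[0][0], t.geometry[0][1])
        d_to = haversine_km(end[0], end[1], t.geometry[-1][0], t.geometry[-1][1])
        if min(d_from, d_to) <= tol_km:
            continue
        if _point_to_polyline_km(end, t.geometry) <= tol_km:
            touches.setdefault(t.seg_id, []).append(s.seg_id)

    out: dict[int, RiverSegment] = {s.seg_id: RiverSegment(
        s.seg_id, s.next_down, list(s.geometry), s.length_km,
        s.discharge_avg, s.flow_regime_class, s.stream_speed_class) for s in segments}

    for t_id, feeders in sorted(touches.items()):
        t = out[t_id]
        # split at the feeder touch point nearest t's upstream end; repeat splits
        # land in the downstream child on the next pass if ever needed
        feeder = min(
            feeders,
            key=lambda f: _arc_position_km(out[f].geometry[-1], t.geometry),
        )
        cut = out[feeder].geometry[-1]
        upstream_geom, downstream_geom = _cut_polyline(t.geometry, cut)
        frac = polyline_length_km(upstream_geom) / max(polyline_length_km(t.geometry), 1e-12)
        child_id = next_id
        next_id += 1
        out[child_id] = RiverSegment(
            child_id, t.next_down, downstream_geom, t.length_km * (1 - frac),
            t.discharge_avg, t.flow_regime_class, t.stream_speed_class)
        t.geometry = upstream_geom
        t.length_km = t.length_km * frac
        t.next_down = child_id
        for f in feeders:
            out[f].next_down = child_id
    return list(out.values())


def _arc_position_km(point: Coord, polyline: list[Coord]) -> float:
    """Arc length from the polyline start to the projection of ``point``."""
    lat0 = math.radians(point[1])
    kx, ky = 111.32 * math.cos(lat0), 111.32
    px, py = point[0] * kx, point[1] * ky
    best_d, best_pos, acc = math.inf, 0.0, 0.0
    for (x1, y1), (x2, y2) in zip(polyline, polyline[1:]):
        ax, ay, bx, by = x1 * kx, y1 * ky, x2 * kx, y2 * ky
        dx, dy = bx - ax, by - ay
        denom = dx * dx + dy * dy
        t = 0.0 if denom == 0 else max(0.0, min(1.0, ((px - ax) * dx + (py - ay) * dy) / denom))
        qx, qy = ax + t * dx, ay + t * dy
        d = math.hypot(px - qx, py - qy)
        seg_len = math.hypot(dx, dy)
        if d < best_d:
            best_d, best_pos = d, acc + t * seg_len
        acc += seg_len
    return best_pos


def _cut_polyline(polyline: list[Coord], cut: Coord) -> tuple[list[Coord], list[Coord]]:
    """Split a polyline at the vertex/projection nearest ``cut``."""
    target = _arc_position_km(cut, polyline)
    acc = 0.0
    for i, (a, b) in enumerate(zip(polyline, polyline[1:])):
        lat0 = math.radians(a[1])
        seg_len = math.hypot((b[0] - a[0]) * 111.32 * math.cos(lat0), (b[1] - a[1]) * 111.32)
        if acc + seg_len >= target - 1e-12:
            upstream = list(polyline[: i + 1]) + [cut]
            downstream = [cut] + list(polyline[i + 1:])
            if len(upstream) < 2:
                upstream = [polyline[0], cut]
            if len(downstream) < 2:
                downstream = [cut, polyline[-1]]
            return upstream, downstream
        acc += seg_len
    return list(polyline), [polyline[-1], cut]


def export_node_matrix(nodes: list[JunctionNode], path: str) -> None:
    """Write the junction reference matrix (node_id, lon, lat, degree) as CSV."""
    pd.DataFrame(
        [(n.node_id, n.lon, n.lat, n.degree) for n in nodes],
        columns=["node_id", "lon", "lat", "degree"],
    ).to_csv(path, index=False)
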