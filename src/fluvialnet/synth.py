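"""Synthetic study fixtures: river trees, road grids, facility layouts.

The generators emulate the structure of the real inputs — a dendritic river
network with downstream-accumulating discharge and GloRiC-style class
attributes, a rectangular road lattice deliberately offset from the rivers
(so river-only territory exists, as in archipelago and floodplain
geographies), and facility points placed on roads, on rivers, and off any
network — with ground truth known by construction, so the whole pipeline is
testable without any external download.

Each generator draws from its own explicitly seeded pseudo-random stream;
nothing touches global random state, and a fixed seed reproduces a fixture
byte-for-byte.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geo import METERS_PER_DEGREE
from .model import Facility, RiverSegment, RoadEdge

KM_PER_DEGREE = METERS_PER_DEGREE / 1000.0

#: share of low / medium / high seasonal flow-regime variability. The defaults
#: mirror the distribution observed in Amazon-basin hydrography, where 91% of
#: reaches show low (5%) or medium (86%) variability between seasons.
DEFAULT_REGIME_PROBS = (0.05, 0.86, 0.09)

LABEL_ROAD = "road"
LABEL_RIVER = "river"
LABEL_OFF = "none"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study area.

    The default bounding box is a ~1-degree square on the equator, so planar
    and geodesic distances agree to ~0.1% and hand checks are easy.
    """

    seed: int = 0
    n_segments: int = 40
    branch_prob: float = 0.35
    bbox: tuple[float, float, float, float] = (-61.0, -1.0, -60.0, 0.0)
    discharge_headwater_cms: float = 5.0
    regime_probs: tuple[float, float, float] = DEFAULT_REGIME_PROBS
    road_grid: tuple[int, int, float] = (3, 3, 3.0)  # rows, cols, spacing_km
    road_offset_km: float = 30.0  # eastward offset of the grid from the river bbox
    facility_plan: tuple[int, int, int] = (6, 3, 1)  # on-road, on-river-only, off-network

    def __post_init__(self) -> None:
        lon0, lat0, lon1, lat1 = self.bbox
        if not (lon0 < lon1 and lat0 < lat1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if not math.isclose(sum(self.regime_probs), 1.0, abs_tol=1e-9):
            raise ValueError(f"regime_probs must sum to 1, got {self.regime_probs}")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in [0, 1]")


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec_seed, stream])


def generate_river_tree(spec: FixtureSpec) -> list[RiverSegment]:
    """Grow a dendritic river tree upstream from a single outlet.

    Each new segment attaches its downstream end to the upstream endpoint of
    an existing segment (a leaf endpoint usually; with probability
    ``branch_prob`` any endpoint, which creates confluences), so every
    junction is an exact endpoint match and a tree of n segments has exactly
    n + 1 junction nodes. Discharge accumulates downstream: each segment
    carries its own headwater contribution plus the sum of its tributaries.
    """
    rng = _rng(spec.seed, 0)
    lon0, lat0, lon1, lat1 = spec.bbox
    cx, cy = (lon0 + lon1) / 2.0, (lat0 + lat1) / 2.0

    # per-segment: upstream endpoint, direction of upstream growth, children count
    up_point: dict[int, tuple[float, float]] = {}
    direction: dict[int, float] = {}
    n_children: dict[int, int] = {}
    parent_of: dict[int, int] = {}
    geoms: dict[int, list[tuple[float, float]]] = {}

    def _grow(seg_id: int, start: tuple[float, float], heading: float) -> None:
        step_km = float(rng.uniform(1.5, 4.0))
        step_deg = step_km / KM_PER_DEGREE
        end = (start[0] + step_deg * math.cos(heading),
               start[1] + step_deg * math.sin(heading))
        if not (lon0 <= end[0] <= lon1 and lat0 <= end[1] <= lat1):
            # steer back toward the bbox centre instead of leaving the area
            heading = math.atan2(cy - start[1], cx - start[0]) + float(rng.normal(0, 0.3))
            end = (start[0] + step_deg * math.cos(heading),
                   start[1] + step_deg * math.sin(heading))
        n_mid = int(rng.integers(1, 4))
        pts = [end]  # upstream first
        for k in range(n_mid, 0, -1):
            t = k / (n_mid + 1)
            jitter = step_deg * 0.05
            pts.append((end[0] + (start[0] - end[0]) * (1 - t) + float(rng.normal(0, jitter)),
                        end[1] + (start[1] - end[1]) * (1 - t) + float(rng.normal(0, jitter))))
        pts.append(start)
        geoms[seg_id] = pts
        up_point[seg_id] = end
        direction[seg_id] = heading
        n_children[seg_id] = 0

    # outlet segment grows upstream (northward-ish) from the bbox south edge
    outlet_start = (cx, lat0 + 0.05 * (lat1 - lat0))
    _grow(1, outlet_start, math.pi / 2 + float(rng.normal(0, 0.3)))
    parent_of[1] = 0

    for seg_id in range(2, spec.n_segments + 1):
        leaves = [s for s, c in n_children.items() if c == 0]
        pool = list(n_children) if rng.random() < spec.branch_prob else leaves
        parent = int(pool[int(rng.integers(len(pool)))])
        parent_of[seg_id] = parent
        n_children[parent] += 1
        heading = direction[parent] + float(rng.normal(0, 0.6))
        _grow(seg_id, up_point[parent], heading)

    # downstream discharge accumulation: children are created after parents,
    # so reverse creation order visits tributaries first
    discharge: dict[int, float] = {}
    inflow: dict[int, float] = {s: 0.0 for s in geoms}
    for seg_id in sorted(geoms, reverse=True):
        own = spec.discharge_headwater_cms * float(rng.uniform(0.5, 1.5))
        discharge[seg_id] = own + inflow[seg_id]
        p = parent_of[seg_id]
        if p:
            inflow[p] += discharge[seg_id]

    levels = np.array(["low", "medium", "high"])
    regime = rng.choice(levels, size=spec.n_segments, p=list(spec.regime_probs))
    stream_cls = rng.integers(1, 4, size=spec.n_segments)

    segments = []
    for i, seg_id in enumerate(sorted(geoms)):
        segments.append(RiverSegment(
            seg_id=seg_id,
            next_down=parent_of[seg_id],
            geometry=geoms[seg_id],
            length_km=0.0,  # recomputed geodesically in __post_init__
            discharge_avg=discharge[seg_id],
            flow_regime_class=str(regime[i]),
            stream_speed_class=int(stream_cls[i]),
        ))
    return segments


def _road_lattice_nodes(spec: FixtureSpec) -> list[tuple[float, float]]:
    rows, cols, spacing_km = spec.road_grid
    spacing_deg = spacing_km / KM_PER_DEGREE
    lon_origin = spec.bbox[2] + spec.road_offset_km / KM_PER_DEGREE
    lat_origin = spec.bbox[1]
    return [(lon_origin + c * spacing_deg, lat_origin + r * spacing_deg)
            for r in range(rows) for c in range(cols)]


def generate_road_grid(spec: FixtureSpec) -> list[RoadEdge]:
    """A rows x cols lattice of bidirectional roads, offset from the rivers.

    The lattice has rows*cols nodes and 2*rows*cols - rows - cols edges. With
    the default 30 km eastward offset no road node lies within walking-
    connector range of any river node, creating genuine river-only territory.
    """
    rows, cols, _ = spec.road_grid
    nodes = _road_lattice_nodes(spec)

    def at(r: int, c: int) -> tuple[float, float]:
        return nodes[r * cols + c]

    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append(RoadEdge(
                    osm_id=f"h-{r}-{c}", fclass="secondary",
                    geometry=[at(r, c), at(r, c + 1)],
                    oneway="B", maxspeed_kmh=60.0))
            if r + 1 < rows:
                edges.append(RoadEdge(
                    osm_id=f"v-{r}-{c}", fclass="secondary",
                    geometry=[at(r, c), at(r + 1, c)],
                    oneway="B", maxspeed_kmh=60.0))
    return edges


def generate_facilities(
    spec: FixtureSpec,
    rivers: list[RiverSegment],
    roads: list[RoadEdge],
) -> tuple[list[Facility], dict[str, str]]:
    """Place facilities per the plan and return ground-truth labels.

    Labels: ``road`` — on a road lattice node (reachable in the roads-only
    scenario); ``river`` — on a river junction beyond snapping range of any
    road (reachable only once rivers are routable); ``none`` — beyond
    snapping range of both networks.
    """
    rng = _rng(spec.seed, 2)
    n_road, n_river, n_off = spec.facility_plan
    facilities: list[Facility] = []
    labels: dict[str, str] = {}

    road_nodes = sorted({tuple(e.geometry[0]) for e in roads}
                        | {tuple(e.geometry[-1]) for e in roads})
    if n_road > len(road_nodes):
        raise ValueError(f"facility plan wants {n_road} on-road sites, "
                         f"grid has {len(road_nodes)} nodes")
    for k, i in enumerate(rng.choice(len(road_nodes), size=n_road, replace=False)):
        lon, lat = road_nodes[int(i)]
        fid = f"chc-road-{k}"
        facilities.append(Facility(fid, lon, lat))
        labels[fid] = LABEL_ROAD

    river_nodes = sorted({tuple(s.geometry[0]) for s in rivers}
                         | {tuple(s.geometry[-1]) for s in rivers})
    if n_river > len(river_nodes):
        raise ValueError("not enough river junctions for the facility plan")
    for k, i in enumerate(rng.choice(len(river_nodes), size=n_river, replace=False)):
        lon, lat = river_nodes[int(i)]
        fid = f"chc-river-{k}"
        facilities.append(Facility(fid, lon, lat))
        labels[fid] = LABEL_RIVER

    # off-network decoys: well south of the river bbox and west of the roads
    lon0, lat0, lon1, _ = spec.bbox
    for k in range(n_off):
        fid = f"chc-off-{k}"
        facilities.append(Facility(
            fid,
            float(rng.uniform(lon0, lon1)),
            lat0 - 0.5 - float(rng.uniform(0.0, 0.2)),
        ))
        labels[fid] = LABEL_OFF
    return facilities, labels


def y_network() -> list[RiverSegment]:
    """Hand-built 3-segment Y: two tributaries joining into one mainstem.

    The confluence sits at (-60.5, -0.5); the mainstem drains south to the
    outlet. Discharge accumulates 5 + 3 -> 8 m^3/s downstream.
    """
    conf = (-60.5, -0.5)
    return [
        RiverSegment(1, 0, [conf, (-60.5, -0.7)], 0.0, 8.0, "medium", 2),  # mainstem
        RiverSegment(2, 1, [(-60.6, -0.3), conf], 0.0, 5.0, "medium", 2),  # west trib
        RiverSegment(3, 1, [(-60.4, -0.3), conf], 0.0, 3.0, "low", 1),     # east trib
    ]


def archipelago(seed: int = 0) -> tuple[list[RiverSegment], list[RoadEdge],
                                        list[Facility], dict[str, str]]:
    """The standard mixed fixture: river tree + offset road grid + 6/3/1 facilities."""
    spec = FixtureSpec(seed=seed)
    rivers = generate_river_tree(spec)
    roads = generate_road_grid(spec)
    facilities, labels = generate_facilities(spec, rivers, roads)
    return rivers, roads, facilities, labels


def random_tree(seed: int, n_segments: int) -> list[RiverSegment]:
    """A bare random dendritic river tree of the requested size."""
    return generate_river_tree(FixtureSpec(seed=seed, n_segments=n_segments))
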