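import itertools
import math

import networkx as nx
import numpy as np
import pytest

import fluvialnet as fn
from fluvialnet.graph import MODE_CONNECTOR, MODE_RIVER, MODE_ROAD

from conftest import records_for


def brute_force_shortest(g: nx.DiGraph, origin: str, dest: str) -> float:
    """Exhaustive simple-path enumeration, independent of the routing code."""
    best = math.inf

    def dfs(u, seen, acc):
        nonlocal best
        if acc >= best:
            return
        if u == dest:
            best = acc
            return
        for v in g.successors(u):
            if v not in seen:
                dfs(v, seen | {v}, acc + g[u][v]["time_h"])

    dfs(origin, {origin}, 0.0)
    return best


class TestBuildGraph:
    def test_rivers_only_y_network(self, y_records):
        g = fn.build_graph(river_records=y_records)
        assert g.g.number_of_nodes() == 4
        assert g.g.number_of_edges() == 6  # 3 segments x 2 directions
        assert all(d["mode"] == MODE_RIVER for _, _, d in g.g.edges(data=True))

    def test_non_navigable_segments_excluded(self, y_segments):
        records = records_for(y_segments, min_discharge_cms=4.0)  # drops seg 3
        g = fn.build_graph(river_records=records)
        assert g.g.number_of_edges() == 4

    def test_oneway_road_has_no_reverse_edge(self):
        edges = [fn.RoadEdge("a", "primary", [(0.0, 0.0), (0.05, 0.0)], oneway="F",
                             maxspeed_kmh=50.0)]
        g = fn.build_graph(road_edges=edges)
        assert g.g.number_of_edges() == 1

    def test_default_speed_when_maxspeed_unknown(self):
        edges = [fn.RoadEdge("a", "track", [(0.0, 0.0), (0.05, 0.0)], maxspeed_kmh=0.0)]
        g = fn.build_graph(road_edges=edges, default_road_speed_kmh=40.0)
        (u, v, t), *_ = g.g.edges(data="time_h")
        assert t == pytest.approx(edges[0].length_km / 40.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fn.build_graph()

    def test_disjoint_layers_warn_not_fail(self, archipelago_fixture, caplog):
        rivers, roads, _, _ = archipelago_fixture
        records = records_for(rivers)
        with caplog.at_level("WARNING"):
            g = fn.build_graph(river_records=records, road_edges=roads)
        assert g.n_connectors == 0
        assert "no road-river connector" in caplog.text
        assert not nx.is_weakly_connected(g.g)

    def test_connectors_link_adjacent_layers(self, y_records):
        # a road ending 100 m east of the Y outlet gets a walking connector
        outlet = y_records[0].geometry[-1]
        near = (outlet[0] + 100 / 111_194.9, outlet[1])
        far = (near[0] + 0.05, near[1])
        roads = [fn.RoadEdge("a", "primary", [near, far], maxspeed_kmh=50.0)]
        g = fn.build_graph(river_records=y_records, road_edges=roads,
                           connector_tolerance_m=500.0, walk_speed_kmh=5.0)
        assert g.n_connectors == 1
        conns = [(u, v, d) for u, v, d in g.g.edges(data=True)
                 if d["mode"] == MODE_CONNECTOR]
        assert len(conns) == 2  # symmetric pair
        assert conns[0][2]["time_h"] == pytest.approx(0.1 / 5.0, rel=0.01)

    def test_combined_reachability_superset_of_single_mode(self, y_records):
        outlet = y_records[0].geometry[-1]
        near = (outlet[0] + 100 / 111_194.9, outlet[1])
        roads = [fn.RoadEdge("a", "primary", [near, (near[0] + 0.05, near[1])])]
        combined = fn.build_graph(river_records=y_records, road_edges=roads)
        rivers_only = fn.build_graph(river_records=y_records)
        roads_only = fn.build_graph(road_edges=roads)
        reach_combined = set(nx.descendants(combined.g, "r0")) | {"r0"}
        for single, node in ((rivers_only, "r0"), (roads_only, "w0")):
            single_reach = set(nx.descendants(single.g, node)) | {node}
            assert single_reach <= set(nx.descendants(combined.g, node)) | {node}


class TestShortestTime:
    def test_origin_equals_destination(self, y_records):
        g = fn.build_graph(river_records=y_records)
        node = next(iter(g.g.nodes))
        assert fn.shortest_time(g, node, node) == 0.0

    def test_unknown_node_raises(self, y_records):
        g = fn.build_graph(river_records=y_records)
        with pytest.raises(KeyError):
            fn.shortest_time(g, "nope", next(iter(g.g.nodes)))

    def test_chain_additivity_and_asymmetry(self):
        # two-segment chain with positive stream: downstream strictly faster
        a = fn.RiverSegment(1, 0, [(0.0, 0.05), (0.0, 0.0)], 18.52, 9.0, "low", 2)
        b = fn.RiverSegment(2, 1, [(0.0, 0.1), (0.0, 0.05)], 9.26, 5.0, "low", 2)
        records = records_for([a, b])
        g = fn.build_graph(river_records=records)
        head, outlet = "r2", "r0"  # ids in (lon, lat) order: outlet south
        down = fn.shortest_time(g, head, outlet)
        up = fn.shortest_time(g, outlet, head)
        assert down == pytest.approx((18.52 + 9.26) / (18.52 + 1.5))
        assert down < up

    def test_unreachable_sentinel(self):
        edges = [fn.RoadEdge("a", "x", [(0.0, 0.0), (0.01, 0.0)], oneway="F")]
        g = fn.build_graph(road_edges=edges)
        u, v = list(g.g.nodes)
        assert math.isinf(fn.shortest_time(g, v, u))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 11))
        g = nx.DiGraph()
        for i in range(n):
            g.add_node(f"n{i}", lon=0.0, lat=0.0, mode=MODE_ROAD)
        for i, j in itertools.permutations(range(n), 2):
            if rng.random() < 0.3:
                g.add_edge(f"n{i}", f"n{j}", time_h=float(rng.uniform(0.05, 2.0)),
                           length_km=1.0, mode=MODE_ROAD, ref="synthetic",
                           geometry=[(0.0, 0.0), (0.0, 0.01)])
        tg = fn.TransportGraph(g=g)
        a, b = f"n{int(rng.integers(n))}", f"n{int(rng.integers(n))}"
        expected = brute_force_shortest(g, a, b)
        got = fn.shortest_time(tg, a, b)
        assert got == pytest.approx(expected) or (math.isinf(got) and math.isinf(expected))

    def test_triangle_inequality(self, y_records):
        g = fn.build_graph(river_records=y_records)
        nodes = list(g.g.nodes)
        for a, b, c in itertools.permutations(nodes, 3):
            tab, tbc, tac = (fn.shortest_time(g, a, b), fn.shortest_time(g, b, c),
                             fn.shortest_time(g, a, c))
            assert tac <= tab + tbc + 1e-12


def test_edge_list_export(tmp_path, y_records):
    import pandas as pd

    g = fn.build_graph(river_records=y_records)
    path = tmp_path / "edges.csv"
    from fluvialnet.graph import export_edge_list
    export_edge_list(g, path)
    df = pd.read_csv(path)
    assert len(df) == 6
    assert set(df["mode"]) == {"river"}
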