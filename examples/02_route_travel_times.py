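"""Shortest travel times on the river graph, showing directional asymmetry.

Every navigable segment contributes two directed edges: the boat travels at
its cruising speed plus the stream speed downstream and minus it upstream, so
the same route costs more hours against the current.
"""
import fluvialnet as fn

segments = fn.random_tree(seed=3, n_segments=60)
_, incidences = fn.build_junctions(segments)
records = fn.to_osm_records(
    segments, {i.seg_id: (i.from_node, i.to_node) for i in incidences})
graph = fn.build_graph(river_records=records)

by_id = {r.seg_id: r for r in records}
outlet = next(s for s in segments if s.next_down == 0)
outlet_node = f"r{by_id[outlet.seg_id].to_node}"

# pick the headwater farthest (in hops) from the outlet
leaf = max((s for s in segments), key=lambda s: s.length_km)
head_node = f"r{by_id[leaf.seg_id].from_node}"

down = fn.shortest_time(graph, head_node, outlet_node)
up = fn.shortest_time(graph, outlet_node, head_node)
print(f"graph: {graph.g.number_of_nodes()} nodes, "
      f"{graph.g.number_of_edges()} directed edges")
print(f"headwater -> outlet: {down:.3f} h  (with the current)")
print(f"outlet -> headwater: {up:.3f} h  (against the current)")
print(f"asymmetry: upstream takes {100 * (up / down - 1):.1f}% longer — "
      "the stream speed added downstream is subtracted upstream")
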