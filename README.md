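# fluvialnet

**Routable river networks and multimodal healthcare catchment analysis.**

In river-dominated regions such as the Amazon basin, most travel to a health
facility happens by boat, yet the standard routable transport datasets
(OpenStreetMap road extracts) contain no navigable waterways. Any travel-time
or catchment analysis built on roads alone systematically misses the
population that lives along the rivers. `fluvialnet` closes that gap for
analysts and health-geography researchers: it converts a river hydrography
layer (HydroSHEDS/HydroRIVERS-style segments with GloRiC hydrological
classes) into an OSM-compatible routable layer, combines it with a
GeoFabrik-style road layer into a directed travel-time graph, and computes
per-facility catchment areas under three scenarios — roads only, rivers only,
and combined.

## The model

A hydrography layer gives each river segment a polyline, a unique id, the id
of the next segment downstream, its length *L* (km), its average discharge
*Q* (m³/s), and hydrological classes for flow-regime variability and stream
velocity. The conversion has three steps:

1. **Junction reconstruction.** The layer states *which* segment is
   downstream but not *where* segments meet. Segment endpoints are clustered
   on a 1 m tolerance grid; each cluster becomes a junction node with a
   coordinate, and each segment gets its upstream/downstream node pair — the
   origin–destination matrix that makes the layer routable. For a dendritic
   tree of *n* segments this yields exactly *n* + 1 nodes.

2. **Transport attributes.** A standard motorised riverboat cruises at
   *v*<sub>boat</sub> = 18.52 km/h (up to 37 km/h). The water current of
   speed *v*<sub>stream</sub> (from the velocity class) helps one way and
   hinders the other:

   *t*<sub>down</sub> = *L* / (*v*<sub>boat</sub> + *v*<sub>stream</sub>),  
   *t*<sub>up</sub> = *L* / max(*v*<sub>boat</sub> − *v*<sub>stream</sub>, *v*<sub>min</sub>),

   so every segment carries two direction-dependent travel times. A discharge
   threshold flags small streams as non-navigable (flagged, never deleted).
   Records are emitted in the GeoFabrik routable schema (DBF-safe ≤10-char
   field names); road-only fields (bridge, tunnel, lanes, electricity) are
   kept but flagged `do_not_apply`, and vessel width/weight/height limits are
   `unrestricted`.

3. **Multimodal graph and catchments.** Rivers, roads, and symmetric walking
   connectors (road node ↔ nearest river node within 500 m) form a directed
   graph weighted by hours. A facility is snapped to its nearest node within
   2 km; its catchment is the buffered union of all edges (or fractions of
   edges) reachable within a travel-time threshold, and the three-scenario
   comparison counts covered facilities and the coverage gain
   100 × (*n*<sub>combined</sub> − *n*<sub>roads</sub>) / *n*<sub>roads</sub>.

## Worked example

```sh
python examples/03_catchment_comparison.py
```

```
facilities:             10
covered, roads only:    6
covered, rivers only:   3
covered, combined:      9
newly covered by rivers: ['chc-river-0', 'chc-river-1', 'chc-river-2']
coverage increase:      50.0% over roads alone
```

The synthetic "archipelago" fixture places a road grid 30 km from a river
tree and ten facilities: six on road junctions, three on river junctions
unreachable from any road, one off both networks. Roads alone cover 6
facilities; the routable rivers add the 3 river-side facilities the road
analysis cannot see (a 50% coverage gain); the off-network facility is
covered by neither, as a real facility registry would show.

Also available: `examples/01_convert_river_network.py` (hydrography →
routable layer) and `examples/02_route_travel_times.py` (directional
travel-time asymmetry). The same pipeline is scriptable from a shell:

```sh
fluvialnet fixtures --scenario archipelago --seed 0 --out-dir fx
fluvialnet convert  --rivers fx/rivers.geojson --out routable.geojson
fluvialnet compare  --rivers fx/rivers.geojson --roads fx/roads.geojson \
                    --facilities fx/facilities.csv --threshold-h 2 --out-dir cmp
```

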