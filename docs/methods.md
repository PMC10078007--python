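# Methods

## Problem and scope

`fluvialnet` turns a river hydrography layer into a routable transport layer
and measures what that buys for healthcare accessibility. The pipeline has
four stages — ingest/validate, junction reconstruction, attribute emission,
graph/catchment analysis — plus a synthetic-fixture generator that supplies
ground-truth test data. It operates entirely in WGS84 (EPSG:4326); no
reprojection is offered.

## Input model and assumptions

River segments follow the HydroSHEDS/HydroRIVERS convention: polylines
digitised upstream→downstream, a unique positive segment id, a next-downstream
id (0 at an outlet), a length in km, and GloRiC-style hydrological classes.
The downstream relation must be a forest (cycles are a validation error), and
each segment has exactly one downstream neighbour — braided, multi-outlet
channels are out of scope. Roads follow the GeoFabrik routable-shapefile
schema; both the GeoFabrik (`B`/`F`/`T`) and raw OSM (`no`/`yes`/`-1`)
`oneway` dialects are normalised on read. Stated segment lengths are trusted
when present; missing or non-positive lengths are recomputed as haversine
polyline length (exact to well under the metre at these extents, so no
ellipsoidal model is used).

## Junction reconstruction

Endpoint clustering uses grid-hash rounding: coordinates divided by the
tolerance (default **1 m**, converted to degrees of arc) and rounded to the
nearest cell. This is order-independent by construction — the same input in
any order yields identical nodes — unlike greedy nearest-neighbour merging.
The node coordinate is the mean of its member endpoints, and node ids are
assigned in lexicographic (lon, lat) order for reproducibility. The known
trade-off of grid rounding is that two points within tolerance of each other
but straddling a cell boundary do not merge; hydrography endpoints are
grid-snapped at source, so exact matches dominate and the diagnostic report
(`validate_topology`) surfaces any remaining linkage mismatch rather than
silently mis-joining.

When a tributary's downstream endpoint touches the *interior* of its target
segment (`split_midsegment_confluences`), the target is cut at the touch
point: the upstream part keeps the original id, the downstream part gets a
fresh id, lengths are prorated by arc length and all other attributes
(discharge, classes) are inherited unchanged. Inheriting discharge on both
halves slightly overstates the upstream half's discharge; at the precision of
a navigability threshold this is immaterial, and routing correctness requires
the node regardless.

## Transport attributes

* **Boat profile** — average 18.52 km/h, maximum 37 km/h: the measured
  cruising and peak speeds of motorised riverboats in Amazonian service.
  Both are configurable (`boat.*` keys).
* **Stream speed** — the current's speed is added to the boat speed
  downstream and subtracted upstream. The velocity *classes* come from the
  data; the km/h magnitude per class is a modelling choice, default
  {1: 0.5, 2: 1.5, 3: 3.0} km/h, config-overridable and required to be
  non-decreasing in class. `apply_stream_speed: false` emits the column but
  computes symmetric travel times, for users who prefer the raw boat speed.
* **Upstream floor** — default behaviour floors the upstream effective speed
  at 1 km/h rather than disconnecting the edge when the current meets or
  exceeds the boat speed; `upstream_mode: block` instead marks the upstream
  direction impassable (stored as an infinite travel time, serialised as
  JSON null). The floor avoids silently fragmenting the graph; blocking is
  the conservative alternative for strong-current analyses.
* **Navigability** — segments with average discharge below
  `min_discharge_cms` (default 0, i.e. keep everything) are flagged
  `navigable = false` but never deleted, so the written layer remains a
  complete, inspectable census; the graph builder excludes them.
* **Schema** — records carry every GeoFabrik routable field plus the river
  extensions, under fixed DBF-legal ≤10-character names
  (`ingest.ROUTABLE_FIELD_NAMES`). Road-only fields hold the string sentinel
  `do_not_apply`, vessel size limits `unrestricted`; sentinels are never
  numeric. Rivers are emitted `oneway = both` with the asymmetry carried by
  the two travel-time columns, matching OSM semantics while preserving
  direction-dependent routing.

## Graph and routing

The graph is a `networkx.DiGraph`: river edges weighted by the per-direction
travel times; road edges by length over `maxspeed` (40 km/h default where
maxspeed is 0/unknown, as is common in OSM extracts); and walking connectors
— symmetric pairs between each road node and its nearest river node within
500 m, weighted by geodesic distance over 5 km/h. Connector creation is
explicit and logged; zero connectors is a warning, not an error, because
genuinely disjoint geographies exist. Scenario graphs are rebuilt from their
layers rather than masked from a master graph, so each scenario is
reproducible in isolation. Shortest times are Dijkstra; unreachable pairs
return an infinite sentinel.

## Catchments

A facility snaps to the nearest graph node within `max_snap_m` (default
2,000 m — deliberately finite so off-network facilities fail to snap, as in
real registries). From the snapped node a single-source shortest-time pass
marks each directed edge: fully reached when entry time + edge time fits the
threshold, otherwise partially reached with fraction
(threshold − entry time) / edge time, and the geometry cut at that fraction.
The polygon is the union of reached geometry buffered by 250 m (default).
A buffer, not a convex or alpha hull: hulls claim coverage across terrain
the network never touches, which is exactly the error this analysis exists
to avoid. The travel-time threshold has **no default** and must be given
explicitly — any single number would masquerade as canonical.

Coverage gain is defined as 100 × (n_combined − n_roads) / n_roads. Other
denominators (e.g. the newly-covered count over the combined count) give
slightly different percentages; the definition used here is fixed and stated
so results are reproducible.

## Synthetic fixtures

The generator emulates the structural features the pipeline depends on, with
ground truth by construction:

* **River tree** — grown upstream from one outlet; every new segment attaches
  its downstream end exactly to an existing upstream endpoint (branch
  probability 0.35), so junctions are exact endpoint matches and a tree of n
  segments has n + 1 nodes. Discharge accumulates downstream (each segment's
  headwater contribution, ~5 m³/s, plus the sum of its tributaries), so a
  parent always exceeds each child. Flow-regime classes are drawn at
  5% / 86% / 9% (low/medium/high), the distribution characteristic of
  Amazon-basin reaches, where 91% of rivers show low-or-medium seasonal
  variability. Geometry lives in a ~1° equatorial box so planar and geodesic
  distances agree to ~0.1%.
* **Road grid** — a rows × cols lattice (default 3×3, 3 km spacing) offset
  30 km east of the river box, guaranteeing river-only territory: no road
  node is within connector (500 m) or snapping (2 km) range of any river.
* **Facilities** — the default plan (6, 3, 1) places six on road nodes,
  three on river junctions, one ~55 km off both networks, with ground-truth
  labels emitted alongside.

What the fixtures do **not** emulate: realistic meandering and DEM-derived
geometry, braided channels, mid-segment confluences (exercised by hand-built
fixtures instead), seasonal variation of travel times, and the empirical
distributions of a real road network (speeds, classes, partial coverage).
Passing tests therefore demonstrate correctness of topology, attribute
arithmetic, routing and scenario logic — not calibration of travel times
against observed journeys.

## Numerical choices

* Floats are written with 6 decimal places (≈0.1 m at the equator); the
  round-trip tests assert identity at that precision.
* Default problem sizes in the test suite and acceptance script — trees up to
  1,000 segments, 100 seeds for topology/IO properties, 20 archipelago seeds
  for scenario dominance, a 10,000-segment network for regime shares — were
  chosen to exercise the asymptotic behaviour while keeping a full run in
  seconds on one core.
* Ties in facility snapping and connector selection resolve to the first
  minimal candidate in deterministic node order; identical inputs and
  configuration always produce identical outputs, and generator output is
  reproduced byte-for-byte by its seed.

## Known limitations

Single-profile boats (no vessel classes or fuel/cost model); static travel
times (no seasonality despite the flow-regime flag being carried precisely so
end-users can model it); no turn restrictions or timetabled ferries; GeoJSON
and CSV interchange only (the attribute schema is shapefile-ready, but
writing .shp/.dbf directly requires external conversion, e.g. ogr2ogr).
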