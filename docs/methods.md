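# Methods

`accesskit` models access to health services on a raster landscape: every
cell carries the time needed to cross it, and the travel time of any point
is the least accumulated crossing time to the nearest open facility. This
note records the models, the parameter choices, the numerical decisions and
the known limits of the approach.

## The land-cover model

All analysis happens on one co-registered grid system (row 0 at the north
edge, origin at the lower-left corner, default 50 m cells). Three layers are
mosaicked into a single categorical grid of twelve classes:

| ids | layer | meaning |
|-----|-------|---------|
| 1–4 | vegetation | Forest, Grass, Bare/rocky, Scrub |
| 101–105 | watercourses | Strahler order 1–4; 105 = order ≥ 5 |
| 201–203 | roads | national, provincial, local |

Watercourses are derived from elevation: depressions are filled by
priority-flood with an epsilon gradient (default 1e-6 m per step across
filled flats) so that steepest-descent D8 flow is defined everywhere and the
flow graph is acyclic; flow accumulation counts upstream cells; cells above
an initiation threshold (default 0.5 % of the grid's cells — small enough to
produce branched, multi-order networks on the synthetic terrain, large
enough that hillslopes stay dry) form the stream network, ordered by the
Strahler rule. Orders 1–4 map to classes 101–104; everything above is capped
into 105, the class treated as never passable. D8 ties break on a fixed
neighbour order (E, SE, S, SW, W, NW, N, NE) so results are identical across
platforms.

The mosaic precedence is road > stream > vegetation: roads are assumed
bridged over watercourses. Weather scenarios therefore never sever a road by
themselves; a flooded or destroyed crossing is expressed the way a local
planner would express it — by drawing a barrier or editing cells, which is a
first-class operation (`edit_landcover`, `ScenarioSpec.barriers`). Where
road classes cross, the faster (lower-id) class wins.

## Friction surfaces and scenarios

Per-cell traversal seconds come from a speed table: `seconds =
cell_size / (km/h / 3.6)`; a speed of zero maps to the impassable sentinel
99,999 s. The packaged reference table gives walking at 1–3 km/h off road
(0.75 km/h in scrub), fordable streams at 2 km/h, and roads at 50/25/10
km/h. Seconds are always derived from the km/h column, not copied from any
rounded seconds column, so a 50 km/h road at 50 m cells costs 3.6 s.

Scenario modifiers apply in a fixed order so that composition is
reproducible and barriers always win:

1. drawn roads / land-cover edits (cell overwrites);
2. road speed overrides (km/h per road class);
3. walking mode: assisted halves walking speed, stretcher cuts it to a
   fifth; applied to off-road classes only — road travel is vehicular
   (a flag extends the factor to roads for walked-road studies);
4. weather: rain closes the three highest watercourse classes
   (103–105), flooding closes all five;
5. night: all speeds × 0.8, i.e. all traversal times × 1.25 — hence the
   whole travel-time surface scales by exactly 1.25 in the exact engine;
6. barriers: listed cells set to 1–600 minutes each.

## Accumulated travel time: two engines

Both engines share one move graph: each cell connects to its 8 ring
neighbours and the 8 knight neighbours of a 5×5 mask, with move cost
`d · (t₁ + t₂)/2` for fractional distance d ∈ {1, √2, √5} cell units. The
mean-of-endpoints convention is symmetric and makes uniform-surface travel
exact along grid axes. Sentinel cells are removed from the graph outright
rather than given a large finite cost, so travel can never leak through a
barrier. One caveat follows from the mask itself: knight moves jump over the
cells between, so a drawn barrier must be at least two cells thick to
enclose completely.

The *chamfer engine* initialises every cell to the sentinel and destinations
to zero, then runs four sequential scans (forward and backward in row-major
order, then forward and backward in column-major order), at each visited
cell keeping the minimum over all sixteen `neighbour + move cost`
candidates. Four scans are the default; `converge=True` adds scan pairs
until no cell changes, which is needed on spatially rough (uncorrelated)
cost fields but changes smooth surfaces only marginally. The *exact engine*
is multi-source Dijkstra (scipy's csgraph) on the same graph and serves both
as the production engine at desk scale and as the oracle for the chamfer
engine; on smooth seeded fields the two agree to well under 1 % per cell and
their zone maps disagree on far less than 5 % of cells.

On a uniform surface the mask metric overestimates Euclidean distance by at
most √(1+(√5−2)²) − 1 ≈ 2.748 %, attained between the axial and knight
directions (≈13.3°); the suite asserts this exact bound. Optimised 5×5
weights could reduce the worst case to ≈1.9 % but would sacrifice exactness
along the axial, diagonal and knight directions, which the move-cost
convention above relies on; we keep the exact local distances.

Accumulated minutes are banded into six remoteness zones over half-open
intervals [min, max): 0–15, 15–30, 30–60, 60–90, 90–120, 120+ (top bound
999,999). Unreachable cells take the top zone.

## Scenario sweeps

A sweep is the cartesian product of named axes over a base scenario
(lexicographic in axis order), e.g. 3 walking modes × 2 times of day × 3
weather states = 18 runs; adding a 2-level service-availability axis gives
36. Service availability filters the destination set per scenario: a
facility may declare the service states under which it is open (a clinic
whose doctor is away on call), and a scenario with no open facility is an
error rather than an empty surface. Grids are written under stable
spec-derived names; the composite image orders runs by a severity score —
the sum of per-axis ranks (stretcher > assisted > walking, night > day,
flooding > rainy > dry) — worst conditions first. The score is a layout
device only; dominance between scenarios is asserted pointwise in the tests.

## The patient/car geosimulation

A patient agent descends the travel-time surface: at each event it takes the
downhill 16-neighbour move minimising remaining surface value plus the
move's own seconds. This is least-cost-path backtracing — the streamline of
the accumulated-cost field — so a walking-only journey replays the surface
value at its start cell exactly on the exact engine (within the chamfer
deviation otherwise). Pure smallest-neighbour-value descent is available as
`descent="value"`; it reaches the destination too but overshoots the
surface time by 10–30 % on typical fixtures because it prefers knight hops
with marginally smaller values at disproportionate cost. Time is
event-driven — each move costs its exact cell-pair seconds — so no tick
length needs choosing; termination is guaranteed in at most one step per
finite cell because the surface value strictly decreases.

With cars disabled the journey uses the cost surface as-is, i.e. the
multi-modal assumption that vehicle travel is available the moment a road is
reached. Enabling cars drops that assumption: the patient then moves at an
ordinary walking pace (default 5 km/h, `walk_on_road_kmh`) on road cells,
keeps walking rather than standing still, and rides at road speed from the
moment a car occupies its cell. Cars appear by a seeded Poisson process
(rate = `traffic_intensity` per minute), spawn anywhere on the
destination-connected road network — the toolkit has no data on where
traffic originates, and a network-uniform spawn is the least-informative
choice — and drive toward the facility by descending a road-constrained
travel-time field computed by the exact engine. Arrival time is therefore
stochastically decreasing in traffic intensity, and a cars-enabled run never
arrives later than the same run with zero traffic; both properties are
asserted over seeded ensembles. Car speed is the road-class speed whether
empty or carrying the patient.

## The synthetic landscape

Every pipeline input can be generated, seeded and deterministic, so no
download is ever needed. The elevation model is low-pass-filtered Gaussian
noise (correlation length about a twelfth of the grid) blended 45:55 with a
radial dome of the same relief (default 150 m): the dome keeps the regional
gradient pointing outward, so depression filling touches well under 5 % of
cells (asserted over ten seeds) and Strahler ordering yields branched,
multi-order networks. Vegetation is a smoothed noise field blended with
relative elevation and cut at fixed quantiles (35 / 65 / 88 %), giving
contiguous patches with all four classes always present. Roads are a
national trunk crossing the extent with gentle meanders, two provincial
branches to the north and south edges and short local spurs; facilities
(default two) sit on the trunk. The default extent is 600×600 cells at 50 m
(a 30×30 km window, the demonstration scale the toolkit targets); the test
suite and the acceptance script use 48–200 cell grids, which exercise every
code path at a fraction of the cost — the problem sizes reported in the
acceptance output are chosen on that basis.

What the generator does *not* emulate: realistic geomorphology (valley
asymmetry, drainage density), land-cover/terrain correlation beyond the
simple elevation blend, road networks that follow valleys, population
surfaces. Tests passing on these landscapes therefore demonstrate the
correctness of the algorithms and the stated invariants, not the realism of
any particular regional parameterisation — real studies should supply their
own elevation, vegetation and road inputs through the same readers.

## Numerical choices and degenerate inputs

* Nodata (default −9999) is excluded everywhere: impassable in costing,
  outlet-adjacent in hydrology, propagated by the mosaic.
* Destination points snap to the nearest cell centre; two points snapping to
  one cell collapse silently (logged). A destination on an impassable cell
  is an error.
* Fill epsilon 1e-6 m: large enough to order flats deterministically in
  float64, small enough that accumulated increments stay millimetric on
  desk-scale grids; filling is idempotent.
* An interior flat with no descent on a user-supplied (externally filled)
  DEM is routed across equal elevation toward the flat's spill by a
  breadth-first pass, never an error.
* Rasterised roads sample polylines at a quarter-cell step, guaranteeing
  8-connected chains with no diagonal gaps; geometry outside the extent is
  clipped and logged.
* All randomness flows from integer seeds through `numpy.random.Generator`;
  no time-based state anywhere, so every output is reproducible
  byte-for-byte (the CLI determinism test asserts this end to end).

## Known limitations

* Costs are isotropic: slope does not modify speed (a natural extension —
  weight the move cost by the elevation difference — but out of scope).
* The knight-move barrier caveat above: one-cell-thin drawn barriers leak.
* Roads are never severed by weather without an explicit barrier edit.
* The car process is a stylised Poisson flow on the road network, not a
  traffic model; it is meant for exploring sensitivity to transport
  availability, not for estimating real waiting times.
* No CRS handling: all inputs must already share one projected,
  metre-based coordinate system.
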