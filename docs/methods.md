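# Methods

## The model

`invnet` treats lakes as nodes and builds two directed, weighted networks
over them.

**The angler network.** Every catch record carries a user, a timestamp and
one or two coordinate pairs (an exact location and/or an approximate one).
Catches are assigned to a lake when the point lies inside the polygon or
within 50 m of its boundary, trying the exact location first and the
approximate one only if that fails; only *fishable* lakes (surface area
strictly greater than 0.06 ha) participate. Assigned catches become
per-user visit sequences (consecutive same-lake, same-day records collapse
to one visit), and each consecutive pair of visits at different lakes is a
movement. A movement with whole-day gap *d* carries the survival-derived
time-decay weight

    w(d) = 1.023 / (1 + (d / 5.341)^1.031)   for d < 99 days,
    w(d) = 0                                 for d ≥ 99 days,

used verbatim: w(0) = 1.023 slightly exceeds 1 and is deliberately not
clipped, so aggregate weights reproduce the original arithmetic.
Zero-weight movements are discarded before aggregation. Movements implying
implausible travel (same-day > 250 km, next-day > 500 km, two-day
> 1,500 km — all strict inequalities) and movements between two lakes
sharing a name (case-folded, trimmed; a typical logging error) are removed.
Remaining movements are summed per *ordered* lake pair into directed edges;
an edge's weight is a propagule-pressure proxy and its geometry is the
straight line between lake midpoints.

**The hydrologic network.** Flowline segments connect lakes and junctions
strictly downstream. Lakes separated by less than 40 m of permanent
(perennial) stream — chains through junctions count their total length —
merge into one node represented by the largest-area member; member
midpoints move to the representative's centroid, and angler edges between
cluster members are deleted. Edges connect *first-order* downstream pairs
(no intermediate lake on the path) and carry a flow-permanence weight:
1.00 for perennial and unclassified streams, 0.75 for intermittent,
0.10 for ephemeral. Ditches, small canals, karst systems, pipelines and
underground conduits carry no edge. Two conventions were genuinely open
and are resolved here as follows: a multi-segment path through junctions
takes the **minimum** segment weight (the least-permanent link limits
passage), and braided channels that yield several paths for one pair
collapse to the **maximum** of those bottleneck weights (the best channel
governs). The downstream relation must be acyclic after merging; a cycle
is an input error and aborts the build.

**Comparison and statistics.** Components are weak (direction ignored for
membership); density is directed, m / n(n−1); reciprocity is the fraction
of directed edges whose reverse exists — structurally zero for the
hydrologic network. The diameter is the longest shortest path within the
largest component, by default with edge weight as traversal cost
(`weight_cost`; the non-integral diameters reported for such networks imply
weighted paths), with an unweighted `hops` mode and a directed variant
retained for sensitivity. Ties for the largest component break
deterministically by size then lexicographic node list. An angler edge is
*reinforced* if the same ordered pair is a hydro edge, *reciprocal
upstream* if its reverse is, and *novel* if neither direction is.

**Density mapping.** The raster follows the standard GIS line-density
definition: for each 5-km cell, the weighted length of edge segments
intersecting a 20-km search disk around the cell center divided by the
disk area (connections/km²). Segment–disk intersection lengths are exact
(quadratic solve), not sampled. The threshold step computes the 20th
percentile (linear interpolation) over cells with *positive* density —
including the vast zero background would make the cut vacuous — and
retains cells strictly above it; with 0% exclusion all positive cells are
retained, and if the threshold equals the raster maximum (uniform positive
raster) cells at the threshold are kept so ties at the top never empty the
map. Highways clipped to the union of retained cells (cell granularity, no
sub-cell interpolation) form the invasion superhighway. Band statistics
use cell-center distance to the *full* highway network, bands
(edge_{k−1}, edge_k] with the first band closed at 0 and the upper bound
closed (a 1e-9 km epsilon guards round-off at exact boundaries).

**Risk.** Lakes are invaded when an occurrence point of a taxon group
(dreissenid mussels, invasive watermilfoils) assigns to them under the
same 50-m rule; each occurrence marks at most one lake. Distances from
lake midpoints to the superhighway feed a Welch two-sample t-test of
invaded lakes against **all** lakes (the published comparison, reproduced
as such rather than invaded vs uninvaded), implemented from the closed
form with Welch–Satterthwaite degrees of freedom. High-risk edges run from
an invaded to an uninvaded lake; per county (destination lake midpoint),
the percentage of incoming weighted connections that are high-risk is
reported, with zero-inflow counties flagged no-data rather than 0% so low
risk is never fabricated. Because the raw-count vs weighted denominator
for the "share of movement at risk" is ambiguous, both are reported.
Superspreaders are the top-k invaded lakes per region by weighted
out-strength; vulnerable hubs the top-k uninvaded by weighted in-strength.

## Coordinate modes

`planar_km` (all synthetic data and tests) treats coordinates as
kilometres on a plane, making every distance exact and reproducible.
`geographic_lonlat` uses haversine great-circle point distances and a
Lambert cylindrical equal-area projection for rasterization; it is
provided for real lon/lat inputs but is not exercised by the synthetic
study system.

## The synthetic study system

The generator emulates the statistical structure the analysis assumes, at
a desk scale. Defaults define the study conditions: 500 lakes in a
400 × 400 km extent placed by a Thomas cluster process (parents at
1.5 / 10⁴ km², offspring σ = 20 km); log-normal lake areas with 5%
planted below the 0.06-ha cutoff and ~1% duplicated names; 200 anglers
with negative-binomial catch counts (mean 120, dispersion 1.5);
log-logistic inter-catch gaps with median 7 days (shape 1.6 — the decay
weight's log-logistic form motivates the family, and the shape keeps a
heavy right tail); next-lake choice with kernel (1 + d/s)^(−2.5) whose
scale s is calibrated by bisection so the realized hop-length median is
20 km; a downhill drainage forest (60% of lakes participate, nearest
lower-elevation neighbour within 40 km, 80% link probability) with
permanence classes drawn at 60/25/10/5% perennial/intermittent/ephemeral/
unclassified plus 5% excluded-class segments; 3 planted merge pairs;
invasions covering 15% of fishable lakes selected with probability
exp(−d/30 km) in distance to the nearest of 3 highway corridors; a 6 × 6
county grid and 3 basin strips.

Planted features exist so filters can be tested for *exactness*, and the
generator protects that exactness by construction: organic next-lake
choices are masked to distances slightly inside the travel-speed limits
for the realized day gap (245/490/1,470 km), so the k planted same-day
long hops (> 260 km, between unique-named fishable lakes, by dedicated
users) are the only violations; points placed more than 50 m outside any
lake are always a user's final catch, so dropping them can never splice
two remaining movements into a new, longer one; merge pairs are planted
between lakes outside the drainage forest (a merged cluster with
independent through-flow could make the collapsed flow relation cyclic,
which consistent hydrology never does), organic segments are floored at
100 m so only planted pairs sit under the 40-m rule, and anglers visit
fishable lakes only, so sub-minimum ponds exercise the area filter without
perturbing movement sequences.

What the generator does **not** emulate: realistic shorelines (lakes are
jittered buffered circles — sufficient for point-in-polygon and buffer
logic), river/stream catches (excluded from the analysis by design),
seasonal or angler-type heterogeneity in movement, terrain-driven
hydrology, and spatial autocorrelation in lake size. Passing tests
therefore demonstrate correctness of the pipeline's operations and
recovery of configured statistical structure, not fidelity to any real
landscape.

## Numerical choices and degenerate inputs

- Assignment ties (point within 50 m of several lakes): containing lake
  first, then smallest boundary distance, then lexicographic lake id —
  fully deterministic.
- Day gaps are whole-day calendar differences (timestamps truncated to
  dates), matching the day-based phrasing of the travel filters.
- "Sequential trips" means consecutive visit pairs per user, not all
  pairs within the 99-day window; the cutoff is exclusive at d = 99
  because the weight is zero there.
- Reciprocity of an empty edge set is 0 by convention (logged); the
  diameter of an empty graph is an error, reported as 0 in summaries of
  edgeless networks.
- An empty catch log yields an empty angler network and a zero raster
  (with a warning), not a crash.
- Percentile computation uses numpy's linear interpolation; all
  percentile/threshold comparisons are strict except the documented
  uniform-raster tie rule.
- Shortest paths run on scipy's sparse Dijkstra; the test suite checks
  them against a pure-Python Floyd–Warshall, and components against
  union-find.

## Problem sizes

Tests and the analysis scripts run the full system at the default scale
(500 lakes, ~24,000 movements, an 80 × 80 raster, a few seconds per run).
The directional invasion-proximity check uses 2,800 lakes so that at least
500 are invaded at 15–20% prevalence. Structural checks (acyclicity,
zero reciprocity) sweep 50 seeds at 40–60 lakes each. These sizes are the
package's chosen study conditions; statistics quoted in the README come
from these runs.

## Known limitations

- The merge rule reads "permanent stream" as the perennial class only;
  intermittent chains never trigger merging.
- Occurrence points mark at most one lake; multi-lake marking within the
  50-m buffer is conceivable but non-deterministic to attribute.
- County/basin assignment uses lake midpoints; a lake polygon straddling
  a boundary is attributed wholly to its midpoint's region.
- The geographic mode's equal-area projection is a single global choice;
  no attempt is made to match any particular GIS projection.
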