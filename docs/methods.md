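# Methods

This note documents the models, conventions and numerical choices behind
`sdmtools`, in the order a workflow meets them, and states what the
synthetic fixtures do and do not demonstrate.

## Raster model and conventions

All grids are rectangular lattices of square cells in planar (projected)
map units; no geodesic computation occurs anywhere (distance-based tools
assume the user supplies projected layers). A grid is (values, xll, yll,
cellsize, nodata), values stored north-to-south. Conventions, fixed and
relied on throughout:

* **Cell ownership** is half-open, `[x0, x0+cs) × [y0, y0+cs)`: a point on
  a shared vertical edge belongs to the eastern cell, on a shared
  horizontal edge to the northern cell. This makes point-in-cell lookup
  total and unambiguous.
* **ESRI ASCII** is written with corner-convention origins; `xllcenter`
  headers are accepted on read and normalised (corner = center − cs/2).
  Values are written with 17 significant digits, so a write/read roundtrip
  is exact for IEEE doubles.
* **GeoTIFF** is an adapter over tifffile (ModelPixelScale, ModelTiepoint,
  GDAL_NODATA tags); the CRS is carried as an opaque string and never
  interpreted. No reprojection or warping is offered.
* **Upscaling** aggregates factor×factor blocks with the chosen statistic,
  ignoring NoData; all-NoData blocks stay NoData; trailing partial blocks
  (when the factor does not divide the dimensions) are aggregated over
  their valid cells rather than dropped; majority/minority ties break to
  the smallest value, making results deterministic.

## Spatial rarefaction

Thinning is greedy, keep-first-in-input-order (optionally after a seeded
shuffle), per species: a candidate is kept iff it is at least *d* from
every already-kept conspecific point. The output is therefore a *maximal*
subset — no dropped point could be re-added — though not necessarily the
*maximum-cardinality* one; permuting input order can swap which maximal
subset is returned. Greedy thinning was chosen because it is the common
"spatial filtering" practice, is O(n·k), and is deterministic given the
input order and seed.

The multi-scale variant accepts up to five filter classes from an integer
raster; each point takes its own class's distance, and a pair spanning two
classes is governed by the **larger** of the two distances (the
conservative choice: fewer residual clusters). Filter sizes are distances
in map units; occurrences on unclassified/NoData cells are warned about
and filtered at the largest supplied distance rather than dropped.

## Background / bias surfaces

The four constructions share one geometric predicate: a template cell
belongs to the region iff the Euclidean distance from its center to the
generating geometry is ≤ the buffer. Hulls are shapely convex hulls, which
degrade gracefully (1 point → point → disk; 2 points or collinear → segment
→ capsule), so no degenerate special-casing is needed. Because the same
exact distance predicate is used everywhere (rather than rasterising a
polygonal approximation of circular arcs), two identities hold as exact
cell-set equalities, and are tested as such:

* α ≥ max pairwise distance ⇒ alpha hull ≡ buffered MCP;
* α < min pairwise distance ⇒ alpha hull ≡ union of per-point disks.

The "local adaptive convex hull" is realised as single-linkage clustering
at threshold α (strict: points merge only via chains of steps < α) with a
buffered hull per cluster. The Gaussian KDE surface is
Σᵢ exp(−dᵢ²/2h²) at cell centers, rescaled to max 1; cells below 1e−6 of
the maximum are excluded from the region entirely, since a MaxEnt bias
value must be positive wherever background sampling is allowed. All
surfaces are masked to the template's data cells.

## Spatial jackknifing and tuning

Occurrences are split into k ∈ [3, 5] groups: *segregated* mode clusters
coordinates with k-means (10 seeded restarts — deterministic given the
seed); *random* mode deals records round-robin after a seeded shuffle
(balanced to within one). The landscape is carved by assigning every data
cell to the group of its nearest occurrence (Voronoi cells dissolved by
group). Folds are leave-one-group-out; background for fold AUC is drawn
from the bias surface restricted to the training groups' regions
(probability ∝ bias weight, with replacement, 10 000 points by default,
seeded per fold), so the withheld region contributes neither presences nor
background to training-side quantities.

The candidate grid is RM list × the five canonical feature-class
combinations (complexity order L < LQ < H < LQH < LQHPT); with the
threshold class disabled the fifth combination is LQHP. OER uses a strict
`< threshold` comparison with the minimum-training-presence threshold by
default; AUC is the tie-aware Mann–Whitney statistic. Selection is
lexicographic (min OER, max AUC, min complexity rank, min RM, then
enumeration order), hence a total order and permutation-invariant. The
sample-size → feature-class mapping ("auto features": all classes ≥ 80;
LQH for 15–79; LQ for 10–14; L < 10) is exposed as an explicit emulation,
never applied silently.

The built-in scorer is a percentile envelope model: per layer, presences
define an envelope [p, 100−p]; a cell scores the fraction of layers whose
value falls inside. It exists so the whole pipeline (partition → folds →
train → threshold → OER/AUC → selection) runs and is testable without the
external MaxEnt program; RM maps to the trim (effective percentile =
p/RM) as the regularization analogue. For MaxEnt itself the package emits
a java batch file in the 3.4 flag dialect (one line per candidate × fold;
flag spellings centralised in one table).

## Post-processing

Binarization: cell = 1 iff score ≥ threshold; thresholds are fixed,
minimum training presence, or a percentile of training scores with linear
interpolation between order statistics. Clade splitting assigns each
presence cell to the clade of its nearest labelled occurrence (2–10
clades), giving pairwise-disjoint grids whose union is the input presence
set. Dispersal enforcement zeroes future suitability in cells farther than
d_max from every current presence cell center.

## Endemism and CANAPE

WE sums 1/(range size in cells) over the species present in a cell, so
each species contributes exactly 1 across the landscape (Σ WE = S, used as
an exact test); CWE = WE/richness, NoData where richness is 0. Ranges come
from binary SDM stacks, or from occupied cells via
`stack_from_occurrences` when no stack exists.

CANAPE consumes randomization tables produced externally (the
randomizations themselves are out of scope): per-cell rank-p fields for PE
on the original tree, PE on a comparison tree, and relative PE, each the
proportion of randomizations with observed ≥ random. The two-step rule —
significant iff either PE rank ≥ 0.95; then super iff both ≥ 0.99, neo iff
RPE rank ≤ 0.025, paleo iff ≥ 0.975, else mixed — follows the established
CANAPE procedure; all four thresholds and the expected column names are
configurable, since export conventions vary. The generic reclassifier
applies one- or two-tailed rank cuts at a user α to any field.

## Connectivity

8-connected lattice, edge weight = steplength × (costₐ + cost_b)/2 with
steplength cellsize (cardinal) or cellsize·√2 (diagonal) — the standard
GIS cost-distance convention. Cost-distance surfaces use sparse
multi-source Dijkstra (scipy.sparse.csgraph). Least-cost paths use an
in-package Dijkstra whose tie-break is explicit and deterministic: among
equal-cost paths, fewest steps, then the lexicographically smallest move
sequence (moves ordered N, NE, E, SE, S, SW, W, NW). Corridors are the
cellwise sum of the two endpoint cost-distance surfaces; the minimum of
that sum equals the LCP cost (checked to 1e−12 relative tolerance — the
two routes sum the same edge weights in different associations, so
equality is exact only up to float rounding). Disconnected pairs yield an
explicit unreachable result (infinite-cost sentinel in matrices), never an
exception mid-matrix. The "LCP distance" reported in pairwise matrices is
the along-path geographic length of the least-cost path, not the
straight-line separation of the endpoints.

## Synthetic fixtures: what they show and what they do not

The generators produce: a noiseless monotone gradient plus a
Gaussian-smoothed patchy layer (optional NoData border); Gaussian
occurrence clusters whose centers are spread along the gradient, so
spatially segregated groups also differ environmentally — the precondition
for the spatial-vs-random fold contrast; disk-shaped binary ranges;
a uniform cost surface with a high-cost wall pierced by one gap; and
randomization tables whose rank-p values are drawn inside ranges that make
each planted category unambiguous under the active thresholds. Everything
is deterministic under the spec seed.

Passing tests on these fixtures demonstrates algorithmic correctness
(geometry, bookkeeping, statistics, determinism) — not ecological realism:
real layers are collinear and noisy, real occurrence bias is not cleanly
clustered, and real randomization exports have richer column sets. The
directional claim verified here (spatial folds report more omission than
random folds under clustered sampling, 20 replicates) is a property of the
evaluation design, not of any species.

## Problem sizes

Tests and the acceptance script run on 100×100-cell landscapes, 30-point
occurrence sets, 4×4 exhaustive-oracle cost grids (100 instances),
and 20 jackknife replicates — sizes at which every brute-force oracle
(subset enumeration, path enumeration, cell scans) is exact and the whole
suite completes in seconds.
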