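# Methods

This note documents the models and procedures `geohab` implements, the
parameter choices that matter, the numerical conventions, and what the
synthetic-data tests do and do not establish.

## Raster model and preprocessing

A `Grid` is a cell-centered, north-up single-band raster: the origin is
the outer corner of cell (0, 0), row index increases southward, and all
distance computations use cell centers. ESRI ASCII grids round-trip
bit-exactly; GeoTIFF round-trips within float32 (the band is stored as
float32 with ModelPixelScale/ModelTiepoint/GDAL-nodata tags).

DEM preprocessing smooths sensor artifacts with a focal mean over a 10×10
window by default. An even window has no center cell; the output cell sits
at the upper-left of the central 2×2 block (window index `(w−1)//2`), the
usual GIS focal-statistics anchoring. Nodata cells are excluded from the
mean and only an entirely-nodata window propagates nodata. The filter's
kernel is a flat mean; a Gaussian option exists because "low-pass" admits
either reading — the mean is the default as the simplest neutral choice.
Mean resampling is restricted to coarsening (upsampling with a mean is
ill-defined); it preserves the global mean of nodata-free grids.

## Terrain derivatives

* **Relief** over a focal window (square, radius 5 cells by default —
  matching the 10-cell preprocessing scale; no canonical radius exists, so
  it is configurable). Two formulas: the classical range `max − min` and
  the default variant `√|max² − min²|`. The absolute value makes the root
  well-defined when elevations below sea level put `min² > max²`. For
  elevations ≥ 1 the variant dominates the range algebraically, which the
  property suite asserts.
* **TPI** is `z − mean(z_window)` with the center cell included in the
  mean (excluding it changes values by a factor `n/(n−1)` on the deviation
  and nothing qualitative; inclusion is the documented choice).
* **Normalized surface** is the global z-score of TPI, so slope-position
  breaks are scale-free. A constant TPI surface has no z-score and is
  rejected as degenerate.
* **Slope/aspect** use Horn's 8-neighbor finite differences (the standard
  GIS estimator); aspect is degrees clockwise from north with flat cells
  flagged by a −1 sentinel.
* **Slope position** buckets the normalized surface at ±1 sd (the
  conventional TPI break) into ridge/valley, with mid cells split by a 5°
  flat cutoff into slope vs toe-slope/flat. All three thresholds live in
  one config dict and are validated for completeness.

## D8 hydrology

Sink filling is priority-flood: a min-heap flood from the grid edge (and
from nodata cells, which act as drains) raises each cell to at most its
spill level — minimal filling, idempotent by construction. Flow direction
is single-neighbor steepest descent with drop/distance weighting
(diagonals √2·cellsize) and a fixed E, SE, S, SW, W, NW, N, NE scan as the
tie-break, so results are deterministic. Cells on flats (no lower
neighbor, some equal neighbor) are resolved by a breadth-first sweep from
already-draining cells across equal elevations, which routes every flat
toward its nearest spill and guarantees acyclicity; a remaining interior
sink is an error naming the cell. Grid-edge cells without a lower
neighbor drain off-grid and are outlets.

Accumulation counts upstream cells excluding the cell itself (the ESRI
convention), evaluated in topological order; the invariant
`acc = Σ_upstream (acc + 1)` and the outlet total `Σ(acc+1) = n_cells`
are asserted against a path-tracing oracle on random DEMs. Streams are
cells with accumulation ≥ a threshold (2 000 cells by default — the
main-ridge extraction setting; the unit is contributing cells, the one
plausible reading for a unitless threshold). Strahler orders are computed
per stream cell; two merging order-k links yield k+1. First-order divide
extraction pours a watershed at the downstream end of every order-1 link
and returns the cells where adjacent basins differ — the ridge-candidate
set bordering first-order streams.

## Wetland candidate rule

A cell is a candidate iff slope ≤ 5°, its center lies within 200 m
(Euclidean, to the nearest boundary vertex/segment of the lake polygon's
boundary line) of a lake, NDVI ∈ [−0.2, 0.3], and the cell is not inside
the lake. The rule is applied cell-wise inside the buffer rather than only
at stream inflow points: cell-wise evaluation subsumes the point-wise
check and is directly testable; inflow/outflow points are still reported
by `lake_inflow_points`. Candidates merge by 8-connectivity into polygons
carrying mean slope, mean NDVI, minimum lake distance and a `verdict`
attribute that an external review file can overwrite (imagery-based
verification is out of the toolkit's scope). Water is NDVI ≤ 0,
inclusive. Candidate counts are monotone in all three thresholds, which
the suite asserts.

## Diversity

Shannon `H = −Σ pᵢ ln pᵢ` (natural log; configurable base) per cell of a
2 000 m lattice. For occurrence points, `pᵢ` is the record-count share of
taxon i within the cell (a presence-only option collapses duplicates);
for a categorical landform raster, `pᵢ` is the cell-count share of each
class within the coarse cell — counts, not areas, since cells are equal
area. Cells are half-open (a point on the right/bottom edge belongs to
the next cell). Zonal aggregation reduces any raster over polygons by
cell-center membership.

## Taxonomy, classification rules, Peltier zonation, conservation value

The packaged taxonomy is a four-level hierarchy over seven groups
(Mountains, Plains, Fluvial landform, Coastal landform, Island,
Baekdudaegan, DMZ) with 7/16/36/77 types per category by the count table;
the prose total of 63 Category-4 types is carried alongside and reported
by the loader, since the two totals disagree in the source material. The
loader validates exactly one Category-1 type per group and a parent for
every finer type. Three Category-4 names could not be recovered from the
source tables and carry neutral names flagged `name_resolved: false`.

Cell classification evaluates YAML rules — conjunctions of comparisons
over named co-registered layers — highest priority wins, and unmatched
cells get an explicit `unclassified` code so classified + unclassified
always partition the valid area. The packaged default rule set is a
worked example for synthetic landscapes, not a national rule base.

Peltier zonation ships as an editable rectangular digitization of the
classical weathering-regime diagram in (mean annual temperature, annual
precipitation) space. The tests assert self-consistency of the packaged
config — the regions partition the envelope, labels are deterministic,
and a precipitation sweep crosses regions in the configured order — not
fidelity to the original 1950 figure.

The conservation engine looks combinations up in the packaged 13-row
criteria table. The table is not a total function; unprinted combinations
resolve conservatively: among printed rows with the same landform grade
and human impact whose diversity levels are each ≤ the query's, take the
worst (highest-numbered) value, flagged `extrapolated`. The policy can
never override a printed row, and at fixed grade and impact "None" the
result is monotone in biodiversity — both asserted exhaustively over all
81 combinations.

## Indicator species analysis

For presence/absence sites with a group assignment, the indicator value
of species s for group set C is `√(A·B)`: fidelity `B` is the occupied
share of C's sites; specificity `A` defaults to the group-size-corrected
form `Σ_{g∈C} mean_g / Σ_all mean_g` (group mean presences), so unequal
group sizes do not bias A — the variant used by the standard `multipatt`
workflow; the original site-count form is available via
`variant="indval"`. Both single-group and group-combination modes exist
(all proper subsets, matching the combination-enabled default of that
workflow). Significance permutes site labels, recomputing the best stat
per permutation, with `p = (1 + #{perm ≥ obs}) / (1 + n_perm)` (999
permutations by default, seedable). `n_perm="exact"` enumerates all
distinct label arrangements (feasible ≤ 10 sites) and returns the exact
tail share; the test suite checks it against an independently coded
enumeration oracle and checks Monte-Carlo p within 3 SE of exact. Ties
for a species' best group resolve to the lowest group index.

## Factor analysis

Extraction is principal components of the correlation matrix (not
maximum-likelihood factor analysis — the toolkit mirrors the
principal-component-rotation workflow common in habitat studies).
Variables flagged reverse-scored are negated before standardization, used
for variables whose raw sense runs against the rest of the battery (e.g.
elevation and precipitation against temperature indices) so their rotated
loadings come out positive. Components with eigenvalue ≥ 1 (Kaiser rule;
configurable) are retained and varimax-rotated (SVD form with Kaiser row
normalization). Reported per variable: rotated loadings, communality h2
(row sum of squared rotated loadings), uniqueness u2 = 1 − h2; per
factor: SS loadings, proportion and cumulative variance, ordered by SS
loadings and sign-aligned so each column's largest loading is positive.
Communality screening flags h2 < 0.3 ("0.3 or more" read as inclusive).

A caveat the test design accounts for: principal-component loadings
absorb part of the unique variance, inflating h2 above the generating
factor model's by roughly `(1 − h2)/m` for m variables per factor. The
recovery fixture therefore uses 6 variables per factor (18 variables,
3 factors, loadings 0.9, n = 2000), for which the population PC
communality is 0.842 — close enough to the model value 0.81 that
recovery is meaningfully tested; with 3 variables per factor the
inflation alone (population h2 0.873) would swamp the comparison.

## Synthetic landscapes: what they establish

Generators are pure functions of their spec and seed. DEMs are a dipping
plane plus isotropic Gaussian bumps (hills/basins) and extruded Gaussian
profiles (ridges/valleys), chosen for closed-form maxima; NDVI band pairs
are constructed as `red = (1−v)/2, nir = (1+v)/2` so the index equals the
requested zone mean exactly at zero noise; communities plant indicators
with occurrence probability `b` in their group and
`q = b(1−a)/(a(K−1))` elsewhere, making the expected group-mean
specificity equal `a`; environment tables follow `x = Lf + ε` with
standard-normal latent factors.

Passing on these fixtures establishes algorithmic correctness —
window statistics, flow routing, rule evaluation, permutation and
rotation machinery — under known ground truth. It does not establish
that the default thresholds (±1 sd breaks, 5° cutoffs, 2 000-cell
streams) delineate real habitats well: real terrain has autocorrelated
roughness, anisotropic landforms, data gaps and registration error that
Gaussian bumps and white noise do not emulate, and real communities have
abundance structure, spatial autocorrelation and detection error absent
from the Bernoulli planting model.

## Problem sizes and determinism

The shipped demo and test fixtures use 36×36-cell landscapes, 12–15-cell
oracle grids (200 and 50 replicates), 500-species null batteries at 199
permutations, and n = 2000 factor tables — sizes at which the exact
oracles (full window scans, path tracing, permutation enumeration) remain
exactly computable, which is the point of the fixtures. Every stochastic
path takes an explicit seed; reruns of the pipeline with the same config
are bit-identical for deterministic stages and identical in all reported
statistics for seeded stochastic ones.
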