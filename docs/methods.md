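# Methods

## Raster model and conventions

A landscape is a rectangular grid of integer land-cover codes with square
cells (default 10 m), a nodata code and a lower-left origin; row 0 is the
northernmost row, the ESRI ASCII grid convention. Cell centers sit at
`origin + (index + 0.5) · cell_size`, and every distance in the package is
measured between cell centers. The total landscape area A is the count of
non-nodata cells times the cell area; nodata cells are excluded from A,
from patch delineation and from diversity proportions. Class code 0 is the
non-green background by convention (configurable everywhere it matters).

## Patches and class-level metrics

A patch is a maximal set of same-class cells connected under 4- or
8-adjacency. The default is 8-neighbour, the FRAGSTATS convention; both are
supported and recorded in report provenance. Components are labelled with
`scipy.ndimage.label` per class and numbered by row-major first occurrence,
so patch ids — and therefore all downstream outputs — are bit-stable.

Patch area is `cells × cell_size²`. Patch perimeter is intrinsic: it counts
every exposed cell face, including faces on the raster boundary, because a
patch's shape does not depend on where the analysis window was cut.

The landscape edge total E is different: whether the raster boundary (and
faces against nodata) count as "edge" is a windowing choice, not a property
of the mosaic, so it is a flag (`include_boundary`, default off). Edges
between a class and the background are real land-cover transitions and are
always counted. ED and LSI use the same E policy for coherence.

Mean patch size at landscape level is `A/N/10⁴`, which makes
`PD × MPS = 100` an identity — a structural self-check the test suite
exercises. At class level the same reading of the defining formula would
divide the *whole* landscape area by a class's patch count; we instead use
`CA_i / n_i` (the class's own area over its patch count), which is the only
reading under which published class-level tables of this metric family are
internally consistent (e.g. CA 2286.76 ha at MPS 51.97 ha gives an integer
44 patches).

MPFD averages `2 ln(0.25 P_ij)/ln(a_ij)` over patches. The term is exactly
1 for squares and lies in [1, 2) for square-cell patches with cell_size ≥
2 m. Cell sizes that make `a_ij = 1 m²` or `P_ij/4 = 1 m` put a zero in a
logarithm; this raises a descriptive error rather than returning NaN.

## Landscape-level metrics

Diversity proportions P_k are class-area shares. At landscape level the
non-green background is included as a patch type by default (a two-class
green/non-green mosaic then has SHEI = SHDI/ln 2); a flag excludes it.
SHEI requires at least two types present (ln 1 = 0).

ENN follows the edge-cell convention: the distance between two patches is
the minimum center-to-center distance between their *edge cells* (cells
with at least one 4-neighbour outside the patch). This is up to
`cell_size/√2` coarser than true polygon edge-to-edge distance. The
landscape ENN is the unweighted mean over all patches that have a
same-class neighbour; a class with a single patch contributes nothing, and
if no class has two patches ENN (and CONNECT) are errors, not NaNs.

CONNECT uses the same pairwise distances: the percentage of same-class
patch pairs within a threshold. The threshold has no defensible universal
default, so it is a required argument of every report and is echoed into
the provenance sidecar (the CLI defaults to 100 m and prints that choice at
run start). CONNECT is non-decreasing in the threshold, which the property
tests verify.

## Network indices

An ecological network is nodes with planar coordinates (m) plus undirected
links with lengths in km. Validation enforces no self-loops, no duplicate
links between a node pair, and positive lengths. Link length precedence:
an explicit `length_km` attribute wins; otherwise the polyline arc length
(corridors follow roads and rivers, not chords); otherwise the node chord.

α, β, γ and the cost ratio are the classical planar-connectivity formulas
(see README). Graph connectivity is *not* required — the indices are
computed on the graph as given — and α is returned unclamped so that
non-planar inputs are visible. The cost ratio `1 − l/d` can be negative
when the mean corridor is shorter than 1 km; it is returned with a warning
rather than clamped. Display values are rounded half-up to 2 decimals (the
convention of published index tables); full precision is kept in the
record.

Of the published district index rows, the Changnan row and both cost
ratios are exactly the formulas evaluated at the printed counts and are
used as fixed checks. The Changbei α/β/γ cells are not reproducible from
the printed v = 44, l = 56 (the formulas give 0.16/1.27/0.44 against
printed 0.23/1.40/0.49), so the counts actually used there are
unrecoverable; those three cells carry no check.

## Corridor overlay

Corridors are polylines with one uniform width, default 40 m — motivated by
greenbelt guidance that belts over 30 m buffer noise effectively. A cell
belongs to the corridor iff its center lies within width/2 of any polyline
(round caps and joins; ties at exactly width/2 included). The center rule
was chosen over any-overlap because it is deterministic, resolution-
consistent and monotone in width. Corridor parts beyond the raster are
clipped silently (logged).

Overlay burns corridor cells that are not already green with a distinct
corridor class (so added green is accountable per class); a
`merge_green` flag collapses all green plus corridors into one class,
reproducing the merged landscape-level before/after experiment, which is
also what the CLI comparison uses. All other land uses become the single
non-green background; nodata is preserved. Overlay is idempotent, and
green area after equals green area before plus the area of the mask
outside prior green — both tested as exact identities.

## Synthetic data

The landscape generator is a random-cluster neutral landscape model: plant
`clumping` seed cells per class, then grow clusters by uniformly random
accretion of 4-adjacent free cells until each class reaches
`round(p · cells)` (within one cell of target). If a cluster is walled in,
a fresh seed is planted on free ground. This generator was chosen over
spectral/threshold models because seeds-per-class directly controls patch
count — the very quantity PD and MPS probe — giving a monotone
fragmentation dial (verified in simulation: PD with 20 seeds ≥ PD with
2 seeds in ≥ 95% of 100 seeded replicates). Each call uses one
`numpy` Generator seeded from the spec; identical specs give bit-identical
rasters.

The network generator places v nodes uniformly in the extent, takes
candidate links from the Delaunay triangulation (guaranteeing planarity and
no duplicates) and thins them at random to `floor(β·v)` links with chord
lengths in km. The reference district networks are built this way at a
frozen seed with the link count pinned to the published l, then scaled so
the summed link length equals the published d: only v, l and d are
faithful; the geometry is declared arbitrary, so geometry-dependent
quantities (corridor density without a district area) carry no claim.

What the synthetic landscapes do **not** emulate: real class proportions
and spatial autocorrelation of an actual city, rivers/roads as linear
constraints, multi-date change. Passing tests therefore demonstrate
correctness of the metric implementations and the qualitative behaviour of
the pipeline, not numeric agreement with any particular city's tables,
which would require the original (undeposited) maps.

## Problem sizes and tolerances

Oracle-equivalence tests run 100 seeded random landscapes up to 30×30
cells against exhaustive brute-force implementations (BFS flood fill, face
enumeration, all-pairs edge-cell distances); at these sizes exact equality
is asserted for counts/areas/perimeters/edges and `pytest.approx` defaults
for distances. The overlay direction checks (ΔPD ≤ 0, ΔMPS ≥ 0, ΔENN ≤ 0,
ΔCONNECT ≥ 0 for bridging corridors) use small hand-designed fixtures where
the expected topology change is provable by inspection. The whole suite
runs in a few seconds on one CPU.

## Known limitations

- No GeoTIFF/CRS support: ESRI ASCII grids and GeoJSON in a shared planar
  metric coordinate system only.
- ENN/CONNECT distances are cell-center based (see above), and the
  all-pairs implementation is quadratic in patch count — fine for district
  scale mosaics, slow for thousands of patches.
- The corridor buffer uses the cell-center rule; very narrow corridors
  (width below the cell spacing) can rasterize to nothing by design.
- Polygon-to-raster class assignment (majority vs. center rule) at the
  original 10 m resolution is unspecified upstream and irrelevant for the
  synthetic inputs, but would matter when reproducing a real map.
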