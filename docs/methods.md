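# Methods

This note documents the models and algorithms behind `phylohex`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical conventions.

## The hexagonal global grid (`phylohex.dggs`)

The grid follows the icosahedral aperture-7 hexagonal DGGS design
popularized by the H3 system. Cell centres at resolution *r* are the
Eisenstein-integer lattice points

    A + (m + nω)·u_r,   ω = e^{iπ/3},   u_r = (B − A) / (2(1+ω)(2+ω)^r)

laid gnomonically on each icosahedron face with projected corners A, B, C,
restricted to the closed face triangle. Because |2(1+ω)|² = 12 and
|2+ω|² = 7, resolution 0 is the 122-cell Goldberg grid and each further
resolution multiplies the cell count by seven (rotating the lattice by
asin√(3/28) ≈ 19.1°), giving 2 + 120·7^r cells with exactly twelve
pentagons at the icosahedron vertices. A divisibility argument shows face
edges carry lattice points only at their endpoints and midpoints; those are
owned by the lowest-indexed incident face, so the centre set is globally
consistent without seam bookkeeping.

Cells are defined as the **spherical Voronoi regions** of the centre set.
Point-to-cell assignment gathers candidate centres by exact integer
quantization on the three nearest faces and picks the nearest centre;
boundaries are computed by clipping half-planes in the gnomonic plane at
the cell centre (spherical bisectors project to straight lines there), so
areas and edge lengths are exact spherical quantities on the authalic
Earth sphere (R = 6371.0072 km). The test suite verifies that cell areas
sum to the full sphere to 1e-9 and that assignment matches a brute-force
nearest-centre search.

Consequences of the Voronoi definition worth knowing:

- Cell ids are this package's own 64-bit encoding (resolution, face,
  lattice coordinates), serialized as 16-character lowercase hex strings.
  They are *not* interchangeable with canonical H3 indexes, though the
  grid geometry matches H3's published constants (resolution 3: mean
  hexagon 12,393 km², mean edge 69.0 km; resolution 4: 1,770 km², 26.1 km;
  resolution 15 cells are below 1 m²).
- A handful of cells along icosahedron-edge seams can have 5 or 7
  boundary vertices instead of 6; interior cells (the overwhelming
  majority) are exact hexagons.
- As in every aperture-7 grid, children are not strictly nested in
  parents: `parent(cell(p, r+1)) == cell(p, r)` holds for cell centres
  always and for arbitrary points in roughly nine cases out of ten.

`grid_stats` enumerates cells exhaustively up to resolution 6 (beyond
that, cell count and mean area come from the closed forms); mean hexagon
area excludes the twelve pentagons, matching the convention of published
grid tables. Default binning resolution is 4; 3 and 4 are the practical
range for regional-to-global analyses.

## Occurrence cleaning (`phylohex.cleaning`)

Stages run in a fixed order — scope (taxon keys, country, bounding box,
years), record quality (basis of record, coordinate precision and
uncertainty), proximity to centroid/institution reference points, polygon
masks (keep-inside land, drop-inside urban), then per-species DBSCAN — on
the principle that cheap filters run first and the density-based outlier
detector sees already-cleaned data. Every stage appends (rows_in,
rows_removed, parameters) to the filter report, including explicit no-op
entries for disabled stages, and the report chain conserves row counts
exactly.

Conventions: year bounds and bounding boxes are closed intervals; rows
with missing year are dropped only when a year bound is active; rows with
missing precision/uncertainty survive those filters (dropping unknowns
would silently bias sparse datasets — the report records the convention);
records at exactly (0, 0) are flagged but kept unless strict mode is on.
Great-circle distances use the haversine formula on a sphere of
R = 6371.0088 km (the IUGG mean radius; the ~0.2% difference from an
ellipsoid is immaterial at the 1–1000 km radii involved). Point-in-polygon
tests count boundaries as inside. The default centroid/institution
exclusion radius is 2 km and is exposed on the CLI.

DBSCAN runs independently per species with great-circle distances
(scikit-learn, haversine metric); records labelled noise are removed.
Species with fewer than `min_pts` records cannot form a core point and are
exempt in full — a sparse range is not evidence of error. Reference
geodata are always user-supplied (GeoJSON for polygons, GeoJSON/CSV for
points); nothing is bundled.

## Trees and branch structures (`phylohex.phylo`)

Trees are used rooted as supplied; no re-rooting. The branch set is every
edge with a parent, plus the root edge when the source file assigns it a
length (it then counts toward total length and adds equally to every
cell's PD). Name matching is case-insensitive on the first two words of a
label (underscores and quotes normalized, authorship/infraspecific
suffixes dropped) or numeric after stripping an `ott` prefix; tips that
collide after normalization are an error. Pruning keeps the smallest
subtree containing the matched tips and the original root, collapsing
internal unifurcations with lengths summed, so tip-to-root path lengths
are invariant. The comparison tree sets every branch length to one; since
RPD/RPE use proportional lengths, the constant is immaterial.

## Indices (`phylohex.metrics`)

All indices are incidence-based (presence = at least one record; record
counts feed only the redundancy index). The implementation works on
boolean branch-membership matrices; the test suite proves it equivalent to
an independent brute-force oracle that enumerates tip-to-root paths and
branch ranges explicitly, on over a hundred random instances, and checks
the conservation identities Σ WE = S and Σ PE = total tree length.
`pe_cwe`, the PD-corrected endemism, is PE/PD of the same cell — the
established corrected variant. Both absolute and proportional PD/PE
columns are emitted since conventions differ between tools.

## Randomization null model (`phylohex.nullmodel`)

Each draw preserves, exactly, the species richness of every cell *and* the
range size of every species. (The classic richness-preserving shuffle is
documented only by its richness contract; preserving both marginals is the
behaviour of the reference implementation family and is adopted here —
prominently, since it determines which indices have degenerate nulls:
richness by construction, WE/CWE in arrangement only.) The algorithm
places species in descending range order into distinct cells sampled with
probability proportional to remaining richness capacity, then repairs any
overflow by moving species from over-full to under-full cells (bounded at
10⁴ swaps; a failed repair rejects and redraws the iteration from a fresh
substream). With spatial constraints the shuffle runs independently within
each cell group, so species stay inside the regions they occupy.

Chunks are seeded counter-style from (base_seed, chunk_index) and merge by
summation: a run is bit-identical for a fixed seed and chunk count, and
chunk layouts agree in distribution. Null summaries are streamed (n, Σ,
Σ², tail counts), so memory is independent of the iteration count. SES
uses the unbiased null standard deviation and is null when the variance is
zero; p-values are add-one ranks, p = (1 + tail count)/(1 + n), with ties
(within 1e-9 relative) counted in both tails — the standard conservative
permutation convention, bounding p away from zero. The CLI default is 999
iterations; 5000 is the documented setting for full-scale reproductions.

## CANAPE (`phylohex.canape`)

Candidates are cells whose PE on the observed tree *or* on the comparison
tree is significantly high one-tailed at α = 0.05; candidates split by the
RPE tails at 0.025 per side into paleo (high) and neo (low), the remainder
is mixed, upgraded to super when both PE forms are high at 0.01. The
thresholds follow the original CANAPE protocol and are all CLI-exposed.
The labels partition the cells by construction. The candidate gate is a
union of two one-sided 5% tests on strongly correlated statistics, so on
truly structureless data it fires in roughly 5–10% of cells, not exactly
5% — the background-scenario test asserts that range.

## Synthetic data (`phylohex.fixtures`)

Generators are deterministic under their seeds and exist to make every
stage testable without downloads:

- `gen_occurrences` draws species ranges as isotropic Gaussian clouds
  (default sd 100 km) around uniform centres, with optional contamination —
  exact duplicates at centroid points, records displaced a fixed 2,000 km
  from their species centre, fossil records — all recorded row-by-row in a
  ground-truth manifest. The Gaussian model is chosen for the analytic
  tractability of planted-outlier distances, not as a biological claim; it
  emulates neither real GBIF sampling bias (beyond record-count skew) nor
  range-shape complexity, so passing cleaning tests demonstrate filter
  correctness, not field performance.
- `gen_tree` simulates a Yule tree (birth rate 1, ultrametric, tips
  `Sp0001…`).
- `gen_endemism_scenario` plants a known signal in a 4.5° × 4.5° region of
  a 15° × 15° domain: 40 widespread background species (sd 600 km, 50
  records each) plus 16 narrow-range endemics (sd 50 km, 30 records). In
  the *neo* scenario each endemic is a very recent split (terminal branch
  0.02 of tree depth 1) from a widespread background sister, so its only
  range-restricted branch is short — planting a clade with a long
  restricted stem would read, correctly, as paleo-endemism. In the *paleo*
  scenario each endemic is an anciently isolated pendant of length 1.25 at
  the root. The *background* scenario has no endemics and calibrates the
  false-positive side.
- `gen_null_community` builds a random incidence matrix (200 cells × 30
  species, fill 0.35) with a richness floor of 5 for type-I calibration:
  in cells with one or two species the randomization null of PD is
  supported on a handful of values, and tie-counting then makes rank
  p-values strongly conservative; the floor keeps the null effectively
  continuous so the nominal rate is meaningful.

## Problem sizes and runtimes

The test suite (≈180 tests) runs in about a minute on one CPU: oracle
equivalence uses 100 random 10-tip × 8-cell instances; the null-model
contract checks 1,000 draws; calibration uses 999 iterations on the
200-cell community; CANAPE recovery uses 199 iterations per scenario.
`scripts/acceptance.py` (≈2 minutes) additionally enumerates the full
resolution-4 grid (288,122 cells) and runs the scenarios at 999
iterations. These sizes were chosen as the smallest at which the
Monte-Carlo assertions are stable.

## Known limitations

- Grid cell ids are package-specific; canonical H3 interoperability would
  require the H3 indexing tables. Seam cells may deviate from perfect
  hexagonality (above).
- Reference geodata I/O is GeoJSON/CSV; other OGC formats need external
  conversion. The GeoPackage writer emits the minimal conformant core
  (single feature layer, EPSG:4326).
- Abundance-weighted indices are out of scope by design; presence is
  binary.
- Name matching is exact after normalization — no fuzzy matching against
  taxonomies, no name-resolution services. Higher-taxon scoping requires a
  user-supplied taxon→species-key table.
- The interactive map references the Leaflet library and basemap tiles by
  URL; the data are embedded, the cartography needs network access.
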