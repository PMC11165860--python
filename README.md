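# phylohex

Spatial phylogenetics from raw species-occurrence records: clean and filter
the records, bin them into hexagonal grid cells, reconcile them with a
phylogeny, compute per-cell diversity and endemism indices with
randomization-based significance, classify cells by endemism type (CANAPE),
and export GIS-ready layers and interactive maps.

The package is aimed at biogeographers and macroecologists who have a
Darwin-Core-style occurrence table (e.g. a GBIF export in Parquet or CSV)
and a rooted, branch-length-bearing tree (Newick or Nexus), and want the
standard spatial-phylogenetics battery without stitching together half a
dozen tools.

## The indices

For a grid cell with species set *C* on a rooted tree with branch set *B*,
branch lengths *L<sub>b</sub>* and per-branch occupied-cell ranges
*R<sub>b</sub>* (the number of cells containing at least one descendant of
*b*):

| index | definition | reads as |
|---|---|---|
| richness | \|C\| | species count |
| PD | Σ *L<sub>b</sub>* over branches on the tip-to-root paths of *C* | Faith's phylogenetic diversity |
| RPD | PD<sub>P</sub>(tree) / PD<sub>P</sub>(unit-length tree) | excess of long vs short branches |
| WE | Σ<sub>s∈C</sub> 1/range(s) | weighted endemism |
| CWE | WE / richness | range-restriction corrected for richness |
| PE | Σ *L<sub>b</sub>*/*R<sub>b</sub>* over the same branch union | PD "owned" by the cell |
| RPE | PE<sub>P</sub>(tree) / PE<sub>P</sub>(unit-length tree) | rare-branch length bias |
| redundancy | 1 − richness/records | sampling-completeness proxy |

Subscript *P* marks proportional (fraction-of-total-tree-length) forms.
WE and absolute PE obey conservation laws — summed over all cells they
equal the species count and the total tree length — which the test suite
asserts to 1e-9.

Significance comes from a richness- and range-preserving randomization of
the cell × species matrix (optionally constrained within user polygons,
e.g. biomes): standardized effect sizes (SES) and add-one rank p-values per
cell and index. CANAPE then classifies each cell as `not_significant`,
`neo`, `paleo`, `mixed` or `super` endemism from the one-tailed significance
of PE, PE on the unit-branch-length comparison tree, and RPE.

Binning uses an icosahedral aperture-7 hexagonal discrete global grid
(resolutions 0–15, cell count 2 + 120·7^r, twelve pentagons per
resolution) implemented in `phylohex.dggs`; at the default working
resolutions 3 and 4 the mean hexagon is ≈12,393 km² (edge ≈69 km) and
≈1,770 km² (edge ≈26 km).

## Worked example

The hand-checkable toy: tree `((A:1,B:1)E:1,(C:1,D:1)F:1)` with three cells
c1 = {A,B} (3 records), c2 = {B,C} (2 records), c3 = {D} (1 record).

```python
from phylohex import fixtures, metrics

toy = fixtures.toy_example()
table = metrics.compute_all(toy["matrix"], toy["tree"], tip_to_key=toy["tip_to_key"])
cols = ["richness", "records", "pd", "pd_p", "we", "cwe", "pe", "rpe", "redundancy"]
print(table.loc[toy["cells"], cols].round(4).to_string())
```

```
                  richness  records   pd    pd_p   we   cwe   pe  rpe  redundancy
cell
0249fffefd000046         2        3  3.0  0.5000  1.5  0.75  2.0  1.0      0.3333
0249fffeaf000058         2        2  4.0  0.6667  1.5  0.75  2.5  1.0      0.0000
0249fffedb0000a4         1        1  2.0  0.3333  1.0  1.00  1.5  1.0      0.0000
```

c1 spans branches A, B and E, so PD = 3 of the total 6 (pd_p = 0.5); its PE
down-weights B and E by their two-cell ranges (1 + ½ + ½ = 2.0); with two
species in three records its redundancy is 1 − 2/3 = 0.333. RPE is 1
everywhere because all branch lengths are equal. Summing the `pe` column
gives 6.0 — the whole tree length — and `we` sums to 4, the species count.

## Command line

```bash
phylohex --input occurrences.parquet --phytree tree.nwk \
         --country "AU" --minyear 1950 --basisofrecordexclude "FOSSIL_SPECIMEN" \
         --dbscan --dbscanepskm 500 --dbscanminpts 20 \
         --resolution 4 --iterations 999 --seed 42 --outdir results/
```

writes, per stage: the filtered table and per-stage filter report, the
presence matrix, pruned and comparison trees, `metrics.csv`,
`significance.csv`, the combined `results.csv`, an EPSG:4326 GeoPackage
(`results.gpkg`, opens in QGIS), an interactive Leaflet map (`map.html`)
with one toggleable layer per index and per-cell hover values, a
data-provider provenance report, and a JSON run manifest with all seeds and
settings. Reference geodata (centroids, institutions, land/urban polygons,
randomization-constraint regions) are user-supplied GeoJSON/CSV inputs.

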