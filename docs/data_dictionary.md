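# Data dictionary

## species_table.tsv (pipeline output)

| column | units | meaning |
|---|---|---|
| species_id | — | species identifier (`sp001`, ...) |
| n_sequences | count | focal haplotypes on the gene tree |
| flagged | bool | true when < 3 haplotypes (cluster count fixed at 1) |
| n_clusters_0.9 / _0.8 / _0.7 | count | Bayesian cluster count at each co-assignment probability threshold |
| crown_age | Myr | depth of the MRCA of the species' haplotypes |
| stem_age | Myr | depth of the MRCA of haplotypes plus sister lineage |
| n_clusters_true | count | generator ground truth (synthetic runs only) |
| lat_midpoint / abs_lat_midpoint | degrees | latitudinal midpoint (signed / absolute) |
| n_clusters | count | cluster count at the reporting threshold (default 0.9) |
| splitting_rate_stem / _crown | /Myr | pure-birth rate ln(N)/t at stem / crown age |
| lineage_loss | — | (stem − crown)/stem |
| crown_branch_index | /Myr | N/crown (or crown/N with the inverted convention) |
| stem_branch_length | Myr | stem − crown |
| crown_index_exceeds_stem | bool | crown index > stem branch length |

## pgls_summary.tsv

One row per response variable (phylogeographic structure, crown/stem age,
stem/crown splitting rate, lineage loss; counts and ages enter square-root
transformed): latitude coefficient and p-value, fitted Pagel's λ, adjusted
R², AICc, randomization-null p and its <5% significance flag.

## Occurrence / range / morphology tables (synthetic inputs)

* `records.tsv`: species_id, lat, lon (degrees), duration_hr, distance_km,
  one column per environmental layer (cell value at the record).
* `ranges.tsv`: species_id, lon_min/lon_max/lat_min/lat_max (degrees),
  range_size_km2, elevation_min/max (m), breeding/wintering latitudinal
  midpoints (degrees), migratory flag.
* `morphology.tsv`: specimen_id, species_id, wing_length_mm,
  secondary_length_mm, tarsus_length_mm.

## Grids

ESRI ASCII rasters (`ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value`
header); values as named (`structure_mean.asc` = per-pixel mean cluster
count over species present).
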