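# geohab

Hierarchical landform-to-habitat delineation for landscape ecology: a
toolkit that turns a digital elevation model (plus spectral bands, species
occurrences and environmental tables) into a habitat classification with
diversity surfaces, indicator species and conservation grades.

Biological communities track topography: ridges, valleys, lake margins and
plains host different species pools, so a habitat inventory starts from a
geomorphometric classification of the terrain. `geohab` implements that
chain end to end:

1. **Raster preprocessing** — ESRI ASCII grid / GeoTIFF I/O, focal low-pass
   smoothing (10×10 default) and mean/nearest resampling.
2. **Terrain derivatives** — local relief (both the classical range
   `max − min` and the variant `√|max² − min²|`, which is the default),
   topographic position index `TPI = z − mean(z_neighborhood)`, its global
   z-score ("normalized surface"), Horn slope/aspect, and a four-class
   slope-position map (ridge / slope / toe slope / valley, ±1 sd breaks).
3. **D8 hydrology** — priority-flood sink filling, steepest-descent flow
   direction, flow accumulation, threshold stream networks with Strahler
   orders (default threshold 2 000 cells), watershed delineation and
   first-order-stream divide extraction (the main-ridge operation).
4. **Wetland candidates** — `NDVI = (NIR − R)/(NIR + R)`, water masking at
   NDVI ≤ 0, and the lake-margin rule: slope ≤ 5°, within 200 m of a lake
   boundary, NDVI ∈ [−0.2, 0.3].
5. **Diversity grids** — Shannon `H = −Σ pᵢ ln pᵢ` of species occurrences
   (biodiversity) or landform classes (geodiversity) on a 2 000 m lattice,
   with zonal aggregation onto polygons.
6. **Habitat taxonomy and rules** — a packaged four-level landform
   taxonomy (7/16/36 types in Categories 1–3), YAML rule–driven cell
   classification, Peltier weathering zonation from (T, P) climate grids,
   and a 13-row conservation-value engine grading units I (absolute
   conservation) / II (transition) / III (coexistence with humans).
7. **Community statistics** — indicator species analysis
   (`IndVal = √(A·B)`, group-size-corrected specificity A and fidelity B,
   permutation p-values, exact enumeration for small communities) and
   principal-component factor analysis with Kaiser retention
   (eigenvalue ≥ 1), varimax rotation, reverse scoring and communalities.
8. **Pipeline** — one YAML config runs all stages with a JSON manifest;
   a seeded synthetic-landscape generator (Gaussian hills, ridges,
   valleys, closed basins, controlled NDVI, planted indicator communities,
   known factor structure) makes every stage testable without downloads.

## Worked example

```sh
geohab run examples/demo.yml --outdir demo_run
```

builds a 36×36 synthetic landscape (hill + incised valley + closed basin
on a south-dipping plane) and prints, among other output:

```
stages completed: 8/8

Category totals: C1=7, C2=16, C3=36, C4=77

Significant indicator species: 7
group
1    2
2    2
3    3

Wetland candidates: 5

Conservation value shares: I: 0.44, II: 0.50, III: 0.06
```

Reading this: the packaged taxonomy counts 7 landform types at the
coarsest category and 16/36/77 at the finer ones; the permutation test
recovered the 2 indicator species planted per community group (plus one
noise species at α = 0.05); five lake-margin wetland candidates passed
the slope/distance/NDVI rule; and grading each 2 km diversity cell with
the conservation table split the landscape 44 % absolute conservation,
50 % transition, 6 % coexistence. The factor analysis table (also
printed) retains three components with communalities ≥ 0.6 for all 11
environment variables.

Library use mirrors the CLI:

```python
from geohab import (LandscapeSpec, Feature, make_dem, fill_sinks,
                    d8_flow_direction, flow_accumulation, extract_streams)

dem = make_dem(LandscapeSpec(features=[Feature("hill", (32, 32), 100, 300)]))
fdir = d8_flow_direction(fill_sinks(dem))
net = extract_streams(flow_accumulation(fdir), fdir, threshold=50)
print(net.n_stream_cells)   # 244
```

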