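# geobia

Object-based land-cover analysis (GEOBIA) for high-resolution riparian
imagery, with two additions that are rarely combined in one pipeline:

1. **Gabor texture fusion** — a bank of complex Gabor filters (4
   orientations × 4 wavelengths) applied to the grayscale band average;
   the 16 magnitude responses are smoothed, z-scored and reduced to
   their first principal component, which joins NDVI and the canopy
   height model (CHM) as a segmentation and classification layer.
2. **Hierarchical class context** — a two-level watershed segmentation
   (sub- and super-objects from one watershed partition, different
   merge levels); super-objects are classified on a broad 7-class
   scheme, rasterized, and attached to each sub-object by majority
   overlap as an extra categorical feature for the fine 13-class
   classification.

Because sub-meter aerial imagery with expert-delineated reference
polygons is rarely shareable, the package ships a synthetic scene
generator that emulates a riparian mosaic: nested 7/13-class Voronoi
patch maps, class-specific band reflectances with noise, class-specific
directional sinusoid textures (exactly what a Gabor bank detects), and
class-specific canopy heights. The full factorial comparison
(±Gabor × ±hierarchy) runs end-to-end on these scenes with no external
data.

## Method core

* **Watershed (intensity method).** The per-pixel mean of min–max
  normalized layers is flooded; regional minima whose *dynamics* (basin
  depth at the first saddle to a deeper basin) reach the `scale`-th
  percentile of the minima-depth distribution seed basins.
* **Full lambda schedule.** Adjacent objects $O_i, O_j$ with per-layer
  mean vectors $u_i, u_j$ merge greedily in order of the cost

  $$t_{i,j} = \frac{\frac{|O_i|\,|O_j|}{|O_i|+|O_j|}\;\lVert u_i-u_j\rVert^2}{\mathrm{length}(\partial(O_i,O_j))}$$

  while the global minimum stays below a threshold set by the
  `merge_level` percentile of the initial cost distribution. Sub- and
  super-objects differ only in merge level.
* **Random forest.** 250 trees, `mtry = floor(p/3)`; accuracy is the
  out-of-bag (OOB) error; variable importance is reported as mean
  decrease in accuracy (per-tree OOB permutation) and mean decrease in
  Gini impurity.
* **Assessment.** PR (percentage of right segmented pixels) against the
  truth map, and FRAGSTATS-style landscape metrics (NP, AREA, FRAC,
  PARA; area-weighted means and SDs) on the classified rasters.

## Worked example

```bash
geobia run --seed 1 --out results/demo
```

runs all six arms on a default 192×192 synthetic scene (40 patches) and
prints, for seed 1:

```
"sub-G-H": {"oob_error": 0.3278, "pr": 55.74}
"sub-G+H": {"oob_error": 0.2748, "pr": 55.74}
"sub+G-H": {"oob_error": 0.2273, "pr": 81.27}
"sub+G+H": {"oob_error": 0.1477, "pr": 81.27}
```

Reading: `-G/+G` is without/with the Gabor PC1 feature, `-H/+H` without/
with the hierarchy attribute. On this scene the hierarchy attribute
lowers the 13-class OOB error in both Gabor conditions (32.8→27.5 % and
22.7→14.8 %), and the Gabor band improves both segmentation quality
(PR 55.7→81.3 %) and classification. `results/demo/` holds the per-arm
tables (`table_super.csv`, `table_sub.csv`, `table_metrics.csv` with the
NP/AREA/FRAC/PARA columns) and a `manifest.json` that reproduces the run
exactly.

The library surface mirrors the pipeline: `geobia.scene` (synthesis),
`geobia.features` (NDVI/CHM/grayscale/intensity), `geobia.gabor`,
`geobia.segmentation`, `geobia.objects`, `geobia.rf`,
`geobia.evaluation`, `geobia.experiment`.

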