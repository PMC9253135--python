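# Methods

This note documents the models and conventions the package implements,
the defaults it ships, and why they were chosen. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic scenes

A scene is a Voronoi tessellation of `n_patches` random sites on a
`height × width` grid; each patch carries one of the 13 sub-classes (the
first 13 sites cover every class once, in seeded random order; the rest
draw uniformly), and the 7-class truth follows from the fixed parent
map. Pixels are class mean reflectance + an additive class-specific
directional sinusoid (shared across the three bands so the grayscale
average preserves it) + i.i.d. Gaussian noise; canopy height is class
mean + Gaussian noise, clamped at 0 m. Generation is a pure function of
(scheme, appearance, dimensions, seed).

The default appearance table encodes the usual spectral ordering
(vegetation bright in NIR/dark in red, water dark, bare surfaces flat
across bands) with pixel noise SDs of 0.03–0.10 and deliberately close
cross-parent pairs — wet meadow vs. grass/forbs, wet shrub vs.
scrub-shrub, road/levee vs. sand/mud — because riparian classes of
different parents genuinely overlap spectrally and this is the confusion
that coarser-scale context can resolve. Forest classes carry the
strongest textures and tallest canopies.

What the generator does **not** emulate: within-patch spectral
gradients, shadows, sensor PSF/georeferencing artifacts, spatial
autocorrelation of noise, mixed pixels, and any real landscape's class
composition. Passing tests therefore demonstrate the pipeline's
mechanics and the direction of the hierarchy effect under controlled
separability, not performance on real imagery.

The *showcase* scene is a constructed best case for the hierarchy
mechanism: sub-classes are spectrally identical within each parent;
parent means sit on a tight ladder (steps of 0.012/0.010 in NIR/red
against pixel noise SD 0.15) so parent identity is ambiguous for small
objects but recoverable by spatial averaging over large ones; and canopy
height tiers (0.5/6/14 m) repeat across parents, identifying the
sub-class *within* a parent without revealing the parent.

## Gabor stage

Frequency-domain filter
`G(u,v) = exp(-π²/f² [γ²(u'-f)² + n² v'²])` with `f = 1/wavelength`;
spatially this is a Gaussian envelope (SDs `γλ/√2` along the wave and
`nλ/√2` across it) times a complex carrier. Defaults:

* wavelengths 2.82842712475, 7.0710678, 17.6776695, 44.19417382 pixels;
  orientations 0°, 45°, 90°, 135° → 16 filters, orientation-major order;
* `γ = n` set by the 1-octave half-response bandwidth design
  (`σ ≈ 0.56 λ`), the classical filter-bank convention, since no
  numeric value is otherwise prescribed;
* kernels truncated at 3σ, re-centred to exactly zero mean (so constant
  images give zero magnitude) and normalized by the envelope mass;
* per-filter Gaussian smoothing of the magnitude, `σ = wavelength/2`
  (common practice for Gabor energy features), applied **before**
  z-scoring the 16 bands; PCA runs on the z-scored stack and each
  component's sign is fixed by its first non-zero loading.

Tiling: tiles are padded by `overlap ≥ ceil(3·σ_max)` pixels of real
image data, so mosaicked interiors equal a whole-image computation to
floating-point tolerance; image borders use edge padding.

## Segmentation

* **Scale.** Basin markers are regional minima whose *dynamics* (depth
  at the first saddle to a deeper basin, computed by a union-find
  flooding sweep) reach the `scale`-th percentile of the minima-depth
  distribution. A raw intensity-percentile depth was tried first and
  rejected: on any scene whose intensity spans its full range the
  suppression depth dwarfs every noise basin and all scales collapse to
  1–3 segments. The percentile-of-dynamics rule keeps the 0–100
  interface, is exactly monotone (segment count non-increasing in
  scale), and adapts to the image's noise floor.
* **Merging.** Threshold = `merge_level`-th percentile of the initial
  lambda-cost distribution; merges proceed while the global minimum cost
  is ≤ threshold; `merge_level = 0` disables merging entirely (so a
  zero-cost pair still merges at any positive level). Ties on the
  minimum break on the lexicographically smaller label pair; the merged
  region keeps the smaller label. The priority-queue implementation with
  lazy invalidation is verified against a brute-force oracle that
  rescans all adjacent pairs each step.
* Regions are 4-connected; boundary length counts shared pixel edges and
  is additive under merging. Both hierarchy levels start from one
  watershed partition and differ only in merge level, so boundaries may
  shift between levels but the super level never has more segments.

## Objects and classification

Per-object features: area, perimeter (exposed pixel edges), compactness
`4πa/p²`, elongation (square root of the eigenvalue ratio of the pixel
coordinate covariance, regularized by the 1/12-pixel variance so a
single pixel scores 1), and mean + population SD of every feature layer
(nir, red, green, ndvi, chm, optionally gabor_pc1). Labels transfer by
majority pixel overlap; exact ties go to the lowest class index;
segments wholly outside valid reference pixels are excluded from
training. The hierarchy attribute is the majority-overlap class of the
rasterized super-object classification, one-hot encoded (sorted category
order) for the forest.

The forest is scikit-learn's `RandomForestClassifier` (250 trees,
`mtry = floor(p/3)`, no class weights, seeded); the package owns OOB
accounting (predictions only from trees whose bootstrap excluded the
sample) and both importance indices — mean decrease in accuracy as the
classical per-tree OOB permutation average, and mean decrease in Gini as
impurity importance. Super-object predictions used for attachment are
the fitted model's predictions on all super-objects; an
`honest_hierarchy` option switches to OOB predictions to quantify the
optimism this may introduce.

## Assessment

PR is defined as percent-*correct* (pixel agreement between the painted
classification and truth), consistent with the metric's name; truth
nodata pixels are excluded. Patches are 8-connected by default (the
FRAGSTATS convention; 4 available); perimeters always count exposed
4-neighbor edges. `FRAC = 2 ln(0.25 p)/ln(a)` with FRAC = 1 for
single-cell patches (undefined log ratio), `PARA = p/a`; AM is the
area-weighted mean, SD the unweighted population SD (a weighted option
exists).

## Experiment defaults and problem sizes

Default factorial: 192×192 scene, 40 patches, scale 30, merge levels
80 (sub) / 90 (super) for both Gabor conditions — chosen in a design
pilot to yield a few hundred sub-objects and ~100 super-objects (object
counts comparable, after scaling, to a segmentation of real imagery) and
seconds-scale arms. The published ENVI parameterizations (scale 30 with
merges 95/95.7; scale 10 with merges 95.6/98.5) are accepted verbatim by
`build_hierarchy` and recorded in run manifests, but ENVI's scale/merge
semantics are proprietary, so numeric parameter values do not transfer;
bit-compatibility with ENVI is explicitly not claimed. Acceptance
replication uses five seeded scenes; all randomness flows from explicit
seeds and reruns are bit-identical.

Note that the +H and −H sub arms share one segmentation, so their PR
coincides here: in-bag forest predictions on training objects are
near-exact, making the painted maps identical. PR differences are
informative across segmentations (the ±Gabor contrast), not across
feature sets.

## Known limitations

* ENVI/FRAGSTATS numeric compatibility is out of scope; parameter
  interfaces and formulas follow public definitions.
* The PR measure inherits its known weakness: it scores classification
  agreement, not boundary quality.
* MDA values are unscaled mean decreases (no division by their SD).
* Scenes are raster-only; no vector reference polygons are produced.
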