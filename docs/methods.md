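# Methods

## Problem and model

The package turns an unsupervised land-cover clustering into a survey-priority
("prospectivity") map for fossil hunting. The input is a georeferenced
multiband raster — nominally Landsat 8 OLI surface reflectance with seven
bands (ultrablue, blue, green, red, NIR, SWIR1, SWIR2) at 30 m — cropped to a
rectangular area of interest, plus a catalog of point records: known
fossil-bearing localities (vertebrate+invertebrate, invertebrate-only, fossil
wood, single vertebrate finds) and surveyed non-localities. A "site" is
identified with the single 30 × 30 m grid cell containing its centroid.

Each pixel is a vector x_i ∈ R^B of band values. k-means partitions the
pixels by minimizing the within-cluster sum of squares

    WCSS = Σ_{j=1..k} Σ_{i ∈ cluster j} ‖x_i − μ_j‖²,

via Lloyd's alternation: assign every pixel to its nearest centroid
(squared Euclidean distance; exact ties go to the lowest cluster index), then
recompute each centroid as the mean of its members. Iteration stops when the
relative change |WCSS − WCSS′| / WCSS drops to ε or after `max_iter`
iterations. Clustering is followed by retroactive supervision: the cluster
containing the most verifiable fossil-bearing sites becomes the positive
class of a binary classifier ("walking back the cat"); all other clusters are
merged into the negative class. Verifiable fossil sites and non-localities
then yield TP/FP/FN/TN and the five standard metrics (accuracy, precision,
NPV, sensitivity, specificity), each reported as UNDEFINED (NaN) when its
denominator is zero. Area statistics (positive-pixel count, fraction of the
AOI, km²) quantify the survey-area reduction.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 8 | number of spectral clusters |
| `epsilon` | 1e-6 | relative WCSS-change stopping threshold (unitless) |
| `max_iter` | 100 | Lloyd iteration cap per restart |
| `n_restarts` | 10 | independent seeded initializations; best final WCSS kept |
| `init` | `kmeans++` | centroid seeding (`random_points` = Forgy also available) |
| `standardize` | off | per-band z-scoring before clustering |
| `n_trees` | 500 | trees in the importance ensemble |
| `features_per_split` | ⌊√B⌋ | candidate bands per tree split |
| `n_pixels_subsample` | 20,000 | stratified cap on ensemble training pixels |

ε is defined on the *relative* WCSS change so that raw digital numbers and
0–1 reflectance behave identically. Restarts exist because Lloyd converges
only to a local optimum that depends on the initial centroids. No
standardization is applied by default: the bands of a single sensor share
units and dynamic range, and clustering raw brightness keeps centroids
directly interpretable as spectra.

### Initialization choice

Seeding with k distinct observed pixels chosen uniformly (Forgy) is the
textbook default, but with several spectrally distinct land covers of very
unequal abundance the probability that k uniform draws cover every class is
tiny (≈7·10⁻⁴ for the default synthetic mixture), and Lloyd frequently
stalls in local optima that split an abundant class while merging two rare
ones: on the default synthetic scene Forgy recovered the planted classes
(ARI ≥ 0.95) in only 2/10 seeds at 10 restarts. D²-weighted seeding
(k-means++) recovered 10/10. The default is therefore `kmeans++`;
`random_points` is retained for strict classical behavior. The Lloyd
iteration itself, the stopping rule and keep-best-restart are identical
under both.

### Other numerical choices

* **Empty clusters** (possible under adversarial seeding): the empty
  centroid is re-seeded with the point currently farthest from its assigned
  centroid; each point can re-seed at most one cluster per iteration. The
  step never increases WCSS, preserving the monotone trace.
* **Assignment ties** break to the lowest cluster index; **selection ties**
  (two clusters with equal site counts) break to the higher centroid NIR
  value — NIR being the most fossil-indicative band — then the lower id.
* **Cell boundaries** are half-open: cell (r, c) covers
  [e₀ + c·s, e₀ + (c+1)·s) × (n₀ − (r+1)·s, n₀ − r·s], so a point on a
  shared edge belongs to the cell to its east/south, and every in-extent
  point belongs to exactly one cell. Cropping keeps every cell with
  positive-area overlap with the AOI rectangle.
* Cluster labels are 1-based; 0 is reserved for nodata in label rasters.
* **Quantiles** in spectral profiles use linear interpolation between order
  statistics (type 7, the numpy default).
* The **profile discrepancy** ranking clusters against the fossil-site
  spectral range is the median across bands of |median_cluster −
  median_sites| — a deliberately simple, robust scalarization of what is
  otherwise a visual comparison of violin plots. It is a package construct,
  not a field standard, and is used only as a consistency check against
  site-count selection.

## Band importance

A bagged ensemble of CART trees (scikit-learn `DecisionTreeClassifier`,
bootstrap per tree, ⌊√B⌋ candidate features per split) predicts cluster
labels from band values; each tree records its out-of-bag (OOB) cases. For
band b and tree t, the band's values are permuted among the tree's OOB cases
and d_{tb} = (permuted OOB error − baseline OOB error) recorded. The
reported importance is mean_t(d_{tb}) normalized by the standard error
sd_t(d_{tb})/√T — the classification analog of the %IncMSE statistic of
classical random-forest software. Under the null (a band carrying no
information about the labels) the statistic is approximately standard
normal; the approximation is slightly heavy-tailed because trees share
training data, which the tests account for by using a generous binomial
bound on the number of |z| > z₀.₉₉₅ exceedances. A class-specific variant
restricts the error difference to OOB cases whose true label is the target
cluster, quantifying which bands matter for telling the predictive cluster
apart. Zero-variance bands get importance 0 with a warning. Training pixels
are capped by a seeded, cluster-stratified subsample (default 20,000) for
desk-scale runtimes; the cap is recorded in run metadata.

## Synthetic scenes: what they emulate, and what they do not

`synthetic_scene` draws a 200 × 200 grid of 30 m pixels (a 6 × 6 km AOI,
40,000 pixels) in the seven Landsat-like bands from eight Gaussian
land-cover classes with diagonal covariance (default sd 0.012 per band on a
0–1 reflectance scale). The class signatures are hand-written to resemble
plausible covers (woodland, riparian forest, grassland, floodplain soil,
water, burned area, alluvium) plus one eroded-outcrop class — bright, high
NIR/SWIR — that plays the fossiliferous role and occupies ≈4.5% of the scene
by weight, mirroring the footprint of a realistic predictive cluster.
Spatial layout is "blocky" by default (square patches, default 10 × 10
pixels) or iid. Fossil sites land in a uniformly chosen fossiliferous-class
pixel with probability p = 15/17 (else uniformly in another class);
non-localities are uniform over the scene; coordinates are jittered strictly
inside their cell. Default catalog size is 17 fossil sites and 74
non-localities. Every output is a pure function of (spec, seed).

What the generator does **not** emulate: radiometric artifacts (clouds,
shadows, sensor noise structure), topographic illumination, mixed pixels,
spatial autocorrelation beyond block constancy, class-dependent non-locality
placement, and any real geology. Passing the recovery tests therefore shows
that the pipeline's machinery is correct and well-calibrated on separable
Gaussian mixtures — not that real Landsat scenes of any particular landscape
are this separable, nor that a real predictive cluster will reach these
metric values.

## Problem sizes in the shipped tests and acceptance script

The test suite and `scripts/acceptance.py` run the full pipeline on the
default 200 × 200 scene (40,000 pixels; k-means with 10 restarts), use
400-site catalogs for rate-recovery checks (binomial 95% intervals),
enumerate all partitions for global-optimum checks at n ≤ 10, k ≤ 3, and fit
60–100-tree ensembles on ≤ 900-pixel fixtures for importance checks — sizes
chosen so the whole suite completes in well under a minute of compute per
module while keeping every statistical check adequately powered.

## Known limitations

* Reprojection between CRSs is out of scope; scene and catalog must share a
  projected CRS in meters. GeoTIFF georeferencing is read from the pixel
  scale + tie point tags only (north-up, square pixels).
* The confusion matrix scores each record independently; several records in
  one pixel count several times.
* Buffer-zone scoring (credit for sites near, not on, positive pixels) is
  not implemented.
* `k` is fixed by the user (default 8); no model-selection criterion is
  provided.
* With `standardize` on, WCSS and its trace are reported in standardized
  units while centroids are mapped back to band units.
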