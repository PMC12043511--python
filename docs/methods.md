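# Methods

This note documents the models implemented in `canopyscale`, the synthetic
world they are tested against, the parameter defaults and why, and the
numerical conventions a user needs to interpret outputs.

## 1. Scaling stems to pixel community-weighted means

Each tree gets a circular crown of radius `r = a · DBH^b` (defaults
`a = 0.5`, `b = 0.6`; DBH in cm, r in m), discretized as a regular 64-gon
(area within 0.2% of the true circle; vertex count configurable). Crowns are
clipped to the plot boundary, and only pixels lying fully inside a plot are
rasterized — crowns censored at the plot edge would otherwise bias the CWM
of boundary pixels. Overlapping crowns are summed without an occlusion
model: the weight of a tree in a pixel is its full crown-pixel intersection
area even where crowns overlap. This is the simplest defensible reading of
"crown horizontal area as the weighting factor"; an occlusion model would
require heights, which the inventories do not carry.

Trait resolution is species mean first, then genus mean (the unweighted mean
of the species-level means of congeners present in the table), else missing.
Matching is exact after whitespace/case normalization — no fuzzy taxonomy.

A pixel's CWM for a trait is retained only when the **coverage** — the
resolved fraction of crown area in the pixel — is at least 0.70
(inclusive). The coverage basis is canopy area by default; a basal-area
basis (resolved share of basal area over trees whose crowns intersect the
pixel) is available as a flag because the two conventions coexist in field
practice. Flipping the basis changes which pixels are retained but never the
CWM value of a pixel retained under both.

Grid convention: planar metre coordinates, pixel `(i, j)` covers the
half-open square `[x0+j·s, x0+(j+1)·s) × [y0+i·s, y0+(i+1)·s)`, row index
increasing northward. Rasters serialize as ESRI ASCII grids, which carry the
origin and cell size in their text header; no CRS handling in the core.

## 2. Covariates

* **Indices** (standard Sentinel-2 band roles: green B3, red B4, red-edge
  B5, NIR B8):
  MCARI `[(B5−B4) − 0.2(B5−B3)]·(B5/B4)`;
  MSAVI2 `(2·B8+1 − sqrt((2·B8+1)² − 8(B8−B4)))/2`;
  NDRE `(B8−B5)/(B8+B5)`. Degenerate pixels (zero denominators) become NaN
  and are dropped from training rows rather than aborting the run.
* **Texture**: per-pixel grey-level co-occurrence matrix over a 9×9 window,
  32 equal-width grey levels spanning the layer's global range, symmetric,
  averaged over the four distance-1 offsets. Entropy `−Σ p ln p` and
  correlation `Σ(i−μ)(j−μ)p/σ²`, with correlation defined as 0 for constant
  windows (σ = 0). Window and level count are configurable; border pixels
  whose window does not fit are NaN.
* **MCWD**: monthly water balance `P − PET` accumulated within a
  hydrological year that starts (deficit = 0) at the climatological wettest
  month, running deficit capped at 0; annual MCWD is the year's most
  negative value, and a multi-year series reports the **mean of annual
  minima** by default (`multi_year="min"` gives the worst year instead —
  both conventions exist in the drought literature). Reported values are ≤ 0
  (more negative = drier).
* **Slope**: Horn's eight-neighbour finite differences, degrees.
* **Resampling** of coarse layers (climate) to the pixel grid is
  nearest-neighbour by default — it preserves class-like values and keeps
  coarse-cell provenance visible — with a bilinear option that reproduces
  linear fields exactly at pixel centres.

## 3. Trait models

Per trait, the retained-pixel CWM is regressed on the full covariate stack
(10 bands, 3 indices, 6 texture layers, MCWD, mean Tmax, slope, 4 soil
layers) with a random forest (scikit-learn), `min_samples_leaf = 5` (the
standard regression default of the ranger implementation this mirrors).

**Tuning.** The search ranges are 500–1500 trees (ladder {500, 1000, 1500})
and mtry 1–10. A two-stage search keeps this affordable on one CPU: the mtry
range is swept at 500 trees using out-of-bag (OOB) RMSE, then the tree
ladder is grown for the winning mtry via warm starts (a 500-tree forest is a
prefix of the 1500-tree one). Candidates within 2% relative RMSE of the
minimum are treated as tied, resolving to smaller mtry and fewer trees — a
one-standard-error-style parsimony rule; OOB RMSE differences inside that
band are estimation noise. Tuning runs on a seeded row subsample (default
400 rows). OOB tuning does mix pixels of one plot across the bag/out-of-bag
split, so it is not spatially blocked; this can only bias the
*hyperparameter choice*, never the reported accuracy, which comes from a
fully blocked CV.

**Evaluation.** Plot-level spatial-block leave-one-out CV: all pixels of one
plot are held out together, the forest is refit on the remaining plots, and
accuracy is the pooled out-of-fold `R² = 1 − SSE/SST` and RMSE. Train/test
plot disjointness is asserted in the tests.

**Uncertainty.** Per-pixel standard errors use the infinitesimal jackknife
for bagged ensembles: `V̂_IJ(x) = Σ_i Cov_b(N_bi, t_b(x))²` over training
rows *i*, where `N_bi` is row *i*'s in-bag count in tree *b* and `t_b(x)`
the tree prediction, with the Monte-Carlo bias correction
`− n·var_b(t_b(x))/B`, clipped at zero (the correction can overshoot at
small B). In-bag counts are regenerated exactly from each tree's stored
bootstrap seed. The estimator is recorded in the run manifest.

**Importance** is impurity decrease (mean decrease in node variance),
rescaled per model so the largest value is 1.

Predictions are masked to pixels with ≥ 25% forest cover (inclusive).

## 4. Trait space and diversity

Predicted trait maps are standardized per trait and decomposed with PCA
(full SVD). The functional trait space is the (PC1, PC2) plane — the third
component is retained in outputs but does not enter the diversity metrics,
which are defined on the 2-D density.

The trait probability density (TPD) is a Gaussian kernel density with
diagonal bandwidth from Silverman's rule per axis (`h = σ·n^(−1/6)`),
evaluated on a rectangular cell grid (default 150–200 cells per axis,
spanning the scores plus 3 bandwidths of padding), converted to per-cell
probability mass and normalized to sum to 1. Pixels may be subsampled
(seeded, default cap 20,000) before the KDE; the cap and bandwidth are
recorded in the manifest. Trimming keeps the highest-density cells that
jointly hold 99% of mass (the same construction gives the 0.5/0.99
highest-density contour sets).

FRich = retained-cell count × cell area (PC-score units squared — the units
are those of the standardized-trait principal components). FDiv uses the
unweighted centre of gravity of the retained cells and probability-weighted
deviations of cell distances, `(Δd + d̄)/(Δ|d| + d̄)`, bounded in [0, 1];
analytic checks: a ring of mass gives exactly 1, a uniform disc gives
54/70 ≈ 0.771.

Regional TPDs are evaluated on the *global* grid with the *global*
bandwidth, so regional FRich/FDiv are directly comparable with each other
and with the global values.

## 5. Sampling priorities and region comparisons

Each trait's s.e. map is min–max standardized to [0, 1] over unmasked
pixels (constant maps are skipped with a warning), averaged pixelwise, and
classified into terciles at the 33.33%/66.67% quantiles. Classification is
rank-based with stable ordering, so class sizes stay within one pixel of
n/3 even with ties.

Region comparisons are Welch (unequal-variance) two-sample t-tests of
pixel-level trait values for every region pair, run on the full data and on
seeded 10% and 1% subsamples — a sensitivity check against significance
driven purely by the enormous pixel count. Bonferroni correction uses
m = (pairs × traits) within each fraction. The percent-difference reporter
prints both `(a−b)/b` and `(a−b)/a` conventions along with the rounded
value, since informal "X% higher" statements are ambiguous about the
baseline. No spatial-autocorrelation correction is applied to these tests;
the subsampling sensitivity is the guard.

## 6. The synthetic landscape

The generator emulates the structure of a tropical plot network without
claiming realism beyond what the pipeline needs:

* **Species pool** — 13 traits, multivariate log-normal; the default
  log-scale correlation matrix is built from two latent axes (an acquisitive
  ↔ conservative chemistry axis: high N/P/K/Ca/Mg/SLA vs high C, wood
  density, thickness; and a leaf-size/mass axis), which makes the pool's
  first two principal components meaningful strategy scores. Geometric means
  are plausible magnitudes for tropical canopy trees (e.g. SLA 120 cm²/g,
  leaf N 2.2%, wood density 0.60 g/cm³); CVs 0.04–0.7 depending on trait.
  Genera come from k-means on log-traits (k = n_species/4), giving
  congeners similar traits so the genus-mean fallback behaves as in real
  tables.
* **Environment** — two standardized latent gradients (fertility: west–east
  trend; wetness: south–north trend; plus smoothed noise) drive soil
  chemistry/texture; elevation is an independent smooth surface;
  sand + clay ≤ 100% by construction.
* **Community assembly** — plots sit on a lattice aligned to pixel
  boundaries. Species abundance in a plot ∝
  `base_abundance · exp(−niche_strength · |score − optimum|²)`, the optimum
  a linear function of local fertility and wetness, scaled per region
  (vertical thirds: west/central/east) by a dispersion factor
  (1.25/1.0/0.8) so regions differ in trait-space spread. Stem counts are
  Poisson (450 stems/ha), locations uniform, DBH log-normal (median 18 cm).
* **Missing traits** — 12% of species plus all species of 6% of genera are
  absent from the "field" trait table; the former resolve via the genus
  fallback, the latter stay unresolved and push some pixels below the 70%
  coverage threshold.
* **Reflectance** — each band is an affine map (a fixed dense 13×10 loading
  matrix) of the standardized true CWM surfaces plus Gaussian noise, clipped
  to [0, 1]. The noise s.d. is calibrated per band so the trait signal
  explains ≈ 0.8 of band variance — prescribing signal strength rather than
  noise magnitude makes "can the model recover the signal" a well-posed
  question. Inside plots the driving CWM is the realized crown-weighted
  value; outside plots it is the smooth niche-model expectation, so
  prediction maps have meaningful targets everywhere. Nonlinearity,
  radiative transfer, phenology, clouds, and atmosphere are deliberately out
  of scope.
* **Climate** — 30 years of monthly P/PET/Tmax on a 10×-coarser grid
  (climate-product resolution), sinusoidal seasonality with a configurable
  extra dry-season deficit, spatial structure from the wetness gradient and
  elevation lapse.

**What passing tests do and do not show.** The synthetic world is affine,
low-rank (two environmental gradients) and noise-calibrated; recovery there
demonstrates that the estimators, the blocking, and the bookkeeping are
correct — not that real tropical reflectance carries this much trait signal.
Conversely, failures of the pipeline on this landscape would be genuine
defects, since the signal is present by construction.

## 7. Problem sizes and determinism

Desk-scale defaults are sized for a single CPU: the default landscape has 50
plots of 1 ha (≈ 4,500–5,000 retained 10-m pixels); the training table
thins to a seeded subsample of 15–20 pixels per plot (≈ 700–1,000 rows) —
adjacent within-plot pixels are strongly autocorrelated, so thinning trades
little information for a large cost saving; tuning uses 400-row subsamples;
the acceptance script runs 30 plots. All randomness flows from explicit
seeds (config seed → per-stage child seeds); identical configs give
byte-identical outputs, verified by manifest digests.

## 8. Known limitations

* No occlusion model for overlapping crowns; crown allometry is a single
  power law with no species effects.
* OOB-based tuning is not spatially blocked (accuracy reporting is).
* The infinitesimal-jackknife bias correction is clipped at zero, which can
  slightly understate uncertainty at very small ensembles.
* GLCM texture is computed per pixel in a Python loop; fine for desk-scale
  grids, not for continental rasters.
* The t-test region comparisons ignore spatial autocorrelation by design;
  interpret their p-values with the subsampling sensitivity in mind.
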