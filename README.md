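# habtex

Image texture as a remotely sensed surrogate for vegetation structure,
applied to predicting avian density and species richness across habitat
mosaics.

Field indices of vegetation structure — foliage-height diversity (the
Shannon index H = −Σ pᵢ ln pᵢ over 30-cm height bands of pole-count
profiles) and horizontal vegetation structure (the SD of canopy heights
among repeated profiles) — predict bird community metrics well but are
impractical to measure over large areas. Moving-window image texture
offers a scalable alternative: first-order variance and entropy, and
second-order GLCM contrast Σᵢⱼ p(i,j)(i−j)², computed over fine-grain
aerial imagery and coarse-grain NDVI at multiple window extents, then
summarized (mean, SD) within 100 m of each sample point. `habtex`
implements that full analysis chain for ecologists and remote-sensing
practitioners:

- moving-window **texture engine** (integral-image based, exact to the
  naive definition, any odd window size) plus NDVI;
- **zonal statistics** in fixed-radius circles around sample points;
- **field-structure indices** from foliage-height profiles;
- **distance-sampling density**: the six standard key × adjustment
  detection models, AIC selection, average detectability
  p̂ = (2/w²)∫₀ʷ r g(r) dr, per-point densities, across-year averaging;
- **richness and sample-based rarefaction** with permutation SDs;
- **regression suite**: OLS with sqrt/log/quadratic options, adjusted R²,
  exact LOOCV prediction error, residual semivariograms, model-ranking
  tables, and predictive raster mapping;
- a **synthetic landscape generator** (three-habitat mosaic, 1-m and 30-m
  imagery, constrained sample points, profiles, point counts) with known
  ground truth, used throughout the test suite for parameter recovery.

## Worked example

Estimating density from distance-sampled point counts
(`examples/04_distance_density.py`): 60 points are surveyed 4 times with
true density declining from 6.4 to 2.8 birds/ha along a covariate and
half-normal detection with σ = 55 m; the six detection models are fit
and AIC-selected:

```
1704 detections at 60 points
  half-normal  none               k=1 AIC= 15425.99 p-hat=0.502
  half-normal  none               k=1 AIC= 15425.99 p-hat=0.502
  uniform      cosine             k=3 AIC= 15430.38 p-hat=0.475
  uniform      simple-polynomial  k=3 AIC= 15427.91 p-hat=0.562
  hazard-rate  cosine             k=3 AIC= 15427.04 p-hat=0.471
  hazard-rate  simple-polynomial  k=3 AIC= 15428.39 p-hat=0.421
selected: half-normal / none (true p-hat for sigma=55 is 0.489)
mean density 4.50 birds/ha (true mean 4.60)
```

The true model family wins by AIC, its estimated average detectability
(0.502) is within 0.02 of the analytic value, and correcting the raw
counts by p̂ recovers the true mean density within 3%.

Fitting richness against a texture covariate with a quadratic term
(`examples/06_regression_mapping.py`, truth 7.08 + 0.40x − 0.0021x²,
noise SD 2, n = 172):

```
richness = 7.14 + 0.388 x + -0.00189 x^2
adjusted R2 0.89   p 9.50e-82   LOOCV error 4.11
semivariogram gamma(h): [3.65 4.07 3.71 4.   3.87 4.03]
```

Coefficients are recovered within sampling error, and the flat
semivariogram (γ ≈ residual variance at every lag) shows the residuals
carry no spatial structure. The full landscape-to-maps run is
`examples/07_full_pipeline.py`.

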