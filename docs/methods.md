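# Methods

`habtex` implements a complete texture-based avian habitat analysis: image
texture computed in moving windows over remotely sensed imagery serves as a
surrogate for vegetation structure, and per-point zonal summaries of those
textures are used to model bird density (estimated by distance sampling)
and species richness. Because the kind of field campaign this emulates is
rarely redistributable, the package pairs the analysis stack with a
synthetic landscape generator that has known ground truth, so every
estimator can be validated by parameter recovery.

## Image texture

Three measures are computed in odd-sided square windows of `w` pixels,
each written to the window's central cell:

- **First-order variance** — population variance of the raw pixel values,
  `sum_i (x_i - xbar)^2 / n` with `n = w^2`. First-order statistics are
  defined over the window's full pixel population, hence the divisor `n`
  rather than `n - 1`. Computed on raw (unquantized) values.
- **First-order entropy** — Shannon entropy `-sum_k p_k ln p_k` (natural
  log, nats) of the window's gray-level histogram after linear min–max
  quantization into `N` levels. Natural log keeps the measure on the same
  scale as the Shannon index used for foliage-height diversity.
- **Second-order (GLCM) contrast** — `sum_ij p(i,j) (i - j)^2` over the
  window's gray-level co-occurrence matrix, accumulated symmetrically and
  averaged over a set of pixel offsets. Because the contrast weight is
  symmetric in the pair, counting each unordered pair once and dividing by
  the pair count `(w - |dr|)(w - |dc|)` is identical to building the full
  symmetric normalized GLCM.

Defaults: `N = 64` gray levels (the common remote-sensing default for
8-bit-equivalent imagery) and the symmetric four-direction offset set
{(0,1), (1,0), (1,1), (1,−1)} at distance 1, since neither direction nor
shift is fixed by convention. The standard window sweeps are 3–51 pixels
at 1-m grain and 3–11 pixels at 30-m grain.

All three are computed with integral-image rectangle sums, so cost is
linear in raster size and independent of window extent. Variance is
globally mean-centered first and accumulated in extended (80-bit)
precision: integral images subtract large nearly equal partial sums, and
this keeps the result within ~1e-12 of the naive per-window computation
even on 8-bit-range data. Entropy and contrast accumulate integer counts,
which are exact in double precision. Edge policy `reflect` mirrors the
raster at its borders so outputs are wall-to-wall (required for
predictive mapping); `mask` flags every partial window as nodata. Under
either policy, a window containing a nodata pixel yields nodata — texture
is never interpolated across gaps.

## Zonal summaries

Every raster (raw pixel values, NDVI, each texture) is summarized as the
mean and sample (`n - 1`) standard deviation of the pixels whose
**centers** fall within 100 m of each sample point. The center-in-circle
rule is asserted as this package's contract because it is deterministic
and reproducible bit-for-bit; no fractional-area weighting is applied.
On a 30-m grid a center-aligned 100-m circle contains exactly 37 pixels.

## Field vegetation structure

A sample point has 16 foliage-height profiles (4 sub-plots x 4 cardinal
directions), each a vector of vegetation contact counts in 30-cm height
bands over 0–12 m (40 bands; taller canopies estimated into the same
bands, so the band vector is fixed at 40).

- **Foliage-height diversity (FHD)**: hits are pooled across the 16
  profiles per band; FHD is the Shannon index (nats) of the pooled
  distribution. Pooling before the index (rather than averaging 16
  per-profile indices) follows the one-index-per-point convention; the
  per-profile alternative systematically underestimates diversity when
  individual profiles are sparse.
- **Horizontal vegetation structure (HVS)**: the sample SD of the 16
  per-profile canopy heights, where canopy height is the **upper edge**
  of the highest occupied band (0 for an empty profile). Upper edge was
  chosen over the midpoint as the conventional reading of a pole tally;
  the choice shifts all heights by 0.15 m and does not affect the SD.

## Distance-sampling density

Surveys are 100-m variable-radius point counts. Detected radii on
`[0, w]` have density `f(r) ∝ r g(r)` where `g` is the detection
function (`g(0) = 1`). Candidate models are the six standard key x
adjustment pairs — half-normal x {cosine, Hermite polynomial}, uniform x
{cosine, simple polynomial}, hazard-rate x {cosine, simple polynomial} —
with 0–3 adjustment terms chosen per pair by AIC, and the overall model
chosen by minimum AIC (ties to fewer parameters, then a fixed key
order). Fits maximize the exact point-transect likelihood by
Nelder–Mead on log-transformed scale parameters, with a 64-node
Gauss–Legendre quadrature for the normalizing integral during
optimization and adaptive quadrature for the final average detectability

    p = (2 / w^2) * integral_0^w r g(r) dr.

A fitted model is discarded when its detection function goes negative,
exceeds 1 appreciably, increases substantially with distance on a
200-point grid, or yields numerically zero detectability — a standard
shape guard on adjustment series. Density for a point-year is
`count / (p * pi w^2 * visits)`, reported in birds ha^-1 per survey
visit (yearly estimates are per-visit densities before across-year
averaging, which is an unweighted mean). Units are the generator's own;
no equivalence to any particular field study's unnormalized densities is
claimed.

**Known limitation — AIC instability among near-equivalent shapes.** For
half-normal data at sigma = 40 m and w = 100 m, the best uniform+1-cosine
model is nearly Kullback–Leibler-equivalent to the true model (expected
AIC gap ~1.4 with equal parameter counts), so AIC selects a
half-normal-key model only ~50–65% of the time at n = 500. The practical
effect is small: the winning alternatives estimate average detectability
within ~0.02–0.03 of truth, so densities are nearly unbiased regardless
of which near-equivalent shape wins.

## Richness and rarefaction

Per-point richness is the count of distinct species over all years and
visits. Accumulation curves are sample-based rarefaction at the survey
event (point x visit) level: the order of events is permuted (default
1000 times) and the mean and SD of the cumulative distinct-species count
are reported per number of accumulated samples. The SD is taken over
permutations (ddof = 1) and is exactly 0 at the full sample count.

## Regression, cross-validation, and mapping

Each candidate model is a single-predictor OLS fit with optional
square-root response transform, log predictor transform (switching to
`log(x + 1)` when any predictor value is non-positive, as texture SD
summaries can be exactly 0), and an optional quadratic term.
Transformations are explicit configuration flags — the package never
silently auto-transforms. Reported per model: coefficients, adjusted
R^2 = 1 − (1 − R^2)(n − 1)/(n − p − 1), the overall-F p-value, and the
LOOCV mean squared prediction error on the transformed response scale,
computed exactly via the hat-matrix identity `mean[(e_i / (1 - h_ii))^2]`
(verified in tests against the literal n-refit loop). Ranking tables
blank out models with p above the significance threshold (default 0.05)
and flag the highest adjusted R^2 among the significant rest; no
multiple-testing correction is applied across the window sweep, by
design. Residual spatial structure is diagnosed with a Matheron
semivariogram (default 10 equal-width bins to half the maximum pairwise
distance). Predictive surfaces evaluate the fitted polynomial pixelwise,
back-transform square-rooted responses by squaring, and optionally clamp
negative densities to zero; zonal-summary predictors are approximated
per pixel by a square focal window matching the 100-m circle's diameter.

## Synthetic landscape generator

The generator defines the study conditions and the ground truth:

- **Habitat mosaic**: Gaussian white noise smoothed at a patch scale
  (default 500 m) and thresholded at the quantiles matching the target
  fractions (25% grassland, 35% savanna, 40% woodland) — the simplest
  construction that yields contiguous patches with exact class shares.
- **Fine-grain imagery (1 m, one band)**: per-habitat bright background
  plus Gaussian pixel noise, with dark circular tree crowns stamped at
  Poisson densities (grassland ~0 crowns, savanna sparse high-contrast
  crowns, woodland dense overlapping crowns on a darker background).
  This reproduces the qualitative texture ordering that motivates the
  analysis: local variance is highest in savanna, where windows straddle
  crown/background edges.
- **Coarse imagery (30 m, red + NIR)**: per-habitat band means plus
  noise, with NDVI increasing from grassland to woodland.
- **Sample points**: candidates at random pixel centers accepted
  sequentially under a minimum-separation rule, then filtered by
  distance to exclusion features and to the nearest other-class pixel
  center. The field design's constraints (400 candidates, 300-m
  separation, 150-m exclusion, 100-m edge buffer) remain the function's
  defaults; the pipeline scales them to its desk-size 2 x 2 km extent
  (800 candidates, 100-m separation, 50-m edge buffer), because ~170
  points at 300-m spacing are geometrically impossible on 400 ha. A full
  study-scale landscape (~24,000 ha at 1 m) would be ~240 Mpixels;
  the 2 x 2 km default keeps a complete run in the low minutes while
  preserving every structural feature of the design.
- **Foliage profiles**: per-profile, per-band Poisson hit counts with
  habitat-specific band-weight vectors whose Shannon entropies equal the
  target habitat FHD means (0.527 / 1.510 / 2.708 nats for
  grassland / savanna / woodland), with ~12 expected hits per profile.
  Pooled-sample FHD then lands within sampling error of those targets
  (the multinomial entropy bias at ~190 pooled hits is < 0.04 nats).
- **Bird surveys**: per point x visit, a Poisson number of birds with
  mean `lambda * disc area` (lambda from a linear-or-quadratic function
  of a chosen covariate, clamped at 0), placed uniformly in the disc,
  each detected with probability `exp(-d^2 / 2 sigma_year^2)`. Default
  sigma per year (58, 55, 42 m) gives average detectabilities of about
  0.51 / 0.49 / 0.33, representative of a declining-effort multi-year
  campaign. Only detected birds are reported, with true radial
  distances.
- **Richness**: `round(max(0, c0 + c1 x + c2 x^2 + N(0, sd)))` with
  default coefficients (7.08, 0.40, −0.0021) and noise SD 2, on a
  covariate scaled to [0, 95] — producing per-point richness between ~7
  and ~26.

What the generator deliberately omits: radiative transfer and phenology,
within-territory bird movement, observer heterogeneity, spatially
autocorrelated regression noise, and imagery georegistration error.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated model, not robustness to these real-data
complications.

## Determinism and numerics

Every stochastic component takes an explicit seed and uses an
independent `numpy` Generator; fixed seeds reproduce outputs
bit-identically. Quantization maps the maximum value to the top level
and a constant raster wholly to level 0. Detection fits reject distances
outside `[0, w]`; regression fits fail explicitly on singular designs;
a zonal circle containing no valid pixel yields a flagged NaN record.

## Problem sizes used in validation

The default end-to-end run uses a 2 x 2 km landscape (4 Mpixel fine
raster), ~155–190 sample points, 3 years x (4, 4, 3) visits, the full
window sweep (variance / entropy / contrast at 3–51 px on the air photo
and 3–11 px on NDVI), and completes in roughly 1.5 minutes on one CPU.
Recovery experiments use 20 replicates of 500 detections (detection
sigma), 100 replicates at n = 172 (richness quadratic), and 20
reduced-scale (1 x 1 km) seeds for the texture-vs-noise comparison.
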