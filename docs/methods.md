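# Methods note

Definitions, assumptions and numerical choices behind `vscpipe`. All
quantitative statements here describe the package's own computations on its
synthetic data; none are field observations.

## 1. Plot-level metrics

For a plot with plant heights `h_1..h_n`:

- **height_max** = max(h_i), in metres.
- **height_var** = coefficient of variation, SD(h) / mean(h). The default
  SD is the sample SD (ddof = 1); a population-SD mode (`sd_mode=
  "population"`) is available. Requires at least two plants; the CV is
  scale-invariant.
- **height_even** — Shannon evenness over height classes:
  `-Σ P_k ln P_k / ln(N_h)`, where `P_k` is the share of plant material in
  height class `k` and `N_h` is the number of classes. Classes are
  half-open intervals `[k·w, (k+1)·w)` anchored at zero, with width `w` =
  1 m in forests, 0.10 m in shrublands and 0.01 m in grasslands
  (configurable). By default `N_h` counts *occupied* classes
  (`nh_mode="occupied"`); `nh_mode="span"` instead counts every class from
  the lowest to the highest occupied one. With a single occupied class the
  ratio is 0/0 and evenness is defined as 1 (a one-layer community is
  perfectly even within its layer).

  Class shares `P_k`:
  - *Woody plots* (forest, shrubland): basal-area fractions, basal area
    `π (d/2)²` from stem diameter `d` (DBH for trees, basal stem diameter
    for shrubs). Trees are recorded above a 3 cm DBH threshold.
  - *Grassland plots* (meadow, steppe, desert): each species' importance
    value IV = (relative height + relative coverage) / 2, computed from the
    species' mean height and mean coverage in the plot; the IV is assigned
    to the class containing the species' mean height.

- **Importance value and diversity.** `importance_value(rh, rc)` is the
  mean of relative height and relative coverage; `shannon_wiener(iv)` is
  `-Σ IV ln IV` for IVs normalised to 1.

- **Gradients.** `gradient_bins` averages the metrics in 3° latitude or
  1,000 m elevation bands; empty intermediate bands are reported with
  n = 0 and NaN means.

## 2. Environmental variables

Thirteen candidates, classified once in `vscpipe.registry`:

- **Resource** (consumed or directly depended on): MAT (mean annual
  temperature), MAP (mean annual precipitation), AI (aridity index =
  MAP / PET), soil pH, SOC (soil organic carbon), TN (total nitrogen).
- **Non-resource** (conditions): T_coldest (coldest-quarter temperature),
  T_diurnal (mean diurnal range), T_annual (annual range), PO2 and PCO2
  (partial pressures of O₂ and CO₂), UR (solar radiation), Wind.

Partial pressures follow the barometric formula
`P(z) = P0 · exp(-z / H) · x`, with sea-level pressure P0 = 101.325 kPa,
scale height H = 8,000 m, and mixing ratios x = 0.20946 (O₂) and
4.0 × 10⁻⁴ (CO₂). PCO2 is therefore exactly proportional to PO2 (r = 1).

### Screening

`screen_variables` applies three ordered Pearson-correlation rules on the
pooled table:

1. drop PCO2 when |r(PO2, PCO2)| ≥ 0.9 (always true by construction);
2. among the temperature trio (T_coldest, T_diurnal, T_annual), when the
   trio is inter-correlated (all pairwise |r| ≥ 0.5), keep only the member
   least correlated with MAT and drop the other two;
3. drop MAP when |r(AI, MAP)| ≥ 0.9.

On the default synthetic scenario this retains nine working variables:
MAT, AI, pH, SOC, TN, T_diurnal, PO2, UR, Wind.

## 3. Driver attribution

- **Stepwise AIC.** Bidirectional stepwise selection starting from the full
  model, with the R-style criterion `AIC = n·log(RSS/n) + 2·edf`. Ties
  prefer the smaller model. Subset R² values are computed from a centred
  Gram matrix cache; the final model is refit with OLS (statsmodels) for
  coefficients and p-values.
- **LMG relative importance.** Each predictor's share of the model R² is
  its Shapley value over predictor subsets — the average, over all
  orderings, of its incremental R². Shares are non-negative and sum to the
  full-model R² to machine precision. Exact enumeration is used and capped
  at 12 predictors (4,096 subsets).
- **Resource decomposition.** LMG shares are summed by variable class and
  expressed as percentages of the model R² (resource + non-resource =
  100%).
- **VIF.** 1/(1 − R²) of each predictor's auxiliary regression on the
  others; NaN for a single predictor, infinite under exact collinearity.
- **Bootstrap size-matching.** To compare regimes with very different plot
  counts, each replicate draws n = 237 plots per vegetation type *without
  replacement* (subsampling to the size of the smallest compared group;
  types with fewer plots than the target, such as shrubland at its default
  30 plots, are excluded), refits the stepwise model and records R² and
  the resource split. Reported values are means over replicates.
- **Moran's I.** `(n/Σw) · (z'Wz)/(z'z)` on residuals, with row-standardised
  inverse-distance weights (haversine distances for geographic
  coordinates) by default; k-nearest-neighbour and explicit weight
  matrices are supported. The null expectation is −1/(n−1). Coincident
  points trigger a warning and a capped weight.
- **Partial correlation.** Residual-on-residual Pearson correlation after
  regressing out the controls.

## 4. Spatial upscaling

- **Ordinary kriging.** The empirical semivariogram (half the mean squared
  difference per distance bin, 12 bins up to 55% of the maximum pair
  distance; all pairs when samples are too few) is fitted by weighted least
  squares (bin counts as weights) to a spherical (default), exponential or
  linear model with a nugget. The kriging system includes a Lagrange
  multiplier and uses γ(0) = 0 on the diagonal, so predictions honour the
  sample values exactly (within 1e-6 numerically). Duplicate sample
  locations are rejected; a constant field short-circuits to a constant
  surface with zero variance.
- **Random-forest upscaling.** `fit_rf` merges the metric and environment
  tables on `plot_id`, sorts by `plot_id` (row-order invariance), splits
  75/25 into training and validation, and fits one
  `RandomForestRegressor` per metric (500 trees, mtry ≈ p/3, unlimited
  depth — all configurable). `height_max` is log10-transformed before
  fitting and back-transformed in predictions. Validation R² is the
  squared Pearson correlation between observed and predicted hold-out
  values by default ("ssr" gives 1 − SSE/SST). `predict_map` applies the
  forests cell-wise to a raster stack, propagating NaN and mask cells.
- **Rasters.** Plain-text ESRI ASCII grids (`*.asc`, NODATA −9999), read
  and written without external geospatial dependencies.

## 5. Synthetic survey generator

Scope: the generator exists to provide *ground truth with known structure*
for testing the analysis chain. It is not a calibrated ecological
simulation.

- **Design.** Five regimes (forest 456, shrubland 30, meadow 669, steppe
  621, desert 237 plots by default; 2,013 total). Each plot draws an
  environment from regime-specific normal distributions (with AI, MAP, PET
  linked by MAP = AI · PET, partial pressures derived from elevation, and
  the temperature trio coupled to MAT within regime). Each metric target
  is `base + Σ slope_v · z_v + noise`, where `z_v` is the variable
  standardised by fixed regime constants; default slopes are derived from
  per-regime variance-share tables (slope = sign · √share · SD_metric) so
  that resource variables dominate the warm, wet regimes and non-resource
  variables (PO2, Wind, temperature fluctuation) dominate the cold alpine
  regimes.
- **Plant records.** Heights are log-normal, rescaled so the plot maximum
  equals the target `height_max` exactly (the CV is scale-invariant, so
  `height_var` is unaffected by the rescaling). Forest DBH follows a
  height allometry with a 3 cm floor; grassland species receive Dirichlet
  coverage shares whose concentration increases with the evenness target.
- **Exactness by metric.** `height_max` follows the configured linear
  model *exactly* (noiseless single-effect runs recover the slope to
  machine precision). `height_var` follows it in expectation — the sample
  CV of a finite plant count is attenuated relative to the target, more so
  in species-poor plots. `height_even` is linked only monotonically
  through the Dirichlet concentration. Consequently the attribution tests
  make exact claims for `height_max` and qualitative claims for the other
  two metrics, and hold-out R² for `height_even` is expected to be low.
- **Rasters.** Each variable's grid is a smooth surface (plane plus one
  long-wavelength sinusoid) spanning the pooled ±2σ range, with derived
  layers (MAP, PO2, PCO2) computed from the AI/PET and elevation grids and
  a small rectangular mask of excluded cells.
- **Clipping.** Targets are clipped to physically meaningful ranges
  (height ≥ 0.01 m — 1 cm measurement precision; CV in [0.02, 2.5];
  evenness in [0.05, 1]).

## 6. Numerical choices

- Sample SD (ddof = 1) throughout unless a population mode is requested.
- AIC in the R style (`n·log(RSS/n) + 2·edf`), which is what makes the
  stepwise path comparable to common statistical practice.
- Class shares renormalised with a tolerance of 1e-6 before Shannon
  computations; the Σ P_k = 1 invariant is tested at 1e-12.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every artifact is reproducible bit-for-bit
  under a fixed seed (CSV floats are written with full round-trip
  precision and read back with `float_precision="round_trip"`).

## 7. Limitations

- The synthetic environment uses normal regimes and linear effects;
  real-world nonlinearities, interactions and sampling bias are out of
  scope.
- The within-regime correlations of the temperature trio with MAT are
  assumed nuisance structure chosen so that pooled screening behaves
  realistically; they are not estimates.
- LMG is exact-enumeration only (≤ 12 predictors); no sampling
  approximation for larger models.
- Kriging is isotropic ordinary kriging; no anisotropy, universal drift or
  co-kriging.
- The bootstrap compares subsample-size-matched models, not effect sizes on
  a common scale; shrubland is excluded by default because its plot count
  is below the matching target.
- Raster handling is limited to single-CRS ASCII grids with a boolean
  mask; no projection or resampling.
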