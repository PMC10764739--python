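# Methods

`yszkit` implements a field-relative soil stratification pipeline: yield
stability zones (YSZ) are classified from multi-year yield grids, soil
health panels are scored, and zone contrasts are tested on per-field
z-scores. Because commercial yield-monitor and soil-panel data are rarely
shareable, the package ships a synthetic study generator with known ground
truth; every downstream stage is validated against that truth and against
independent oracles.

## Zone classification

For each year *t*, cell yields are expressed relative to the field mean:
r(i,t) = 100·(y(i,t) − Ȳ_t)/Ȳ_t. The **yield level** of a cell is the
temporal mean of r, and **yield stability** its temporal sample SD (n−1).
A cell is *unstable* (US) when SD > 15 percentage points; otherwise it is
*low* (LS), *medium* (MS) or *high* (HS) and stable according to whether the
level is below −10%, within ±10%, or above +10%. All thresholds are strict
inequalities, so exact boundary values fall to the stable/medium side;
thresholds are configurable (`ysz.Thresholds`). Cells with fewer than 80% of
years valid (and never fewer than 2) are nodata rather than imputed.
Relative-NDVI stacks pass through the identical code path for fields without
monitor histories.

Relative yield must be a *percent* deviation (not a raw subtraction) for the
±10/±15 thresholds to be interpretable; this normalisation also makes the
classification invariant to rescaling all yields by a positive constant and
to year order, both enforced as property tests. A defensible alternative
stability definition — per-year field SDs averaged per cell — exists in the
literature's wording; the per-cell temporal SD is implemented because only
it measures a cell's own year-to-year variability.

## Interpolation

Yield monitors emit semi-regular points; `interp` fits a spherical
variogram to the binned empirical semivariogram by weighted least squares
(Cressie weights N/γ², bounds nugget ≥ 0, partial sill ≥ 0) and solves the
ordinary kriging system per cell with the 64 nearest neighbours — an
approximation to global kriging that keeps the solve tractable at 2 m
resolution. With a zero nugget the predictor is exact at data locations
(asserted to 1e−6); duplicate coordinates are averaged before solving;
cells beyond the convex hull of the points plus 10 m are nodata rather than
extrapolated. IDW (power 2, snap tolerance half a cell) is the fallback when
a variogram cannot be fitted, e.g. under 10 points or a constant field
(returned as a zero-sill model flagged `constant_field`).

## Terrain

Slope and aspect use Horn's 3×3 kernel (edge cells via replicated-edge
padding, i.e. one-sided differences); slope is percent rise/run, aspect the
downslope-facing direction in degrees clockwise from north, nodata on
flats. Depressions are removed with a priority-flood fill (output ≥ input,
idempotent; a single-cell pit rises exactly to its lowest neighbour). Flow
routing is D8 on an epsilon-drained copy of the filled surface, which
resolves filled flats deterministically toward the lower edge; ties in
steepest descent go to the lowest row-major neighbour index. Flow
accumulation is a cell count that **includes the cell itself**, so it is
≥ 1 everywhere and log10 is always defined — matching the convention of
analysing log flow accumulation without a zero guard. Conservation (off-grid
outflow sums to the cell count) and equality with a graph-reachability brute
force are tested. Elevation and yield grids may arrive at different
resolutions (e.g. 10 m national elevation vs 2 m yield); nearest-neighbour
resampling (`terrain.resample_to`) is provided and the choice of target
resolution is left to the user.

## Scores

The soil health score combines six indicators — CO₂-burst (mg CO₂-C/kg),
Solvita colour (log OD), SLAN (mg N/kg), water-stable aggregates (vol %),
water-soluble organic C (mg/kg) and SOC (%) — as

SHS = 10 · Σ_k min(x_k / d_k, cap),  d = (250, 5.25, 400, 80, 400, 3.5).

The d-values are maximum-value scaling factors; the per-term cap (default 1)
makes saturation explicit. Note an internal tension in the score's published
description: six equally weighted capped terms × 10 give a 0–60 range, while
the score is described as 0–50; the cap is therefore configurable and the
0–60 default range is documented rather than silently rescaled. The overall
fertility score is OFS = NI/2 + SHS, where the nutrient index NI (%) is the
equal-weight mean of capped P, K and available-N ratios against
crop-recommended values (user inputs; defaults 50/150/25 mg/kg are
placeholder agronomic magnitudes). Available N = water-soluble NO₃-N plus
mineralisable N estimated linearly from the CO₂-burst; the 0.1 mg N per mg
CO₂-C default coefficient is an explicit placeholder for laboratory-specific
calibrations. Localised (soil-type-conditioned) score variants are out of
scope; the general score is computed.

## Statistics

Regional gradients dominate absolute soil metrics, so zone contrasts use
per-field z-scores (sample SD; zero-SD fields yield missing z with a
warning). The 0–30 cm analysis row is the per-core mean of the two depth
increments. The suite provides:

- pairwise-complete Pearson correlation matrices with r², t-based two-sided
  p and 0.05/0.01/0.001 stars;
- bidirectional stepwise OLS from the full model minimising AIC, with exact
  collinear candidates dropped and the AIC trace retained for audit;
- one-way ANOVA with eta² = SS_between/SS_total, Tukey HSD 95% family-wise
  intervals, and a median-centred Levene (Brown–Forsythe) check;
- bootstrapped post-hoc power: resample with replacement within each group
  (stratified, sizes preserved), rerun the ANOVA, report the fraction of
  iterations with p < α plus a binomial 95% CI. **Caveat:** this standard
  retrospective estimator inherits the observed effect, so under an exact
  null its expectation is well above α (≈0.24 for four groups) — a known
  optimism of post-hoc power, deliberately not corrected away;
- management contrasts: per-field HS−LS differences of the z-scored
  response per depth, averaged by management level, with no inferential
  test attached (a ten-field study cannot support one).

ANOVAs pool z-scores across fields (n = 120 cores) rather than modelling
field as a factor; z-scoring removes the field main effect by construction.

## Synthetic study generator

The generator emulates a ten-field commercial transect across
Michigan–Indiana–Illinois, using each field's printed precipitation,
temperature, texture and management flags as fixed inputs. Per field it
builds:

1. **Terrain**: a planar tilt (default 1.5%) plus random Gaussian
   mounds/depressions (default 8, ≈1.2 m, ≈50 m width) on a 300×300 m,
   2 m grid (9 ha — smaller than the real 17–86 ha fields but large enough
   for contiguous zone patches and cheap enough for replicate studies).
2. **Latent zones** tied to terrain: after smoothing with a 20 m length
   scale, the wettest (highest log flow accumulation) 18% of cells are US,
   and among the remaining stable cells the steepest 10% are LS and the
   flattest 12% HS — reproducing zone area shares of roughly 18/10/60/12 %
   and the topographic signatures of the zones (LS on steep ground, US
   where flow accumulates).
3. **Yield histories**: yield(i,t) = Ȳ_t·(1 + L(i)/100 + U(i)·w_t + ε),
   with L = ∓15% on LS/HS cells plus a smooth 3% jitter, year shocks w_t
   rescaled to exactly 25% sample SD on unstable cells, and 5% white noise.
   With jitter and noise off, classification recovers the true zones
   exactly; under default noise recovery is ≈98%.
4. **Soil cores**: 3 per zone (≥20 m apart, ≥10 m from the edge), split at
   0–15/15–30 cm. SOC is drawn as field_mean + offset_z·σ_f + noise·σ_f
   with σ_f = 0.472 %SOC and zone offsets (LS −0.52, MS −0.14, US +0.29,
   HS +0.37 SD) chosen so the pairwise differences equal the standardized
   zone separations the design is meant to detect (HS−LS 0.89, US−LS 0.81,
   US−MS 0.43, HS−MS 0.51 — an internally consistent set, both pairs
   implying MS−LS = 0.38). Deep-increment offsets are multiplied by 1.5,
   emulating depth-amplified stratification; noise splits evenly between a
   core-level and a depth-level component so the two increments of one core
   correlate. The six health-panel metrics use the same offsets scaled by
   0.7 around typical Midwest panel levels; bulk density runs opposite in
   sign (denser in LS). Field-mean SOC follows the regional gradient
   3.0 + 0.12·clay% − 0.39·MAT (+ N(0, 0.25) field noise), which places the
   regional stepwise adjusted R² near 0.65–0.70 under defaults.
   Management effects default to zero; `management_shift` adds a configured
   per-depth HS−LS gap shift for no-till, cover-crop or prescription-N
   fields when those contrasts are under study.

Per-field seeds derive from the master seed and a CRC32 of the field id, so
results are independent of field-list order. A fast `mode="stats"` skips
terrain and yield simulation (zones from smoothed Gaussian random fields,
terrain covariates drawn around configured zone means: slope 2.3/1.7/1.3/
0.9 % and log flow accumulation 0.56/0.61/0.59/1.15 for LS/MS/HS/US) for
replicate-heavy statistical work.

What the generator does **not** emulate: crop-growth mechanisms, weather
series, harvester artifacts (overlaps, headland passes), spatially
autocorrelated within-zone soil noise, and measurement error structure of
the laboratory panel. Passing tests therefore demonstrate that the pipeline
recovers known structure of the configured statistical form — not that real
fields satisfy that form.

## Numerical choices and limitations

- Within-zone noise SD is a calibration choice (1 field-SD unit): published
  zone analyses print between-zone differences in SD units but not
  within-zone variances.
- Zone offsets are recovered nearly unbiasedly only when the within-zone SD
  is pooled across fields (80 df); per-field SDs at 3 cores per zone are too
  noisy and inflate standardized differences by ≈10%.
- The kriging neighbour cutoff (64) and the hull margin (10 m) are
  pragmatic defaults, exposed as parameters.
- 0–30 cm values are the mean of the two increments — a choice, since a
  depth-aggregated sample could equally be modelled as a separate analysis.
- Raster I/O uses TIFF with grid metadata (origin, resolution, nodata) in
  the image description tag; values round-trip bit-exactly. Point I/O is
  CSV and GeoJSON; binary shapefiles are not supported.
- No spatial autocorrelation of residuals and no mixed-effects models are
  fitted; no multiple-testing correction is applied across response
  variables (Tukey handles the family within one ANOVA).
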