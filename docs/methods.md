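# Methods

## Scope and data model

All layers live on regular equal-angle lon/lat grids with cell-center
registration (`GridSpec`); the canonical analysis grid is global 0.5°, with
centers at −179.75…179.75° E and −89.75…89.75° N. A `MonthlyClimateField`
holds one variable's 12 monthly long-term-mean layers for one model and
scenario; masked cells are NaN. I/O is CF-style netCDF (`time=12, lat, lon`)
through xarray's scipy (NETCDF3) backend — the one netCDF engine guaranteed
by the dependency set. Square cells are a deliberate restriction: native GCM
grids with unequal lon/lat spacing would need a two-resolution grid type,
which nothing downstream requires here.

## Ingest

Long-term monthly means average each calendar month over all available
years (100–600 in typical archives); missing values are skipped, and a
cell-month is masked only when no year contributes. Unit conversion is
linear — temperature K → °C by subtracting 273.15; precipitation flux
(kg m⁻² s⁻¹ ≡ mm s⁻¹) to monthly totals by multiplying with the seconds of a
30-day month (2 592 000), the 360-day-calendar convention, applied uniformly.
A `use_physical_calendar` flag switches to real month lengths. Because both
operations are linear, conversion and time-averaging commute (tested).
Longitudes are normalized to [−180, 180) and latitudes sorted ascending on
read.

## Change-factor downscaling

Trends, not raw LGM fields, are interpolated:

* temperature trend: LGM − modern (°C), per month and cell;
* precipitation trend: (LGM − modern)/modern (dimensionless). The ratio is
  undefined at zero modern rain; the rules are: both scenarios zero → trend
  0; modern below 0.1 mm month⁻¹ with a wet LGM → denominator floored at
  0.1 mm month⁻¹ and the cell flagged.

Trends and the modern climatology are interpolated to the target grid by
ordinary kriging and the trends re-applied (difference: modern + trend;
ratio: modern × (1 + trend), clipped at 0 with a logged count). When
LGM ≡ modern the reconstructed LGM layer equals the interpolated modern
layer exactly — the round-trip identity the test suite asserts at global
2° → 0.5° scale.

### Variograms

The spatial structure of each surface is summarized by an omnidirectional
sample variogram: 15 equal-width lag bins up to one third of the domain
diagonal, semivariance γ̂(h) = ½·mean (zᵢ − zⱼ)² per bin. Above 3000 points a
seeded random subsample is used (all-pairs enumeration is quadratic; the
estimate at the lags that matter is insensitive to this at the densities
involved). A spherical model

γ(h) = nugget + psill·(1.5 h/r − 0.5 (h/r)³) for h < r, nugget + psill beyond

is fitted by weighted least squares with weights N_h/h², bounds keeping all
parameters admissible. The spherical family is used because climate fields
decorrelate completely beyond a finite distance. Optimizer failure returns
the method-of-moments initial estimate flagged `converged=False`, never
silently. A flat sample variogram (constant field) yields a degenerate
model (sill ≈ 0), also flagged.

### Kriging

Ordinary kriging predicts from the 12 nearest observations per target cell,
solving the (k+1)-system with a Lagrange multiplier enforcing Σλ = 1.
Systems are assembled and solved in batches of 20 000 cells, which keeps a
global 0.5° surface (259 200 cells) at a few seconds. Distances are
Euclidean in degree space on unprojected (lon, lat) — the convention of
kriging toolchains on geographic grids; a haversine metric is available on
the distance helper. Neighbor ties are broken by (lat, lon) lexicographic
order of the observations, so results are invariant to input permutation.
Duplicate locations are averaged before the solve; a cell whose system stays
singular is masked and counted. For a degenerate variogram the OK solution
limit is equal weights, which the implementation uses directly — this keeps
constant and zero-trend fields exactly reproduced.

### Alternative interpolators and the MSE benchmark

For sensitivity analysis: IDW (power 2, the same 12-neighbor stencil),
thin-plate splines (scipy `RBFInterpolator`; local 12-neighbor mode above
50 observations, since a dense global TPS solve is cubic in the observation
count), and a 12th-degree trend surface on a bivariate Legendre basis with
total degree ≤ 12 (91 coefficients; raw monomials of that degree are
numerically unusable). Natural neighbor is feature-flagged off — no robust
implementation exists in the supported dependency set — and the benchmark
records the method set it actually ran.

The accuracy benchmark draws, per replicate, n cells uniformly without
replacement from the cells valid in every layer and reports
MSE = (1/n)·Σ(Xᵢ − Zᵢ)² per method (X interpolated, Z original). Defaults are
5000 points and 1000 replicates; the acceptance-scale configuration uses 500
points × 200 replicates on a 120×120 synthetic field with every second cell
observed. On fields drawn from a spherical model with a nugget, kriging
attains the lowest median MSE; exact interpolators (TPS, IDW) chase the
nugget noise.

## Bioclimatic variables

Quarters are all 12 windows of three consecutive calendar months with
December–January wrap-around; ties go to the earliest start month.
Wettest/driest select on the window precipitation sum, warmest/coldest on
the window mean temperature. BIO definitions are the standard ones; the
deliberate deviations/choices:

* BIO1 = annual mean of tas itself, not (tasmax + tasmin)/2 — the GCM
  supplies a genuine mean-temperature field;
* BIO4 = sample SD (ddof = 1) of monthly tas × 100 (switchable);
* BIO15 = 100·SD(pr)/(1 + mean(pr)) — the +1 mm offset keeps deserts finite
  (switchable, recorded in output metadata);
* BIO3 = 100·BIO2/BIO7, masked where BIO7 = 0.

A cell with any non-finite month in any input is masked in all 19 outputs.
Every layer is validated against a straight-from-definition loop oracle and
the full stack is invariant under a common rotation of the month axis.

## Ensemble agreement

Per-cell spread = sample SD (ddof = 1) across models — models are a sample
from a larger space of plausible GCMs. QCD = (q₃ − q₁)/(q₃ + q₁) with type-7
(linear-interpolation) quartiles, at least 4 models per cell.
Absolute-temperature variables (BIO1, BIO5, BIO6, BIO8–BIO11) are shifted to
Kelvin before the quartiles: around 0 °C the Celsius denominator changes sign
and the ratio is meaningless. Range/ratio variables (BIO2, BIO3, BIO4, BIO7)
and precipitation variables are nonnegative already and enter unshifted.
Cells with a nonpositive shifted denominator are masked and counted in the
map metadata. The agreement mask marks cells where every one of the 19 QCD
maps is below the threshold (default 0.5); cells where any variable is
undefined are reported separately (value 255). Latitude profiles are
unweighted band means (south → north); region summaries aggregate an
arbitrary integer label grid.

## Model grouping

Per variable, models are correlated by Pearson r over all shared unmasked
cells, unweighted (a cos-latitude-weighted option exists because equal-angle
grids oversample the poles). Clustering is agglomerative on d = 1 − r with
complete linkage (both configurable, recorded in the result), cut at
k = 4. Group ids are renumbered by first appearance in the model roster, so
tables are stable under reordering. The all-variables consensus clusters the
mean of the 19 per-variable distance matrices; correlating stacked layers is
the plausible alternative and is noted in the result metadata. Dendrograms
export as Newick with branch lengths from merge heights.

## Synthetic pseudo-GCM ensembles

The generator emulates exactly the features the analysis consumes. Model m
in planted group g is, per month, scenario, and base variable,

  field = common climatology + amp(lat)·(G_g + f·N_m)

with G_g a unit-variance group deviation field, N_m the model's own noise
field, f the within-group noise fraction (default 0.05), and amp(lat) the
disagreement profile: a logistic ramp in |lat| with midpoint 35° and width
8°, rising from 0.5 to 4 °C for temperature and falling from 50 to
5 mm month⁻¹ for precipitation. The common climatology has a meridional
temperature gradient, a hemisphere-antisymmetric seasonal cycle, an
ITCZ-like precipitation peak, and shared smooth anomaly fields. The LGM
scenario applies a uniform 5 °C cooling and 25 % drying to the shared part.
Defaults are nine models in four planted groups — the configuration of the
real multi-archive ensembles this stands in for.

Random fields are stationary Gaussian with spherical covariance, generated
by circulant embedding: the covariance is wrapped onto a torus of twice the
grid size, its 2-D FFT gives the eigenvalues, slightly negative eigenvalues
are clipped, and each draw costs one FFT. The empirical semivariance of
generated fields matches the requested model (tested against a brute-force
pairwise oracle at lag = range/2 within 25 %). tasmin ≤ tas ≤ tasmax holds
by construction (tas ± half of a positive diurnal-range field) and
precipitation is clipped at zero after noise.

What the generator does **not** emulate: land/sea masks, orography,
teleconnections, ice sheets, non-Gaussian precipitation tails, and
inter-variable physical coupling beyond the diurnal-range construction.
Tests passing on these ensembles therefore validate the statistical
machinery (interpolation, derivation, agreement, clustering), not any claim
about a specific real GCM.

## Problem sizes and numerical choices

The test suite runs the synthetic pipeline at 4° resolution (45×90 cells),
the kriging round trip and the cross-method correlation checks at the full
global 2° → 0.5° geometry, and the MSE benchmark at 1° over a 120°×120°
domain — sizes chosen so the whole suite completes in about a minute on one
CPU while every assertion still exercises the full-scale code paths.
Tolerances: kriging vs dense solve 1e−8; round-trip identity bit-equal
(difference) / 1e−10 (ratio); oracle comparisons 1e−9 to 1e−12 relative.

Known limitations: no anisotropic native grids (square cells only); no
GeoTIFF export (netCDF only); Euclidean-in-degrees distances by default,
which stretch longitudes near the poles; natural-neighbor interpolation
unavailable; no area weighting in the default correlation and profile
statistics.
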