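# Methods

## Model and procedure

The pipeline treats monthly gridded NEE (net ecosystem exchange, positive =
release from land), TWS (terrestrial water storage anomaly) and air
temperature on one regular lat–lon land grid, spanning whole calendar
years. Its core statistic is the decomposition of the Pearson correlation
between the global annual NEE anomaly `X_G` and the global mean driver
anomaly (`T_G` or `TWS_G`) into per-cell, per-calendar-month terms.

The decomposition is exact, not approximate, and rests on two bookkeeping
choices made throughout the package:

1. **NEE is extensive.** The flux density (kgC m⁻² month⁻¹) is converted
   once — in the anomaly stage — to PgC month⁻¹ per cell by multiplying
   with the spherical cell area. `X_G(y)` is then literally the sum of
   cell-month anomalies `x_{i,m}(y)`, so by bilinearity of covariance
   `corr(X_G, D_G) = Σ_{i,m} corr(x_{i,m}, D_G)·σ_{x_{i,m}}/σ_{X_G}`.
2. **Every σ is the sample standard deviation (ddof = 1).** The σ ratio in
   the contribution formula is convention-invariant only if numerator and
   denominator use the same convention; mixing conventions silently breaks
   additivity.

The contributions are computed as `cov(x_{i,m}, D_G)/(σ_{X_G}·σ_{D_G})`,
which is algebraically identical to the corr·σ-ratio form but makes the
degenerate case behave: a cell-month with zero anomaly variance has zero
covariance with anything and contributes an exact 0 to the sum. Its
correlation is undefined, not zero — the `zero_variance` quality layer in
the contribution map records this distinction, while the scalar `pearson`
and `partial_corr` functions raise on zero-variance input. `C^TWS` carries
an extra minus sign so that, with the globally negative NEE–TWS coupling,
positive contributions of either kind read the same way ("this region and
season supports the global relationship").

Partial correlations (each driver controlling for the other) are computed
by the residual method — correlate the OLS residuals of `X_G ~ D₁` and
`D₂ ~ D₁` — with the closed form
`(r_ab − r_ac·r_bc)/√((1−r_ac²)(1−r_bc²))` reserved for the test suite as
an independent oracle.

## Anomaly construction

Two detrending modes exist as deliberately separate code paths:

* **Whole-series** (correlation/decomposition path): one OLS line, fit on
  the monthly sample index, removed per cell. Stationary seasonal cycles
  survive this detrending, but they are constant across years and therefore
  cancel in every across-years covariance and standard deviation the
  analysis uses.
* **Per-month-group** (sensitivity path): the across-years series of each
  calendar month is detrended independently (12 fits per cell), which also
  removes month-dependent trends and the seasonal cycle itself.

Volcanic years (default 1982, 1991, 1992, configurable) are excluded
**after** detrending and **before** any correlation: trends are estimated
on the full record (maximal information), and the excluded years are
dropped from all annual series simultaneously. The order is pinned by
tests; excluding first and refitting gives measurably different anomalies.

Annual aggregation: `X_G` is the sum of the 12 monthly extensive anomalies
(PgC yr⁻¹); `T_G` and `TWS_G` are area-weighted means over the land mask of
the annual mean of monthly anomalies. The mean (not sum) keeps native
units; Pearson correlation is invariant to the ×12 rescaling, so the choice
does not affect any correlation. Area weights come from spherical cell
areas (Earth radius 6 371 000 m); only relative weights matter. The land
mask is binary — fractional coastal cells are not represented.

The CO₂ growth rate of year *y* is `CO₂(Jan, y+1) − CO₂(Jan, y)` from a
monthly (year, month, ppm) table; missing Januaries are an error rather
than an interpolation.

## Seasons

Northern-hemisphere seasons are MAM, JJA, SON and a **calendar-year DJF**
(December, January, February of the same year). A cross-year DJF would be
the more meteorological convention, but it breaks the exact additivity of
season sums to the annual sum at the record boundaries; calendar-DJF keeps
`MAM + JJA + SON + DJF = annual` to float precision, which the acceptance
checks rely on. The convention is a named constant (`NH_SEASONS`) and can
be overridden per call.

Tropical dry/wet seasons come from the climatological mean seasonal cycle:
month *m* is dry in a cell iff long-term mean PET strictly exceeds
long-term mean precipitation (ties → wet). One fixed partition per cell is
used for all years — year-by-year classification would make season
membership a random variable and the seasonal sums incomparable across
years. Cells with 0 or 12 dry months have no contrast and are flagged
excluded; for every non-excluded cell dry + wet month counts equal 12 by
construction.

Seasonal sensitivities solve, per cell and season,
`NEE_s = a^TWS·TWS_s + a^T·T_s + ε` by OLS, where the seasonal vectors are
the per-month-group-detrended anomalies summed over the season's months in
each year. An intercept is included even though the anomalies are
near-zero-mean — it guards against numerical mean drift and changes the
slope estimates only at float precision. Standard errors use the usual OLS
formula with n − 3 degrees of freedom. Cells whose predictors are
(near-)collinear — determinant of the centered cross-product matrix below
1e−12 of its scale — are reported as NaN rather than as exploding
coefficients. Because per-month-group detrending applies the same linear
projection to every month of a group, summing detrended months over a
season is identical to detrending the seasonal sums; the equivalence is
tested.

## Synthetic-data generator

The generator emulates the covariance structure the analysis assumes,
nothing more: no energy balance, no actual circulation modes.

* **Latent modes.** A small number (default 2) of annual AR(1) series
  (default σ = 1, φ = 0.6 and 0.2) represent global climate modes. They are
  expanded to monthly resolution either by linear interpolation between
  year-center knots (default) or piecewise-constant per year ("repeat").
  Temperature and TWS load on the same modes with different per-variable
  coefficients (defaults: T 0.6/0.25 °C, TWS 40/−25 mm per mode unit,
  modulated by a smooth deterministic spatial pattern), which produces the
  realistic situation of correlated-but-not-collinear drivers — droughts
  and heat anomalies co-occur.
* **Planted NEE response.** Each land cell's extensive NEE anomaly is
  `a^TWS_{i,m}·TWS′ + a^T_{i,m}·T′ + noise`, with sensitivities specified
  per latitudinal band and calendar month. Defaults encode the
  seasonal-compensation sign structure in the north (spring a^T = −5e−4,
  summer +8e−4, autumn +2e−4 PgC month⁻¹ °C⁻¹ per cell) and
  water-dominated tropics/south (a^TWS = −5e−6 / −3e−6 PgC month⁻¹ mm⁻¹);
  magnitudes are chosen so the global annual NEE anomaly has a std of
  order 1 PgC yr⁻¹ on the default grid, the observed order of magnitude.
* **Nuisance structure.** Per-band linear trends, latitude-scaled seasonal
  cycles in T and NEE, monthly white noise per variable (defaults 0.4 °C,
  20 mm, 5e−5 PgC month⁻¹), and additive NEE pulses in the configured
  volcanic years (default 1982/1991/1992, −1e−4 PgC month⁻¹ per cell) so
  the exclusion logic has real outliers to remove.
* **Dry seasons.** Precipitation climatologies step through evenly spaced
  levels around a flat PET line so each band has a prescribed dry-season
  length (defaults 3/5/4 months for NH/tropics/south, phase shifted with
  longitude); a small fraction (5%) of cells is made permanently arid to
  exercise the exclusion flag.
* **Reproducibility.** All randomness derives from one root seed through
  named substreams (CRC32 of the component name spawns a child
  SeedSequence), so any component is reproducible in isolation and the
  whole field set is bit-identical under a fixed seed.

The generator's truth object carries the planted sensitivity maps, the mode
realizations, the noiseless planted NEE signal and the planted dry-season
lengths. Planted band shares are computed from the noiseless signal and the
realized driver anomalies — the ground truth the decomposition should
approach as noise shrinks.

**What passing tests do and do not show.** The synthetic fields are
Gaussian, linear in their drivers, stationary apart from linear trends, and
free of missing data, observational error correlation, and regime changes.
Tests therefore validate the *estimator machinery* — exactness of the
decomposition, unbiased recovery of linear sensitivities, correct
bookkeeping — not the adequacy of linear TWS/T response as a description of
real ecosystems, and not the behaviour of the method under data gaps or
non-Gaussian extremes.

### Compensation scenario

`make_compensation_scenario(strength)` plants northern a^T < 0 in MAM and
a^T > 0 in JJA with spring magnitude = strength × summer magnitude, a
water-dominated tropics, and switches off all noise, trends, cycles and
pulses, with "repeat" mode expansion. Under these conditions the monthly
temperature anomaly is constant within each year, so at strength 1 the
spring and summer NEE responses are exactly antisymmetric and the annual
northern C^T cancels. The cancellation survives whole-series detrending up
to a small aliasing term (the OLS trend line sampled at different months of
the same year), measured at ~10⁻³ % of the summer contribution — far below
the 10% diagnostic threshold used in the end-to-end checks; the annual
contribution is exactly linear (hence monotone) in strength up to the same
aliasing.

### Share-recovery diagnostic

Fractional shares are ratios with cov(X_G, D_G) in the denominator; in
study conditions where regional contributions have mixed signs the global
covariance can sit near zero and the share of any region becomes
arbitrarily large — an ill-conditioning of the quantity, not an estimator
error (the absolute contributions remain well behaved). The planted-share
recovery diagnostic therefore runs on a water-dominated, uniform-sign
scenario in which both global correlations are bounded away from zero;
`planted_band_shares` reports ground truth in the same sign convention the
decomposition uses (shares relative to |r|, C^TWS carrying its minus sign).

## Numerical choices and problem sizes

* Detrending subtracts means before fitting the slope, so constant and
  exactly linear inputs return exact zeros (≲1e−15 in practice).
* Band assignment is by cell-center latitude with a strict inequality for
  the north (>25°N), making the three bands a partition for any grid.
* File I/O uses xarray's scipy NetCDF backend with integer (year, month)
  time coordinates; round-trips preserve every float bit.
* Default study conditions are 38 years (1979–2016 nominally) on a 4° toy
  grid with ~30% land. The test and acceptance suites run the same
  conditions on coarser grids (15°–30°, 12–38 years, 50-study additivity
  sweeps, 100-replicate Monte-Carlo at 30 years) — chosen so the planted
  structure is well resolved while a full run stays within seconds.

## Known limitations

* No regridding: all variables must arrive on one grid.
* No gap handling: missing months inside the span are an error, not an
  imputation problem.
* The binary land mask ignores fractional coastal areas.
* Significance testing of the correlations and contributions is out of
  scope; the spread across input datasets (`sign_consistency`) is the only
  robustness measure provided.
* The dry/wet classification is climatological; interannual migration of
  the dry season is not represented.
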