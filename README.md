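# neevar

Regional and seasonal attribution of the interannual variability of the
global land carbon sink.

## The problem

The net land–atmosphere CO₂ flux (net ecosystem exchange, NEE; positive =
release to the atmosphere) varies strongly from year to year, and that
variability drives fluctuations of the atmospheric CO₂ growth rate. Whether
those fluctuations are governed mainly by terrestrial water storage (TWS)
or by temperature (T) is contested, partly because a single global
correlation hides where and when the coupling arises. `neevar` implements a
covariance decomposition that splits the global correlation into additive
contributions from every grid cell and calendar month, so the question
"which regions and seasons make the global NEE variability look
water-driven or temperature-driven?" gets a quantitative answer.

It is a library + CLI for carbon-cycle researchers working with monthly
gridded NEE, TWS and climate fields (inversions, vegetation models,
upscaled flux products). Real datasets are read from NetCDF; a first-class
synthetic-data generator plants known covariance structure so that every
stage of the pipeline can be validated against ground truth.

## The statistic

Because NEE is extensive, the global annual anomaly splits exactly over
cells *i* and calendar months *m*: `X_G(y) = Σ_i Σ_m x_{i,m}(y)` (PgC).
Covariance is bilinear, so the Pearson correlation between `X_G` and the
global mean temperature anomaly `T_G` decomposes as

    corr(X_G, T_G) = Σ_i Σ_m corr(x_{i,m}, T_G) · σ_{x_{i,m}} / σ_{X_G}
                   = Σ_i Σ_m C^T_{i,m}

and analogously `C^TWS_{i,m} = −corr(x_{i,m}, TWS_G) · σ_{x_{i,m}} / σ_{X_G}`,
the minus sign chosen so that with the globally negative NEE–TWS
correlation a positive contribution of either kind means "removing this
cell-month's NEE variability weakens the global relationship". The
contribution of any region × season is the plain sum of its cell-month
terms, and the whole-globe, whole-year sum reproduces `r_T` (and `−r_TWS`)
to float precision.

Supporting computations: whole-series and per-calendar-month OLS
detrending; volcanic-year exclusion; simple and partial correlations;
climatological dry/wet-season classification (a month is dry where PET >
precipitation); per-cell seasonal sensitivities from the multiple
regression `NEE_s = a^TWS·TWS_s + a^T·T_s + ε`; and the CO₂ growth rate as
the January-to-January difference of the monthly mole fraction.

## Worked example

```python
import numpy as np
from neevar import (SimConfig, generate_fieldset, build_anomaly_cube,
                    aggregate_global, correlations, contribution_map,
                    aggregate_contributions, default_bands)

config = SimConfig(seed=1, n_years=20, lat_step=10, lon_step=10)
fieldset, truth = generate_fieldset(config)           # planted ground truth
cube = build_anomaly_cube(fieldset)                   # detrend, PgC/month
series = aggregate_global(cube)                       # X_G, T_G, TWS_G
corr = correlations(series)
print(f"r_TWS = {corr.r_tws:+.3f}  r_T = {corr.r_t:+.3f}")
cmap = contribution_map(cube, series)
print("additivity residual:", abs(cmap.c_t.sum() - cmap.r_t))
print(aggregate_contributions(cmap, default_bands(fieldset.geometry)))
```

Output:

```
r_TWS = -0.625  r_T = +0.617
additivity residual: 1.1102230246251565e-16
    region  season       C_T     C_TWS   share_T  share_TWS  n_cells  empty
0       NH  annual  0.339829  0.092135  0.550579   0.147381       66  False
1  tropics  annual  0.194853  0.360501  0.315694   0.576666       57  False
2    south  annual  0.082539  0.172511  0.133727   0.275953       64  False
```

Read it as: in this synthetic study the global NEE anomaly correlates at
−0.63 with global TWS and +0.62 with global temperature; the per-cell
contributions sum back to those correlations exactly; 58% of the
water-storage relationship originates in the tropics while 55% of the
temperature relationship comes from the Northern Hemisphere — the planted
structure.

The same pipeline runs from a shell:

```bash
neevar simulate  -c config.yaml   # synthetic fields + planted truth
neevar decompose -c config.yaml   # correlations, C^T / C^TWS maps, summary CSV
neevar sensitivity -c config.yaml # per-cell seasonal a^TWS, a^T maps
neevar report    -c config.yaml   # region x season contribution table
```

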