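"""Covariance decomposition of the global NEE-climate correlations.

The global annual NEE anomaly X_G is an extensive quantity: it is exactly
the sum of per-cell, per-calendar-month anomalies x_{i,m}. Because
covariance is bilinear,

    corr(X_G, T_G) = sum_{i,m} corr(x_{i,m}, T_G) * sigma_{x_{i,m}} / sigma_{X_G}

so each cell-month owns an additive contribution

    C^T_{i,m}   =  corr(x_{i,m}, T_G)   * sigma_{x_{i,m}} / sigma_{X_G}
    C^TWS_{i,m} = -corr(x_{i,m}, TWS_G) * sigma_{x_{i,m}} / sigma_{X_G}

C^TWS carries a minus sign so that, with the globally negative NEE-TWS
correlation (wet years mean more carbon uptake), positive contributions of
either kind mean "removing this region/season's NEE variability would weaken
the global relationship". Contributions sum exactly to r_T and -r_TWS, and
their regional/seasonal aggregates are plain sums of cell-month terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomalies import AnomalyCube, GlobalAnnualSeries
from .grid import GridGeometry, RegionMask

#: calendar-year season conventions for the Northern Hemisphere; DJF is
#: December + January-February of the SAME calendar year so the four season
#: sums reproduce the annual sum exactly.
NH_SEASONS: dict[str, tuple[int, ...]] = {
    "MAM": (3, 4, 5),
    "JJA": (6, 7, 8),
    "SON": (9, 10, 11),
    "DJF": (12, 1, 2),
}

ANNUAL_MONTHS: tuple[int, ...] = tuple(range(1, 13))


class UndefinedCorrelationError(ValueError):
    """A correlation is undefined (zero variance or exact collinearity)."""


# ---------------------------------------------------------------------------
# correlation primitives
# ---------------------------------------------------------------------------

def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 3:
        raise ValueError(f"{name} needs at least 3 samples")
    return arr


def pearson(a, b) -> float:
    """Pearson correlation of two equal-length annual series.

    Zero-variance input raises :class:`UndefinedCorrelationError` — an
    undefined correlation is distinct from r = 0.
    """
    x = _as_series(a, "a")
    y = _as_series(b, "b")
    if x.size != y.size:
        raise ValueError("series must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(xc @ xc)
    sy = float(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant series")
    return float((xc @ yc) / np.sqrt(sx * sy))


def _ols_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    # residuals of y ~ 1 + x
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise UndefinedCorrelationError("control series is constant")
    yc = y - y.mean()
    return yc - xc * (float(xc @ yc) / sxx)


def partial_corr(a, b, control) -> float:
    """Partial correlation of ``a`` and ``b`` controlling for ``control``.

    Computed as the Pearson correlation of the OLS residuals of a~control
    and b~control; equals the closed form
    (r_ab - r_ac r_bc) / sqrt((1-r_ac^2)(1-r_bc^2)).
    """
    x = _as_series(a, "a")
    y = _as_series(b, "b")
    z = _as_series(control, "control")
    if not (x.size == y.size == z.size):
        raise ValueError("series must have equal length")
    rx = _ols_residuals(x, z)
    ry = _ols_residuals(y, z)
    # residual variance 0 means the control explains the series exactly
    tol = 1e-14
    if float(rx @ rx) <= tol * float(x @ x) or float(ry @ ry) <= tol * float(y @ y):
        raise UndefinedCorrelationError("series collinear with the control")
    return pearson(rx, ry)


@dataclass(frozen=True)
class CorrelationResult:
    """Global simple and partial correlations of X_G with TWS_G and T_G."""

    r_tws: float
    r_t: float
    partial_r_tws: float
    partial_r_t: float
    n_years: int


def correlations(series: GlobalAnnualSeries) -> CorrelationResult:
    """r_TWS, r_T and the partials controlling for the other driver."""
    return CorrelationResult(
        r_tws=pearson(series.x_g, series.tws_g),
        r_t=pearson(series.x_g, series.t_g),
        partial_r_tws=partial_corr(series.x_g, series.tws_g, series.t_g),
        partial_r_t=partial_corr(series.x_g, series.t_g, series.tws_g),
        n_years=series.n_years,
    )


# ---------------------------------------------------------------------------
# contribution maps
# ---------------------------------------------------------------------------

@dataclass
class ContributionMap:
    """Per-cell, per-calendar-month contributions to the global correlations.

    ``c_t[m-1]`` and ``c_tws[m-1]`` are the C^T and C^TWS maps of calendar
    month m; they sum (over all cells and months) to ``r_t`` and ``-r_tws``.
    Cell-months whose anomaly variance is zero contribute exactly 0 and are
    flagged in ``zero_variance`` (their correlation is undefined, not zero).
    """

    geometry: GridGeometry
    c_t: np.ndarray        # (12, nlat, nlon)
    c_tws: np.ndarray      # (12, nlat, nlon)
    sigma_x: np.ndarray    # (12, nlat, nlon), PgC month^-1
    zero_variance: np.ndarray
    r_t: float
    r_tws: float
    sigma_x_g: float
    n_years: int


def contribution_map(cube: AnomalyCube, series: GlobalAnnualSeries) -> ContributionMap:
    """Decompose r_T and r_TWS into per-cell per-month contributions.

    The across-years series of each cell-month is correlated with T_G (and
    TWS_G) over the same retained years as the global correlation, then
    scaled by sigma_x / sigma_X_G (sample standard deviations, n-1
    throughout). Implemented directly as cov(x_{i,m}, .) / (sigma_X_G *
    sigma_.), which is the identical quantity and makes the zero-variance
    case contribute an exact 0.
    """
    if cube.retained_years.size != series.n_years or not np.array_equal(
        cube.retained_years, series.years
    ):
        raise ValueError("cube and global series must share the same retained years")
    n = series.n_years
    x = cube.nee[cube.retained]                     # (Y, 12, nlat, nlon)
    xc = x - x.mean(axis=0)
    tc = series.t_g - series.t_g.mean()
    wc = series.tws_g - series.tws_g.mean()
    xg = series.x_g
    sigma_x_g = float(np.std(xg, ddof=1))
    if sigma_x_g == 0.0:
        raise UndefinedCorrelationError("global NEE anomaly has zero variance")
    sigma_t = float(np.std(series.t_g, ddof=1))
    sigma_tws = float(np.std(series.tws_g, ddof=1))
    if sigma_t == 0.0 or sigma_tws == 0.0:
        raise UndefinedCorrelationError("global driver series has zero variance")

    cov_t = np.tensordot(tc, xc, axes=(0, 0)) / (n - 1)
    cov_tws = np.tensordot(wc, xc, axes=(0, 0)) / (n - 1)
    c_t = cov_t / (sigma_x_g * sigma_t)
    c_tws = -cov_tws / (sigma_x_g * sigma_tws)
    sigma_x = x.std(axis=0, ddof=1)
    return ContributionMap(
        geometry=cube.geometry,
        c_t=c_t,
        c_tws=c_tws,
        sigma_x=sigma_x,
        zero_variance=(sigma_x == 0.0),
        r_t=pearson(xg, series.t_g),
        r_tws=pearson(xg, series.tws_g),
        sigma_x_g=sigma_x_g,
        n_years=n,
    )


# ---------------------------------------------------------------------------
# regional / seasonal aggregation
# ---------------------------------------------------------------------------

SeasonSpec = "tuple[int, ...] | np.ndarray"


def _season_selector(season, shape: tuple[int, int]) -> np.ndarray:
    """Normalize a season spec to a (12, nlat, nlon) boolean selector.

    A season is either a tuple of calendar months (1..12), applied uniformly
    to every cell (NH seasons, annual), or an explicit per-cell month mask of
    shape (12, nlat, nlon) (tropical dry/wet seasons).
    """
    if isinstance(season, np.ndarray) and season.ndim == 3:
        if season.shape != (12,) + shape:
            raise ValueError(f"per-cell season mask must have shape (12, {shape[0]}, {shape[1]})")
        return season.astype(bool)
    months = np.asarray(season, dtype=int)
    if months.size == 0 or np.any((months < 1) | (months > 12)):
        raise ValueError("season months must lie in 1..12")
    sel = np.zeros((12,) + shape, dtype=bool)
    sel[months - 1] = True
    return sel


def aggregate_contributions(
    cmap: ContributionMap,
    regions: list[RegionMask],
    seasons: dict[str, "SeasonSpec"] | None = None,
) -> pd.DataFrame:
    """Sum contributions over (region x season) and express fractional shares.

    ``seasons`` maps a label to either a tuple of calendar months or a
    per-cell (12, nlat, nlon) month mask; by default only the annual sum
    (all 12 months) is reported. Shares are relative to |r|: a region/season
    whose NEE variability opposes the global relationship gets a negative
    share. Empty regions contribute 0 and are flagged.

    Returns a tidy frame with columns region, season, C_T, C_TWS, share_T,
    share_TWS, n_cells, empty.
    """
    if seasons is None:
        seasons = {"annual": ANNUAL_MONTHS}
    rows = []
    for region in regions:
        region.validate(cmap.geometry)
        cells = region.member_cells
        for label, season in seasons.items():
            sel = _season_selector(season, cmap.geometry.shape) & cells[None, :, :]
            c_t = float(cmap.c_t[sel].sum())
            c_tws = float(cmap.c_tws[sel].sum())
            rows.append(
                {
                    "region": region.name,
                    "season": label,
                    "C_T": c_t,
                    "C_TWS": c_tws,
                    "share_T": c_t / abs(cmap.r_t),
                    "share_TWS": c_tws / abs(cmap.r_tws),
                    "n_cells": int(cells.sum()),
                    "empty": not bool(cells.any()),
                }
            )
    return pd.DataFrame(rows)


def remove_region(cube: AnomalyCube, region: RegionMask) -> AnomalyCube:
    """A copy of the cube with the region's NEE anomaly removed (set to 0).

    Recomputing the global correlation on the result operationalizes the
    reading of a positive contribution: removing that region's NEE
    variability should shrink |r|.
    """
    nee = cube.nee.copy()
    nee[:, :, region.member_cells] = 0.0
    return AnomalyCube(
        geometry=cube.geometry,
        years=cube.years,
        nee=nee,
        tws=cube.tws,
        temp=cube.temp,
        detrend_mode=cube.detrend_mode,
        excluded_years=cube.excluded_years,
    )


# ---------------------------------------------------------------------------
# multi-dataset sign consistency
# ---------------------------------------------------------------------------

def sign_consistency(
    maps: list[ContributionMap],
    regions: list[RegionMask],
    seasons: dict[str, "SeasonSpec"] | None = None,
    min_agreeing: int | None = None,
) -> pd.DataFrame:
    """Across-dataset sign agreement of aggregated contributions.

    ``maps`` are ContributionMaps from >= 2 input datasets on the same grid.
    Each is aggregated over (region x season); for each aggregate and driver
    the result reports whether every dataset agrees in sign (``all_agree``)
    and whether at least ``min_agreeing`` of them share the sign of the
    ensemble mean (``majority_agree``; default rule: strictly more than
    10 of 14, scaled as ceil(n * 11/14) for other ensemble sizes).
    """
    if len(maps) < 2:
        raise ValueError("sign consistency needs at least 2 datasets")
    shape = maps[0].geometry.shape
    for m in maps[1:]:
        if m.geometry.shape != shape:
            raise ValueError("contribution maps are on mismatched grids")
    summaries = [aggregate_contributions(m, regions, seasons) for m in maps]
    keys = summaries[0][["region", "season"]]
    n = len(summaries)
    if min_agreeing is None:
        min_agreeing = int(np.ceil(n * 11.0 / 14.0))
    rows = []
    for quantity in ("C_T", "C_TWS"):
        values = np.stack([s[quantity].to_numpy() for s in summaries])  # (n, rows)
        signs = np.sign(values)
        mean_sign = np.sign(values.mean(axis=0))
        all_agree = np.all(signs == signs[0], axis=0) & (signs[0] != 0)
        n_with_mean = (signs == mean_sign).sum(axis=0)
        for i in range(len(keys)):
            rows.append(
                {
                    "region": keys["region"].iloc[i],
                    "season": keys["season"].iloc[i],
                    "quantity": quantity,
                    "all_agree": bool(all_agree[i]),
                    "n_agree_with_mean": int(n_with_mean[i]),
                    "majority_agree": bool(n_with_mean[i] >= min_agreeing),
                }
            )
    return pd.DataFrame(rows)
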