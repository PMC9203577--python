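"""Anomaly construction: detrending, extensive NEE, global series, CGR.

Two detrending modes are used by the analysis and kept as separate code
paths:

* ``whole-series`` — one OLS line is removed from each cell's full monthly
  series. Feeds the correlation/decomposition analysis.
* ``per-month-group`` — the across-years series of each calendar month is
  detrended independently (12 separate fits per cell). Feeds the seasonal
  sensitivity regressions.

Volcanic-year exclusion (default 1982, 1991, 1992) is applied AFTER
detrending and before any correlation: the trend is always fit on the full
record, and excluded years are dropped from the retained annual series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridGeometry, MonthlyFieldSet

DEFAULT_EXCLUDED_YEARS = (1982, 1991, 1992)

KG_PER_PG = 1e12


class AnomalyError(ValueError):
    """Raised when anomaly construction preconditions are violated."""


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def detrend_whole_series(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Remove an OLS straight line (fit on the sample index) along ``axis``.

    The result has zero mean and zero OLS slope along ``axis`` to float
    precision; a constant or exactly linear input maps to zeros.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[axis]
    if n < 2:
        raise AnomalyError("detrending needs at least 2 samples")
    x = np.moveaxis(x, axis, 0)
    t = np.arange(n, dtype=float)
    tc = t - t.mean()
    xc = x - x.mean(axis=0)
    # slope = <tc, xc> / <tc, tc>; subtracting mean first keeps residuals exact
    slope = np.tensordot(tc, xc, axes=(0, 0)) / (tc @ tc)
    resid = xc - tc.reshape((n,) + (1,) * (x.ndim - 1)) * slope
    return np.moveaxis(resid, 0, axis)


def detrend_by_month_group(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Detrend each calendar month's across-years series independently.

    ``values`` must cover whole calendar years along ``axis`` (length a
    multiple of 12, months ordered January..December within each year) and
    span at least 3 years. Trends that differ between calendar months are
    removed exactly, which a single whole-series fit cannot do.
    """
    x = np.asarray(values, dtype=float)
    n = x.shape[axis]
    if n % 12 != 0:
        raise AnomalyError("per-month-group detrending needs whole calendar years")
    n_years = n // 12
    if n_years < 3:
        raise AnomalyError("per-month-group detrending needs at least 3 years")
    x = np.moveaxis(x, axis, 0)
    grouped = x.reshape((n_years, 12) + x.shape[1:])
    resid = detrend_whole_series(grouped, axis=0)
    return np.moveaxis(resid.reshape(x.shape), 0, axis)


# ---------------------------------------------------------------------------
# extensive NEE
# ---------------------------------------------------------------------------

def to_extensive(nee_density: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Convert an NEE flux density (kgC m^-2 month^-1) to PgC month^-1 per cell.

    Multiplies by cell area and 1e-12 kg->Pg; cells outside the land mask are
    set to exactly zero so that spatial sums run over land only.
    """
    density = np.asarray(nee_density, dtype=float)
    extensive = density * (geometry.cell_area / KG_PER_PG)
    return np.where(geometry.land_mask, extensive, 0.0)


# ---------------------------------------------------------------------------
# anomaly cube and global aggregation
# ---------------------------------------------------------------------------

@dataclass
class AnomalyCube:
    """Detrended per-cell anomalies arranged as (year, calendar month, lat, lon).

    ``nee`` holds the extensive NEE anomaly x_{i,m}(y) in PgC month^-1;
    ``tws`` (mm) and ``temp`` (degC) keep their native units. ``years`` lists
    every year of the fitting span; ``excluded_years`` are dropped only when
    annual series are formed downstream.
    """

    geometry: GridGeometry
    years: np.ndarray
    nee: np.ndarray   # (n_years, 12, nlat, nlon), PgC month^-1
    tws: np.ndarray   # mm
    temp: np.ndarray  # degC
    detrend_mode: str
    excluded_years: tuple[int, ...] = DEFAULT_EXCLUDED_YEARS

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.detrend_mode not in ("whole-series", "per-month-group"):
            raise AnomalyError(f"unknown detrend_mode '{self.detrend_mode}'")
        shape = (self.years.size, 12) + self.geometry.shape
        for name in ("nee", "tws", "temp"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise AnomalyError(f"'{name}' has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        self.excluded_years = tuple(int(y) for y in self.excluded_years)

    @property
    def retained(self) -> np.ndarray:
        """Boolean selector of years kept for the annual statistics."""
        return ~np.isin(self.years, self.excluded_years)

    @property
    def retained_years(self) -> np.ndarray:
        return self.years[self.retained]


def build_anomaly_cube(
    fieldset: MonthlyFieldSet,
    mode: str = "whole-series",
    excluded_years: tuple[int, ...] = DEFAULT_EXCLUDED_YEARS,
) -> AnomalyCube:
    """Detrend a field set and arrange NEE/TWS/T as an AnomalyCube.

    NEE is converted to the extensive PgC month^-1 form (the one conversion
    point in the pipeline) before detrending; detrending is linear, so the
    order does not matter, but extensive anomalies are what the covariance
    decomposition sums.
    """
    if mode == "whole-series":
        detrend = detrend_whole_series
    elif mode == "per-month-group":
        detrend = detrend_by_month_group
    else:
        raise AnomalyError(f"unknown detrend mode '{mode}'")
    n_years = fieldset.n_years
    shape = (n_years, 12) + fieldset.geometry.shape

    nee_ext = to_extensive(fieldset.nee, fieldset.geometry)
    return AnomalyCube(
        geometry=fieldset.geometry,
        years=fieldset.years,
        nee=detrend(nee_ext, axis=0).reshape(shape),
        tws=detrend(fieldset.tws, axis=0).reshape(shape),
        temp=detrend(fieldset.temp, axis=0).reshape(shape),
        detrend_mode=mode,
        excluded_years=tuple(excluded_years),
    )


@dataclass(frozen=True)
class GlobalAnnualSeries:
    """Retained-year global annual series: X_G (PgC yr^-1), T_G (degC), TWS_G (mm)."""

    years: np.ndarray
    x_g: np.ndarray
    t_g: np.ndarray
    tws_g: np.ndarray

    def __post_init__(self) -> None:
        for name in ("years", "x_g", "t_g", "tws_g"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (self.years.size == self.x_g.size == self.t_g.size == self.tws_g.size):
            raise AnomalyError("global series must share one set of retained years")
        if self.years.size < 3:
            raise AnomalyError("need at least 3 retained years")

    @property
    def n_years(self) -> int:
        return int(self.years.size)


def aggregate_global(cube: AnomalyCube) -> GlobalAnnualSeries:
    """Global annual series from a whole-series-detrended cube.

    X_G(y) is the plain sum of the extensive NEE anomaly over all cells and
    months of year y — the additivity that makes the covariance decomposition
    exact. T_G and TWS_G are area-weighted means over the land mask of the
    annual (mean-of-monthly) anomaly. Excluded years are dropped from all
    three series here, after detrending.
    """
    if cube.detrend_mode != "whole-series":
        raise AnomalyError("global correlation series require whole-series detrending")
    keep = cube.retained
    if keep.sum() < 3:
        raise AnomalyError("fewer than 3 retained years after exclusion")
    x_g = cube.nee[keep].sum(axis=(1, 2, 3))

    geom = cube.geometry
    weights = np.where(geom.land_mask, geom.cell_area, 0.0)
    wsum = weights.sum()
    annual_t = cube.temp[keep].mean(axis=1)   # (Y, nlat, nlon)
    annual_tws = cube.tws[keep].mean(axis=1)
    t_g = (annual_t * weights).sum(axis=(1, 2)) / wsum
    tws_g = (annual_tws * weights).sum(axis=(1, 2)) / wsum
    return GlobalAnnualSeries(years=cube.retained_years, x_g=x_g, t_g=t_g, tws_g=tws_g)


# ---------------------------------------------------------------------------
# CO2 growth rate
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CGRSeries:
    """Annual atmospheric CO2 growth rate, ppm yr^-1.

    ``cgr[k]`` is the January-to-January increment of year ``years[k]``:
    CO2(Jan, years[k]+1) - CO2(Jan, years[k]).
    """

    years: np.ndarray
    cgr: np.ndarray


def compute_cgr(co2: pd.DataFrame) -> CGRSeries:
    """CO2 growth rate from a monthly mole-fraction table.

    Parameters
    ----------
    co2 : DataFrame with columns ``year``, ``month``, ``ppm`` (NOAA
        MBL-like monthly layout). Requires January of at least 2 consecutive
        years.
    """
    required = {"year", "month", "ppm"}
    if not required.issubset(co2.columns):
        raise AnomalyError(f"CO2 table must have columns {sorted(required)}")
    jan = co2.loc[co2["month"] == 1].sort_values("year")
    years = jan["year"].to_numpy(dtype=int)
    if years.size < 2:
        raise AnomalyError("need January values for at least 2 years")
    if np.any(np.diff(years) != 1):
        raise AnomalyError("missing January: years with January values must be consecutive")
    ppm = jan["ppm"].to_numpy(dtype=float)
    return CGRSeries(years=years[:-1], cgr=np.diff(ppm))
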