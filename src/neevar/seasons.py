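"""Dry/wet season classification and per-cell seasonal sensitivity regression.

A tropical month is "dry" when the climatological (long-term mean) monthly
potential evapotranspiration strictly exceeds precipitation in that cell;
otherwise it is "wet" (ties count as wet). Cells whose whole year is dry or
wet have no seasonal contrast and are flagged excluded.

The seasonal sensitivities of NEE to water storage and temperature come from
a per-cell multiple regression on anomalies: the monthly series of each
variable is detrended per calendar-month group, the months of a season are
summed into one value per year, and NEE_s is regressed on (TWS_s, T_s) with
an intercept,

    NEE_s = a^TWS * TWS_s + a^T * T_s + eps .

a^TWS is in PgC month^-1 per mm and a^T in PgC month^-1 per degC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anomalies import AnomalyCube
from .grid import GridGeometry


class SeasonError(ValueError):
    """Raised when season classification or regression inputs are invalid."""


# ---------------------------------------------------------------------------
# dry / wet classification
# ---------------------------------------------------------------------------

@dataclass
class SeasonMask:
    """Per-cell dry/wet month classification with exclusion flags.

    ``dry[m-1]`` is True where calendar month m is climatologically dry
    (PET > precipitation, strict). ``excluded`` flags cells with 0 or 12 dry
    months, which have no dry/wet contrast within the year. Both refer only
    to cells inside ``valid`` (the land mask used at classification time).
    """

    geometry: GridGeometry
    dry: np.ndarray       # (12, nlat, nlon) bool
    excluded: np.ndarray  # (nlat, nlon) bool
    valid: np.ndarray     # (nlat, nlon) bool, cells that were classified

    @property
    def wet(self) -> np.ndarray:
        return ~self.dry & self.valid[None, :, :]

    def season_selector(self, which: str) -> np.ndarray:
        """(12, nlat, nlon) month mask for 'dry' or 'wet', non-excluded cells only."""
        usable = (self.valid & ~self.excluded)[None, :, :]
        if which == "dry":
            return self.dry & usable
        if which == "wet":
            return ~self.dry & usable
        raise SeasonError(f"unknown season '{which}'")


def classify_dry_wet(
    precip_clim: np.ndarray,
    pet_clim: np.ndarray,
    geometry: GridGeometry,
) -> SeasonMask:
    """Classify each cell's calendar months as dry or wet.

    Parameters
    ----------
    precip_clim, pet_clim : (12, nlat, nlon) climatological monthly means,
        mm month^-1. Classification uses one fixed partition per cell from
        the long-term seasonal cycle, not year-by-year values.
    """
    precip = np.asarray(precip_clim, dtype=float)
    pet = np.asarray(pet_clim, dtype=float)
    expected = (12,) + geometry.shape
    if precip.shape != expected or pet.shape != expected:
        raise SeasonError(f"climatologies must have shape {expected} (12 monthly means)")
    if np.any(np.isnan(precip[:, geometry.land_mask])) or np.any(
        np.isnan(pet[:, geometry.land_mask])
    ):
        raise SeasonError("climatology has missing months over land")
    valid = geometry.land_mask.copy()
    dry = (pet > precip) & valid[None, :, :]
    n_dry = dry.sum(axis=0)
    excluded = valid & ((n_dry == 0) | (n_dry == 12))
    return SeasonMask(geometry=geometry, dry=dry, excluded=excluded, valid=valid)


def climatology(monthly: np.ndarray) -> np.ndarray:
    """Long-term mean seasonal cycle: (n_years*12, ...) -> (12, ...)."""
    x = np.asarray(monthly, dtype=float)
    if x.shape[0] % 12 != 0:
        raise SeasonError("climatology needs whole calendar years")
    return x.reshape((-1, 12) + x.shape[1:]).mean(axis=0)


def dry_season_length(mask: SeasonMask) -> np.ndarray:
    """Dry-season length in months per cell (0..12); NaN where excluded or not land."""
    length = mask.dry.sum(axis=0).astype(float)
    length[~mask.valid | mask.excluded] = np.nan
    return length


# ---------------------------------------------------------------------------
# seasonal sensitivity regression
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMap:
    """Per-cell seasonal sensitivities of NEE to TWS and T with OLS errors.

    All maps are (nlat, nlon); NaN marks cells where the regression is
    undefined (outside the land/season domain, degenerate or collinear
    predictors). ``resid_std`` is the residual standard deviation of the fit
    (ddof = 3: intercept + two slopes).
    """

    geometry: GridGeometry
    season: str
    a_tws: np.ndarray
    a_t: np.ndarray
    se_tws: np.ndarray
    se_t: np.ndarray
    resid_std: np.ndarray
    n_years: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.a_tws)


def seasonal_totals(cube: AnomalyCube, season, label: str = "season") -> tuple[np.ndarray, ...]:
    """Sum each variable's per-month anomalies over the season months, per year.

    ``season`` is a tuple of calendar months or a (12, nlat, nlon) per-cell
    month mask (cells with no season months become all-zero and are left
    undefined by the regression). Returns (nee_s, tws_s, t_s, in_domain):
    (Y, nlat, nlon) seasonal sums over retained years and the cells where
    the season is nonempty.
    """
    from .decomp import _season_selector

    sel = _season_selector(season, cube.geometry.shape)
    keep = cube.retained
    weights = sel.astype(float)[None, :, :, :]
    nee_s = (cube.nee[keep] * weights).sum(axis=1)
    tws_s = (cube.tws[keep] * weights).sum(axis=1)
    t_s = (cube.temp[keep] * weights).sum(axis=1)
    in_domain = sel.any(axis=0)
    return nee_s, tws_s, t_s, in_domain


def seasonal_sensitivity(
    cube: AnomalyCube,
    season,
    label: str = "season",
    collinearity_tol: float = 1e-12,
) -> SensitivityMap:
    """Estimate a^TWS and a^T per cell for one season by multiple OLS.

    Requires a per-month-group detrended cube and at least 4 retained years.
    The per-cell design is [1, TWS_s, T_s]; the intercept is included as a
    guard against numerical mean drift even though anomalies are near
    zero-mean. Cells whose predictors are (near-)collinear — squared
    predictor correlation within ``collinearity_tol`` of 1 — are undefined
    (NaN), as are cells outside the land mask or season domain.
    """
    if cube.detrend_mode != "per-month-group":
        raise SeasonError("seasonal sensitivities require per-month-group detrending")
    n = int(cube.retained.sum())
    if n < 4:
        raise SeasonError("need at least 4 retained years for the seasonal regression")
    nee_s, tws_s, t_s, in_domain = seasonal_totals(cube, season, label)
    domain = in_domain & cube.geometry.land_mask

    # centered normal equations, vectorized over cells; centering makes the
    # slope estimates identical to the intercept-included fit
    wc = tws_s - tws_s.mean(axis=0)
    tc = t_s - t_s.mean(axis=0)
    yc = nee_s - nee_s.mean(axis=0)
    sww = (wc * wc).sum(axis=0)
    stt = (tc * tc).sum(axis=0)
    swt = (wc * tc).sum(axis=0)
    swy = (wc * yc).sum(axis=0)
    sty = (tc * yc).sum(axis=0)
    det = sww * stt - swt**2
    scale = sww * stt
    with np.errstate(invalid="ignore", divide="ignore"):
        ok = domain & (scale > 0) & (det > collinearity_tol * scale)
        a_tws = np.where(ok, (stt * swy - swt * sty) / det, np.nan)
        a_t = np.where(ok, (sww * sty - swt * swy) / det, np.nan)
        resid = yc - a_tws[None] * wc - a_t[None] * tc
        sse = np.where(ok, (resid * resid).sum(axis=0), np.nan)
        dof = n - 3
        if dof <= 0:
            raise SeasonError("need more retained years than regression parameters")
        s2 = sse / dof
        se_tws = np.sqrt(s2 * stt / det)
        se_t = np.sqrt(s2 * sww / det)
        resid_std = np.sqrt(s2)
    return SensitivityMap(
        geometry=cube.geometry,
        season=label,
        a_tws=a_tws,
        a_t=a_t,
        se_tws=np.where(ok, se_tws, np.nan),
        se_t=np.where(ok, se_t, np.nan),
        resid_std=np.where(ok, resid_std, np.nan),
        n_years=n,
    )
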