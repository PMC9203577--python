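"""Synthetic monthly field sets and CO2 series with planted ground truth.

The generator emulates the covariance structure the attribution analysis
assumes, not the physics: a few latent global climate modes (AR(1) annual
series expanded to months) drive co-varying temperature and water-storage
anomalies everywhere, and the NEE anomaly of each cell responds linearly to
its local TWS and T anomalies with planted, band- and month-dependent
sensitivities:

    x_{i,m} = a^TWS_{i,m} * TWS'_{i,m} + a^T_{i,m} * T'_{i,m} + noise

On top of the anomalies each variable carries a linear trend, a stationary
seasonal cycle, and white monthly noise; listed "volcanic" years receive an
additive NEE pulse so the year-exclusion logic has something to exclude.
Precipitation and PET climatologies are built so that each land cell has a
prescribed number of months with PET > precipitation.

All randomness flows from one root seed through named substreams, so any
single component is reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridGeometry, MonthlyFieldSet, default_bands

BAND_NAMES = ("NH", "tropics", "south")


class ConfigError(ValueError):
    """Raised when a simulation configuration is invalid."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModeSpec:
    """One latent global mode: an annual AR(1) series.

    ``std_annual`` is the stationary standard deviation of the annual values
    (dimensionless mode units; variables scale it through their loadings),
    ``ar1`` the lag-1 autocorrelation.
    """

    std_annual: float = 1.0
    ar1: float = 0.5


@dataclass(frozen=True)
class BandSensitivity:
    """Planted per-cell NEE sensitivities for one latitudinal band.

    ``a_tws`` (PgC month^-1 per mm) and ``a_t`` (PgC month^-1 per degC) are
    12-vectors indexed by calendar month, applied uniformly to every land
    cell of the band.
    """

    a_tws: tuple[float, ...]
    a_t: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("a_tws", "a_t"):
            vec = tuple(float(v) for v in getattr(self, name))
            if len(vec) == 1:
                vec = vec * 12
            if len(vec) != 12:
                raise ConfigError(f"{name} must have 1 or 12 entries")
            object.__setattr__(self, name, vec)


def _monthly(constant: float, **by_month: float) -> tuple[float, ...]:
    vec = [constant] * 12
    for key, value in by_month.items():
        vec[int(key[1:]) - 1] = value
    return tuple(vec)


def _default_sensitivity() -> dict[str, BandSensitivity]:
    # NH: spring warmth enhances uptake (negative), summer warmth releases
    # carbon (positive) — the seasonal-compensation sign structure; tropics
    # and south: water-dominated (wet years mean uptake, hence negative a_tws).
    nh_a_t = _monthly(0.0, m3=-5e-4, m4=-5e-4, m5=-5e-4, m6=8e-4, m7=8e-4, m8=8e-4,
                      m9=2e-4, m10=2e-4, m11=2e-4)
    return {
        "NH": BandSensitivity(a_tws=(-1e-6,), a_t=nh_a_t),
        "tropics": BandSensitivity(a_tws=(-5e-6,), a_t=(2e-4,)),
        "south": BandSensitivity(a_tws=(-3e-6,), a_t=(1e-4,)),
    }


@dataclass(frozen=True)
class TrendSpec:
    """Linear trends per year for one band: degC, mm, and PgC month^-1 per cell."""

    t_per_year: float = 0.02
    tws_per_year: float = -0.3
    nee_per_year: float = 1e-6


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic study.

    Defaults emulate the nominal study layout: 38 years (1979-2016), a 4-deg
    toy grid with ~30% land, two latent modes, band-wise sensitivities with
    the northern spring/summer sign flip, weak trends, monthly noise, NEE
    pulses in the three volcanic years, and tropical dry seasons of 5 months.
    """

    seed: int = 0
    n_years: int = 38
    start_year: int = 1979
    lat_step: float = 4.0
    lon_step: float = 4.0
    land_fraction: float = 0.3
    band_boundary: float = 25.0
    modes: tuple[ModeSpec, ...] = (ModeSpec(1.0, 0.6), ModeSpec(1.0, 0.2))
    mode_expansion: str = "linear"  # "linear" | "repeat"
    t_loadings: tuple[float, ...] = (0.6, 0.25)      # degC per mode unit
    tws_loadings: tuple[float, ...] = (40.0, -25.0)  # mm per mode unit
    sensitivity: dict[str, BandSensitivity] = field(default_factory=_default_sensitivity)
    trends: dict[str, TrendSpec] = field(
        default_factory=lambda: {
            "NH": TrendSpec(0.03, -0.2, 2e-6),
            "tropics": TrendSpec(0.02, -0.5, 1e-6),
            "south": TrendSpec(0.015, -0.3, 1e-6),
        }
    )
    noise_t: float = 0.4        # degC, monthly white noise per cell
    noise_tws: float = 20.0     # mm
    noise_nee: float = 5e-5     # PgC month^-1 per cell
    noise_precip: float = 3.0   # mm month^-1
    t_seasonal_amplitude: float = 5.0   # degC, scaled by sin(lat)
    nee_seasonal_amplitude: float = 0.005  # kgC m^-2 month^-1
    volcanic_years: tuple[int, ...] = (1982, 1991, 1992)
    volcanic_nee_pulse: float = -1e-4   # PgC month^-1 per land cell
    dry_months: dict[str, int] = field(
        default_factory=lambda: {"NH": 3, "tropics": 5, "south": 4}
    )
    arid_fraction: float = 0.05  # land cells forced to a year-round dry climate
    precip_base: float = 100.0   # mm month^-1, also the PET level
    precip_amplitude: float = 60.0

    def validate(self) -> None:
        if self.n_years < 3:
            raise ConfigError("n_years must be at least 3")
        if not 0 < self.land_fraction <= 1:
            raise ConfigError("land_fraction must be in (0, 1]")
        for spec in self.modes:
            if spec.std_annual < 0:
                raise ConfigError("mode std must be non-negative")
            if not -1 < spec.ar1 < 1:
                raise ConfigError("AR(1) coefficient must lie in (-1, 1)")
        for name in ("noise_t", "noise_tws", "noise_nee", "noise_precip"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.mode_expansion not in ("linear", "repeat"):
            raise ConfigError("mode_expansion must be 'linear' or 'repeat'")
        if len(self.t_loadings) != len(self.modes) or len(self.tws_loadings) != len(self.modes):
            raise ConfigError("loadings must have one entry per mode")
        for band in BAND_NAMES:
            if band not in self.sensitivity or band not in self.trends:
                raise ConfigError(f"missing sensitivity/trend spec for band '{band}'")
            if self.dry_months.get(band) is None or not 1 <= self.dry_months[band] <= 11:
                raise ConfigError("dry_months must map each band to 1..11")


@dataclass
class SimTruth:
    """Everything planted by the generator, for downstream recovery tests.

    ``nee_signal`` is the noiseless planted extensive NEE anomaly (the
    sensitivity terms only, no noise/trend/cycle/pulses); ``t_signal`` and
    ``tws_signal`` are the anomaly parts (modes + noise) of the climate
    fields. ``dry_month_count`` is NaN for cells forced arid.
    """

    config: SimConfig
    a_tws_map: np.ndarray       # (12, nlat, nlon)
    a_t_map: np.ndarray         # (12, nlat, nlon)
    modes_annual: np.ndarray    # (n_modes, n_years)
    modes_monthly: np.ndarray   # (n_modes, n_years*12)
    t_signal: np.ndarray        # (n_time, nlat, nlon) degC
    tws_signal: np.ndarray      # mm
    nee_signal: np.ndarray      # PgC month^-1
    dry_month_count: np.ndarray  # (nlat, nlon)
    arid_cells: np.ndarray       # (nlat, nlon) bool


# ---------------------------------------------------------------------------
# seeded substreams
# ---------------------------------------------------------------------------

def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible random substream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _ar1_series(rng: np.random.Generator, n: int, std: float, phi: float) -> np.ndarray:
    """Stationary AR(1) draw of length n with marginal std ``std``."""
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    scale = np.sqrt(1.0 - phi**2)
    for k in range(1, n):
        x[k] = phi * x[k - 1] + scale * eps[k]
    return std * x


def _expand_to_months(annual: np.ndarray, mode: str) -> np.ndarray:
    """Expand an annual series to months.

    "linear" interpolates between year-center knots (month index 5.5 of each
    year, flat beyond the ends); "repeat" holds each annual value for all 12
    months of its year.
    """
    n_years = annual.size
    if mode == "repeat":
        return np.repeat(annual, 12)
    t = np.arange(n_years * 12, dtype=float)
    knots = 12.0 * np.arange(n_years) + 5.5
    return np.interp(t, knots, annual)


# ---------------------------------------------------------------------------
# field-set generation
# ---------------------------------------------------------------------------

def _make_geometry(config: SimConfig) -> GridGeometry:
    nlat = int(round(180.0 / config.lat_step))
    nlon = int(round(360.0 / config.lon_step))
    rng = substream(config.seed, "land")
    mask = rng.random((nlat, nlon)) < config.land_fraction
    if not mask.any():
        mask[nlat // 2, nlon // 2] = True
    return GridGeometry.regular(config.lat_step, config.lon_step, mask)


def _loading_pattern(geometry: GridGeometry, k: int) -> np.ndarray:
    """Smooth deterministic spatial modulation of mode k's loading."""
    lat = np.deg2rad(geometry.lat_centers)[:, None]
    lon = np.deg2rad(geometry.lon_centers)[None, :]
    return 1.0 + 0.4 * np.sin((k + 1) * lat) + 0.2 * np.cos(lon + k)


def _band_maps(config: SimConfig, geometry: GridGeometry):
    bands = {b.name: b.member_cells for b in default_bands(geometry, config.band_boundary)}
    a_tws = np.zeros((12,) + geometry.shape)
    a_t = np.zeros((12,) + geometry.shape)
    trend_t = np.zeros(geometry.shape)
    trend_tws = np.zeros(geometry.shape)
    trend_nee = np.zeros(geometry.shape)
    for name in BAND_NAMES:
        cells = bands[name]
        sens = config.sensitivity[name]
        a_tws[:, cells] = np.asarray(sens.a_tws)[:, None]
        a_t[:, cells] = np.asarray(sens.a_t)[:, None]
        trend = config.trends[name]
        trend_t[cells] = trend.t_per_year
        trend_tws[cells] = trend.tws_per_year
        trend_nee[cells] = trend.nee_per_year
    return bands, a_tws, a_t, trend_t, trend_tws, trend_nee


def _precip_pet(config: SimConfig, geometry: GridGeometry, bands, arid: np.ndarray):
    """Climatologies with a planted number of PET>precip months per band.

    Dry months form a contiguous block whose start shifts with longitude;
    precipitation steps through evenly spaced levels around the PET line so
    the planted count is robust to climatological noise. Arid cells sit
    permanently below PET.
    """
    nlat, nlon = geometry.shape
    pet = np.full((12, nlat, nlon), config.precip_base)
    precip = np.full((12, nlat, nlon), config.precip_base + config.precip_amplitude / 2.0)
    months = np.arange(12)
    lon_phase = np.round(3.0 * np.sin(np.deg2rad(geometry.lon_centers))).astype(int)
    dry_count = np.zeros((nlat, nlon))
    base_phase = {"NH": 5, "tropics": 7, "south": 0}
    for name in BAND_NAMES:
        cells = bands[name] & ~arid
        if not cells.any():
            continue
        k = config.dry_months[name]
        phase = (base_phase[name] + lon_phase) % 12  # (nlon,)
        # rank r of each month relative to the block start; months with
        # r < k are the dry ones, stepped A/12 apart around the PET line
        rank = (months[:, None] - phase[None, :]) % 12          # (12, nlon)
        level = config.precip_base + config.precip_amplitude * (rank - k + 0.5) / 12.0
        precip_band = np.broadcast_to(level[:, None, :], (12, nlat, nlon))
        precip[:, cells] = precip_band[:, cells]
        dry_count[cells] = k
    precip[:, arid] = config.precip_base - config.precip_amplitude / 2.0
    dry_count[arid] = np.nan
    return precip, pet, dry_count


def generate_fieldset(config: SimConfig) -> tuple[MonthlyFieldSet, SimTruth]:
    """Generate a MonthlyFieldSet with planted structure and return its truth.

    Deterministic given ``config.seed``; every random component draws from
    its own named substream.
    """
    config.validate()
    geometry = _make_geometry(config)
    nlat, nlon = geometry.shape
    n_years = config.n_years
    n_time = n_years * 12
    years = config.start_year + np.arange(n_years)
    month_idx = np.tile(np.arange(12), n_years)
    year_frac = np.arange(n_time) / 12.0

    bands, a_tws_map, a_t_map, trend_t, trend_tws, trend_nee = _band_maps(config, geometry)

    # latent modes
    n_modes = len(config.modes)
    modes_annual = np.empty((n_modes, n_years))
    for k, spec in enumerate(config.modes):
        rng = substream(config.seed, f"mode{k}")
        modes_annual[k] = _ar1_series(rng, n_years, spec.std_annual, spec.ar1)
    modes_monthly = np.stack(
        [_expand_to_months(modes_annual[k], config.mode_expansion) for k in range(n_modes)]
    )

    # climate anomaly signals: loadings x modes + white noise
    t_signal = np.zeros((n_time, nlat, nlon))
    tws_signal = np.zeros((n_time, nlat, nlon))
    for k in range(n_modes):
        pattern = _loading_pattern(geometry, k)
        t_signal += config.t_loadings[k] * pattern[None] * modes_monthly[k][:, None, None]
        tws_signal += config.tws_loadings[k] * pattern[None] * modes_monthly[k][:, None, None]
    if config.noise_t > 0:
        t_signal += config.noise_t * substream(config.seed, "noise_t").standard_normal(
            t_signal.shape
        )
    if config.noise_tws > 0:
        tws_signal += config.noise_tws * substream(config.seed, "noise_tws").standard_normal(
            tws_signal.shape
        )

    # planted NEE response (extensive, PgC/month), land only
    land = geometry.land_mask
    nee_signal = (
        a_tws_map[month_idx] * tws_signal + a_t_map[month_idx] * t_signal
    ) * land[None]

    # assembled fields: anomaly signal + seasonal cycle + trend + noise (+ pulses)
    lat_rad = np.deg2rad(geometry.lat_centers)[None, :, None]
    t_cycle = (
        config.t_seasonal_amplitude
        * np.sin(lat_rad)
        * np.cos(2 * np.pi * (month_idx[:, None, None] - 6) / 12.0)
    )
    temp = t_signal + t_cycle + trend_t[None] * year_frac[:, None, None]
    tws = tws_signal + trend_tws[None] * year_frac[:, None, None]

    nee_ext = nee_signal + trend_nee[None] * year_frac[:, None, None] * land[None]
    if config.noise_nee > 0:
        nee_ext = nee_ext + config.noise_nee * substream(
            config.seed, "noise_nee"
        ).standard_normal(nee_ext.shape) * land[None]
    if config.volcanic_years:
        pulse_years = np.isin(np.repeat(years, 12), np.asarray(config.volcanic_years))
        nee_ext += config.volcanic_nee_pulse * pulse_years[:, None, None] * land[None]
    # store NEE as a flux density; the analysis converts back with the same areas
    with np.errstate(divide="ignore", invalid="ignore"):
        nee_density = np.where(land[None], nee_ext / (geometry.cell_area[None] * 1e-12), 0.0)
    nee_cycle = (
        config.nee_seasonal_amplitude
        * np.sin(lat_rad)
        * np.cos(2 * np.pi * (month_idx[:, None, None] - 7) / 12.0)
    )
    nee_density = nee_density + nee_cycle * land[None]

    # precipitation / PET with planted dry-season structure
    arid = np.zeros(geometry.shape, dtype=bool)
    if config.arid_fraction > 0:
        rng = substream(config.seed, "arid")
        arid = land & (rng.random(geometry.shape) < config.arid_fraction)
    precip_clim, pet_clim, dry_count = _precip_pet(config, geometry, bands, arid)
    precip = np.tile(precip_clim, (n_years, 1, 1))
    pet = np.tile(pet_clim, (n_years, 1, 1))
    if config.noise_precip > 0:
        rng = substream(config.seed, "noise_precip")
        precip = precip + config.noise_precip * rng.standard_normal(precip.shape)
        pet = pet + config.noise_precip * substream(
            config.seed, "noise_pet"
        ).standard_normal(pet.shape)

    fieldset = MonthlyFieldSet(
        geometry=geometry,
        years=years,
        nee=nee_density,
        tws=tws,
        temp=temp,
        precip=precip,
        pet=pet,
    )
    truth = SimTruth(
        config=config,
        a_tws_map=a_tws_map,
        a_t_map=a_t_map,
        modes_annual=modes_annual,
        modes_monthly=modes_monthly,
        t_signal=t_signal,
        tws_signal=tws_signal,
        nee_signal=nee_signal,
        dry_month_count=dry_count,
        arid_cells=arid,
    )
    return fieldset, truth


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

def make_compensation_scenario(strength: float, n_years: int = 38, seed: int = 0) -> SimConfig:
    """A noiseless diagnostic scenario with planted spring/summer compensation.

    Northern cells respond to temperature with a^T < 0 in spring (MAM) and
    a^T > 0 in summer (JJA), the spring magnitude being ``strength`` times
    the summer one, so at strength 1 the planted annual northern temperature
    contribution cancels by antisymmetry. The tropics and south are
    water-dominated. All noise, trends, pulses and seasonal cycles are off
    and modes are expanded piecewise-constant, which makes the cancellation
    structural rather than statistical.
    """
    if not 0.0 <= strength <= 1.0:
        raise ConfigError("strength must lie in [0, 1]")
    g = 8e-4
    nh_a_t = _monthly(0.0, m3=-strength * g, m4=-strength * g, m5=-strength * g,
                      m6=g, m7=g, m8=g)
    return SimConfig(
        seed=seed,
        n_years=n_years,
        mode_expansion="repeat",
        modes=(ModeSpec(1.0, 0.5), ModeSpec(1.0, 0.1)),
        t_loadings=(0.6, 0.3),
        tws_loadings=(40.0, -30.0),
        sensitivity={
            "NH": BandSensitivity(a_tws=(0.0,), a_t=nh_a_t),
            "tropics": BandSensitivity(a_tws=(-5e-6,), a_t=(0.0,)),
            "south": BandSensitivity(a_tws=(-3e-6,), a_t=(0.0,)),
        },
        trends={name: TrendSpec(0.0, 0.0, 0.0) for name in BAND_NAMES},
        noise_t=0.0,
        noise_tws=0.0,
        noise_nee=0.0,
        noise_precip=0.0,
        t_seasonal_amplitude=0.0,
        nee_seasonal_amplitude=0.0,
        volcanic_years=(),
    )


# ---------------------------------------------------------------------------
# CO2 series
# ---------------------------------------------------------------------------

def generate_co2_series(
    n_years: int,
    seed: int = 0,
    baseline: float = 340.0,
    increments: np.ndarray | None = None,
    mean_increment: float = 2.0,
    increment_std: float = 0.5,
    seasonal_amplitude: float = 3.0,
    noise_std: float = 0.0,
    start_year: int = 1979,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Monthly CO2 mole fractions with known January-to-January increments.

    The January value of year y is ``baseline`` plus the cumulative sum of
    the increments of all earlier years; within a year the series ramps
    linearly toward the next January, with a stationary seasonal cycle and
    optional white noise on top. With zero noise the annual growth rate
    (January-to-January difference) equals the planted increment exactly.

    Returns a (year, month, ppm) DataFrame spanning ``n_years`` years and
    the increment vector actually used (length ``n_years``, of which the
    first ``n_years - 1`` are observable as growth rates).
    """
    if n_years < 2:
        raise ConfigError("n_years must be at least 2")
    rng = substream(seed, "co2")
    if increments is None:
        increments = mean_increment + increment_std * rng.standard_normal(n_years)
    increments = np.asarray(increments, dtype=float)
    if increments.size != n_years:
        raise ConfigError("increments must have one entry per year")
    cumulative = np.concatenate([[0.0], np.cumsum(increments)[:-1]])  # at each January
    month = np.tile(np.arange(1, 13), n_years)
    year = np.repeat(start_year + np.arange(n_years), 12)
    within = (month - 1) / 12.0
    ppm = (
        baseline
        + np.repeat(cumulative, 12)
        + np.repeat(increments, 12) * within
        + seasonal_amplitude * np.cos(2 * np.pi * (month - 1) / 12.0)
    )
    if noise_std > 0:
        ppm = ppm + noise_std * rng.standard_normal(ppm.size)
    return pd.DataFrame({"year": year, "month": month, "ppm": ppm}), increments


# ---------------------------------------------------------------------------
# planted-truth summaries
# ---------------------------------------------------------------------------

def planted_band_shares(truth: SimTruth, geometry: GridGeometry) -> pd.DataFrame:
    """Fractional band shares of the planted NEE-driver covariances.

    Computed from the noiseless planted NEE signal and the realized driver
    anomalies, in the same convention the decomposition reports:
    share_T of band R is cov(X_R, T_G) / |cov(X_G, T_G)| and share_TWS is
    -cov(X_R, TWS_G) / |cov(X_G, TWS_G)|, with X_R the annual sum of the
    planted signal over the band's cells (the minus sign matches the C^TWS
    definition). This is the ground truth the decomposition should recover
    up to noise, trend estimation and year exclusion.
    """
    config = truth.config
    n_years = config.n_years
    land = geometry.land_mask
    weights = np.where(land, geometry.cell_area, 0.0)
    wsum = weights.sum()
    annual = truth.nee_signal.reshape(n_years, 12, *geometry.shape)
    t_ann = truth.t_signal.reshape(n_years, 12, *geometry.shape).mean(axis=1)
    tws_ann = truth.tws_signal.reshape(n_years, 12, *geometry.shape).mean(axis=1)
    t_g = (t_ann * weights).sum(axis=(1, 2)) / wsum
    tws_g = (tws_ann * weights).sum(axis=(1, 2)) / wsum

    def _cov(a, b):
        return float(np.cov(a, b, ddof=1)[0, 1])

    x_g = annual.sum(axis=(1, 2, 3))
    rows = []
    for band in default_bands(geometry, config.band_boundary):
        x_band = annual[:, :, band.member_cells].sum(axis=(1, 2))
        rows.append(
            {
                "region": band.name,
                "share_T": _cov(x_band, t_g) / abs(_cov(x_g, t_g)),
                "share_TWS": -_cov(x_band, tws_g) / abs(_cov(x_g, tws_g)),
            }
        )
    return pd.DataFrame(rows)
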