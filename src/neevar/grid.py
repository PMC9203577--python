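"""Grid geometry, monthly field sets, region masks and NetCDF I/O.

Conventions shared by the whole pipeline:

* Regular lat-lon grids, cell-center coordinates, latitude ascending.
* Cell areas from spherical geometry (Earth radius 6 371 000 m); only the
  relative weights matter for area-weighted means.
* The time axis is calendar months, ordered January..December within each
  year, covering an integer number of years.
* NEE is stored as a flux density in kgC m^-2 month^-1 with positive values
  meaning a net carbon release from land to the atmosphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import xarray as xr

EARTH_RADIUS_M = 6_371_000.0

#: canonical variable names of a MonthlyFieldSet, in storage order
FIELD_VARIABLES = ("nee", "tws", "temp", "precip", "pet")

#: units recorded in NetCDF output for each canonical variable
FIELD_UNITS = {
    "nee": "kgC m-2 month-1",
    "tws": "mm",
    "temp": "degC",
    "precip": "mm month-1",
    "pet": "mm month-1",
}


class GridError(ValueError):
    """Raised when a grid, field set or mask violates its contract."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def spherical_cell_areas(lat_centers: np.ndarray, lon_centers: np.ndarray) -> np.ndarray:
    """Cell areas in m^2 for a regular lat-lon grid defined by its centers.

    The area of a cell spanning [lat_s, lat_n] x [lon_w, lon_e] on a sphere is
    ``R^2 * (sin lat_n - sin lat_s) * (lon_e - lon_w)`` with angles in radians,
    which makes the areas proportional to cos(latitude) for small spacings.
    """
    lat = np.asarray(lat_centers, dtype=float)
    lon = np.asarray(lon_centers, dtype=float)
    dlat = _uniform_spacing(lat, "latitude")
    dlon = _uniform_spacing(lon, "longitude")
    lat_n = np.clip(lat + dlat / 2.0, -90.0, 90.0)
    lat_s = np.clip(lat - dlat / 2.0, -90.0, 90.0)
    band = EARTH_RADIUS_M**2 * (np.sin(np.deg2rad(lat_n)) - np.sin(np.deg2rad(lat_s)))
    return np.repeat((band * np.deg2rad(dlon))[:, None], lon.size, axis=1)


def _uniform_spacing(coords: np.ndarray, name: str) -> float:
    if coords.size < 2:
        return 180.0 if name == "latitude" else 360.0
    steps = np.diff(coords)
    if np.any(steps <= 0):
        raise GridError(f"{name} centers must be strictly ascending")
    if not np.allclose(steps, steps[0], rtol=1e-6):
        raise GridError(f"{name} centers must be regularly spaced")
    return float(steps[0])


@dataclass(frozen=True)
class GridGeometry:
    """A regular lat-lon grid with land mask and spherical cell areas.

    Parameters
    ----------
    lat_centers : (nlat,) array of cell-center latitudes, degrees north, ascending.
    lon_centers : (nlon,) array of cell-center longitudes, degrees east.
    land_mask : (nlat, nlon) boolean array, True over land. Binary: fractional
        coastal cells are not represented.
    cell_area : (nlat, nlon) array of cell areas in m^2; computed from
        spherical geometry when omitted.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    land_mask: np.ndarray
    cell_area: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        mask = np.asarray(self.land_mask, dtype=bool)
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        object.__setattr__(self, "land_mask", mask)
        if mask.shape != (lat.size, lon.size):
            raise GridError(
                f"land_mask shape {mask.shape} does not match grid ({lat.size}, {lon.size})"
            )
        if not mask.any():
            raise GridError("land_mask has no land cells")
        if self.cell_area is None:
            area = spherical_cell_areas(lat, lon)
        else:
            area = np.asarray(self.cell_area, dtype=float)
            if area.shape != mask.shape:
                raise GridError("cell_area shape does not match grid")
        if np.any(area <= 0):
            raise GridError("cell_area must be positive everywhere")
        object.__setattr__(self, "cell_area", area)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def n_land(self) -> int:
        return int(self.land_mask.sum())

    @classmethod
    def regular(cls, lat_step: float, lon_step: float, land_mask: np.ndarray) -> "GridGeometry":
        """Build a global grid with the given spacings and land mask."""
        nlat = int(round(180.0 / lat_step))
        nlon = int(round(360.0 / lon_step))
        lat = -90.0 + lat_step * (np.arange(nlat) + 0.5)
        lon = -180.0 + lon_step * (np.arange(nlon) + 0.5)
        return cls(lat, lon, land_mask)


# ---------------------------------------------------------------------------
# monthly field sets
# ---------------------------------------------------------------------------

@dataclass
class MonthlyFieldSet:
    """Co-registered monthly NEE / TWS / T / precipitation / PET fields.

    All arrays have shape ``(n_years * 12, nlat, nlon)`` with months ordered
    January..December within each year. NEE is a flux density
    (kgC m^-2 month^-1, positive = release to atmosphere); TWS is a storage
    anomaly in mm; temperature in degC; precipitation and PET in mm month^-1.
    """

    geometry: GridGeometry
    years: np.ndarray  # (n_years,) consecutive calendar years
    nee: np.ndarray
    tws: np.ndarray
    temp: np.ndarray
    precip: np.ndarray
    pet: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        if self.years.size < 3:
            raise GridError("a field set must span at least 3 whole years")
        if np.any(np.diff(self.years) != 1):
            raise GridError("years must be consecutive")
        n_time = self.years.size * 12
        shape = (n_time,) + self.geometry.shape
        for name in FIELD_VARIABLES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise GridError(
                    f"variable '{name}' has shape {arr.shape}, expected {shape}"
                )
            setattr(self, name, arr)

    @property
    def n_years(self) -> int:
        return int(self.years.size)

    @property
    def month_of_step(self) -> np.ndarray:
        """Calendar month (1..12) of each time step."""
        return np.tile(np.arange(1, 13), self.n_years)

    @property
    def year_of_step(self) -> np.ndarray:
        return np.repeat(self.years, 12)


# ---------------------------------------------------------------------------
# region masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMask:
    """A named set of land cells."""

    name: str
    member_cells: np.ndarray  # (nlat, nlon) bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "member_cells", np.asarray(self.member_cells, dtype=bool))

    def validate(self, geometry: GridGeometry) -> None:
        if self.member_cells.shape != geometry.shape:
            raise GridError(f"region '{self.name}' shape does not match grid")
        if np.any(self.member_cells & ~geometry.land_mask):
            raise GridError(f"region '{self.name}' extends outside the land mask")


def validate_partition(regions: list[RegionMask], geometry: GridGeometry) -> None:
    """Check that the regions are pairwise disjoint and cover the land mask."""
    total = np.zeros(geometry.shape, dtype=int)
    for region in regions:
        region.validate(geometry)
        total += region.member_cells
    if np.any(total > 1):
        raise GridError("region masks overlap")
    if np.any((total == 0) & geometry.land_mask):
        raise GridError("region masks do not cover the land mask")


def default_bands(geometry: GridGeometry, boundary: float = 25.0) -> list[RegionMask]:
    """The three latitudinal bands used for regional attribution.

    Northern Hemisphere is land strictly north of ``boundary`` (default 25 N),
    the tropics span ``-boundary..boundary`` inclusive, and the southern
    extra-tropics lie strictly south of ``-boundary``. A cell belongs to a
    band by its center latitude, so the three masks always partition the land
    mask.
    """
    lat = geometry.lat_centers[:, None]
    land = geometry.land_mask
    bands = [
        RegionMask("NH", land & (lat > boundary)),
        RegionMask("tropics", land & (lat >= -boundary) & (lat <= boundary)),
        RegionMask("south", land & (lat < -boundary)),
    ]
    validate_partition(bands, geometry)
    return bands


# ---------------------------------------------------------------------------
# NetCDF I/O
# ---------------------------------------------------------------------------

def _geometry_to_dataset(geometry: GridGeometry) -> xr.Dataset:
    return xr.Dataset(
        {
            "land_mask": (("lat", "lon"), geometry.land_mask.astype(np.int8)),
            "cell_area": (("lat", "lon"), geometry.cell_area, {"units": "m2"}),
        },
        coords={"lat": geometry.lat_centers, "lon": geometry.lon_centers},
    )


def _geometry_from_dataset(ds: xr.Dataset) -> GridGeometry:
    lat = np.asarray(ds["lat"].values, dtype=float)
    if lat.size > 1 and lat[0] > lat[-1]:
        raise GridError("latitude coordinate must be ascending")
    return GridGeometry(
        lat_centers=lat,
        lon_centers=np.asarray(ds["lon"].values, dtype=float),
        land_mask=np.asarray(ds["land_mask"].values).astype(bool),
        cell_area=np.asarray(ds["cell_area"].values, dtype=float),
    )


def write_fieldset(fieldset: MonthlyFieldSet, path) -> None:
    """Write a MonthlyFieldSet to a CF-style NetCDF file.

    Layout: dimensions ``time``/``lat``/``lon``; auxiliary integer coordinates
    ``year(time)`` and ``month(time)``; one data variable per canonical field
    plus ``land_mask`` and ``cell_area``.
    """
    ds = _geometry_to_dataset(fieldset.geometry)
    n_time = fieldset.n_years * 12
    ds = ds.assign_coords(
        time=np.arange(n_time),
        year=("time", fieldset.year_of_step),
        month=("time", fieldset.month_of_step),
    )
    for name in FIELD_VARIABLES:
        ds[name] = (("time", "lat", "lon"), getattr(fieldset, name), {"units": FIELD_UNITS[name]})
    ds.attrs["nee_sign_convention"] = "positive = net carbon release from land"
    ds.to_netcdf(path, engine="scipy")


def read_fieldset(path, variable_map: dict[str, str] | None = None) -> MonthlyFieldSet:
    """Read a MonthlyFieldSet from NetCDF.

    Parameters
    ----------
    path : file written by :func:`write_fieldset` or any NetCDF file with
        dimensions time/lat/lon, integer ``year``/``month`` coordinates,
        ``land_mask`` and ``cell_area`` variables.
    variable_map : mapping from canonical names (``nee``, ``tws``, ``temp``,
        ``precip``, ``pet``) to the variable names used in the file. Identity
        by default.
    """
    variable_map = dict(variable_map or {})
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    geometry = _geometry_from_dataset(ds)
    year = np.asarray(ds["year"].values, dtype=int)
    month = np.asarray(ds["month"].values, dtype=int)
    years = _validate_time_axis(year, month)
    fields = {}
    for name in FIELD_VARIABLES:
        file_name = variable_map.get(name, name)
        if file_name not in ds:
            raise GridError(
                f"file is missing variable '{file_name}' (mapped to '{name}')"
            )
        fields[name] = np.asarray(ds[file_name].values, dtype=float)
    return MonthlyFieldSet(geometry=geometry, years=years, **fields)


def _validate_time_axis(year: np.ndarray, month: np.ndarray) -> np.ndarray:
    if year.size == 0 or year.size % 12 != 0:
        raise GridError("time axis must cover whole calendar years")
    expected_month = np.tile(np.arange(1, 13), year.size // 12)
    if not np.array_equal(month, expected_month):
        raise GridError("time axis is ragged: months must run January..December per year")
    years = year[::12]
    if not np.array_equal(year, np.repeat(years, 12)):
        raise GridError("time axis is ragged: year labels inconsistent within years")
    return years


def write_contribution_map(cmap, path) -> None:
    """Write a ContributionMap (per-cell, per-calendar-month C^TWS and C^T).

    The global correlations r_T and r_TWS that the map decomposes are stored
    as file attributes, alongside sigma_X_G and the sample size.
    """
    ds = _geometry_to_dataset(cmap.geometry)
    ds = ds.assign_coords(month=np.arange(1, 13))
    dims = ("month", "lat", "lon")
    ds["C_T"] = (dims, cmap.c_t)
    ds["C_TWS"] = (dims, cmap.c_tws)
    ds["sigma_x"] = (dims, cmap.sigma_x, {"units": "PgC month-1"})
    ds["zero_variance"] = (dims, cmap.zero_variance.astype(np.int8))
    ds.attrs.update(
        r_T=float(cmap.r_t),
        r_TWS=float(cmap.r_tws),
        sigma_X_G=float(cmap.sigma_x_g),
        n_years=int(cmap.n_years),
    )
    ds.to_netcdf(path, engine="scipy")


def read_contribution_map(path):
    """Read a ContributionMap written by :func:`write_contribution_map`."""
    from .decomp import ContributionMap

    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    return ContributionMap(
        geometry=_geometry_from_dataset(ds),
        c_t=np.asarray(ds["C_T"].values, dtype=float),
        c_tws=np.asarray(ds["C_TWS"].values, dtype=float),
        sigma_x=np.asarray(ds["sigma_x"].values, dtype=float),
        zero_variance=np.asarray(ds["zero_variance"].values).astype(bool),
        r_t=float(ds.attrs["r_T"]),
        r_tws=float(ds.attrs["r_TWS"]),
        sigma_x_g=float(ds.attrs["sigma_X_G"]),
        n_years=int(ds.attrs["n_years"]),
    )
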