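"""Gridded time-series containers shared by every pipeline stage.

All variables travel as one of three carriers on a regular lat/lon grid:

* :class:`DailyField` — daily values with a missing-data mask (satellite
  soil moisture and vegetation optical depth have daily gaps),
* :class:`MonthlyField` — contiguous calendar-month values,
* :class:`StaticField` — time-invariant layers (population density, land area).

Masks are boolean arrays with ``True`` marking missing data; values under the
mask are NaN. NetCDF round-tripping goes through :mod:`xarray` with CF-style
``time``/``lat``/``lon`` coordinates and NaN as ``_FillValue``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "Grid",
    "DailyField",
    "MonthlyField",
    "StaticField",
    "ClimatologyStats",
    "AnomalyField",
    "month_number",
    "month_tuple",
    "write_field",
    "read_field",
]


# ---------------------------------------------------------------------------
# calendar helpers: months are handled as integer offsets from year 0
# ---------------------------------------------------------------------------

def month_number(year: int, month: int) -> int:
    """Serial month index (year 0, January = 0). ``month`` is 1-based."""
    return year * 12 + (month - 1)


def month_tuple(number: int) -> tuple[int, int]:
    """Inverse of :func:`month_number`: serial index -> (year, month)."""
    return number // 12, number % 12 + 1


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Grid:
    """Regular lat/lon grid described by cell-center coordinates.

    Parameters
    ----------
    lat, lon
        Ascending cell-center coordinates in degrees.
    cell_size
        Cell edge length in degrees (square cells).
    """

    lat: np.ndarray
    lon: np.ndarray
    cell_size: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lat", np.asarray(self.lat, dtype=float))
        object.__setattr__(self, "lon", np.asarray(self.lon, dtype=float))

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, cell_size: float,
                lat0: float = -10.0, lon0: float = 0.0) -> "Grid":
        """Grid of ``n_lat × n_lon`` cells; (lat0, lon0) is the SW corner."""
        lat = lat0 + cell_size * (np.arange(n_lat) + 0.5)
        lon = lon0 + cell_size * (np.arange(n_lon) + 0.5)
        return cls(lat=lat, lon=lon, cell_size=float(cell_size))

    @property
    def shape(self) -> tuple[int, int]:
        return self.lat.size, self.lon.size

    @property
    def n_cells(self) -> int:
        return self.lat.size * self.lon.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return (self.cell_size == other.cell_size
                and np.array_equal(self.lat, other.lat)
                and np.array_equal(self.lon, other.lon))

    def cell_area_km2(self) -> np.ndarray:
        """Approximate spherical cell area, shape (n_lat, n_lon), km^2."""
        km_per_deg = 111.2
        widths = (km_per_deg * self.cell_size) ** 2 * np.cos(np.deg2rad(self.lat))
        return np.repeat(widths[:, None], self.lon.size, axis=1)


# ---------------------------------------------------------------------------
# field carriers
# ---------------------------------------------------------------------------

def _masked(values: np.ndarray, mask: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = ~np.isfinite(values)
    else:
        mask = np.asarray(mask, dtype=bool) | ~np.isfinite(values)
    values = values.copy()
    values[mask] = np.nan
    return values, mask


@dataclass
class StaticField:
    """Time-invariant gridded layer (population density, land area)."""

    values: np.ndarray          # (n_lat, n_lon)
    grid: Grid
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values, self.mask = _masked(self.values, self.mask)


@dataclass
class DailyField:
    """Daily gridded values starting at ``start`` (an ISO date string)."""

    values: np.ndarray          # (n_days, n_lat, n_lon)
    grid: Grid
    start: str                  # first day, "YYYY-MM-DD"
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values, self.mask = _masked(self.values, self.mask)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.values.shape[0], freq="D")


@dataclass
class MonthlyField:
    """Contiguous calendar-month gridded values.

    ``start`` is the (year, month) of the first time slice; the time axis has
    no skipped months by construction.
    """

    values: np.ndarray          # (n_months, n_lat, n_lon)
    grid: Grid
    start: tuple[int, int]      # (year, 1-based month)
    mask: np.ndarray | None = None
    units: str = ""

    def __post_init__(self) -> None:
        self.values, self.mask = _masked(self.values, self.mask)
        self.start = (int(self.start[0]), int(self.start[1]))

    @property
    def n_months(self) -> int:
        return self.values.shape[0]

    @property
    def month_numbers(self) -> np.ndarray:
        """Serial month index per time slice."""
        return month_number(*self.start) + np.arange(self.n_months)

    @property
    def month_of_year(self) -> np.ndarray:
        """1..12 per time slice."""
        return self.month_numbers % 12 + 1

    @property
    def years(self) -> np.ndarray:
        return self.month_numbers // 12

    def time_index(self, year: int, month: int) -> int:
        """Position of calendar (year, month) on the time axis."""
        idx = month_number(year, month) - month_number(*self.start)
        if not 0 <= idx < self.n_months:
            raise IndexError(f"{year}-{month:02d} outside field calendar")
        return idx

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(f"{self.start[0]}-{self.start[1]:02d}-01",
                             periods=self.n_months, freq="MS")


@dataclass
class ClimatologyStats:
    """Per-cell, per-month-of-year mean/sd over a reference period.

    ``sd`` uses the n−1 denominator. Cells with fewer than two valid years for
    a month-of-year, or zero spread, are masked (``mask`` True) so that the
    z-score step never divides by zero. "Zero spread" is judged relative to
    the mean's magnitude (|sd| ≤ 1e-12·max(|mean|, 1)) so that a constant
    series is degenerate even when rounding leaves a ~1e-16 residue.
    """

    mean: np.ndarray            # (12, n_lat, n_lon)
    sd: np.ndarray
    n: np.ndarray               # valid-year count, ints
    period: tuple[int, int]     # (first_year, last_year), inclusive
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mask is None:
            with np.errstate(invalid="ignore"):
                degenerate = ~(self.sd > 1e-12 * np.maximum(np.abs(self.mean), 1.0))
            self.mask = (self.n < 2) | degenerate
        self.mask = self.mask | ~np.isfinite(self.mean) | ~np.isfinite(self.sd)


@dataclass
class AnomalyField:
    """Dimensionless z-score anomalies on a monthly calendar."""

    z: np.ndarray               # (n_months, n_lat, n_lon)
    grid: Grid
    start: tuple[int, int]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.z, self.mask = _masked(self.z, self.mask)

    # mirror the MonthlyField calendar API
    n_months = MonthlyField.n_months
    month_numbers = MonthlyField.month_numbers
    month_of_year = MonthlyField.month_of_year
    years = MonthlyField.years
    time_index = MonthlyField.time_index

    @property
    def values(self) -> np.ndarray:  # uniform access for composite code
        return self.z


# ---------------------------------------------------------------------------
# NetCDF I/O (xarray, scipy backend, CF-style coordinates)
# ---------------------------------------------------------------------------

def _coords(grid: Grid) -> dict:
    return {"lat": ("lat", grid.lat, {"units": "degrees_north"}),
            "lon": ("lon", grid.lon, {"units": "degrees_east"})}


def to_dataset(fields: dict[str, DailyField | MonthlyField | StaticField]) -> xr.Dataset:
    """Bundle named fields (sharing one grid) into an xarray Dataset."""
    first = next(iter(fields.values()))
    ds = xr.Dataset(coords=_coords(first.grid))
    ds.attrs["cell_size_deg"] = first.grid.cell_size
    for name, f in fields.items():
        if f.grid != first.grid:
            raise ValueError("all fields in one dataset must share a grid")
        if isinstance(f, StaticField):
            ds[name] = (("lat", "lon"), f.values)
        else:
            ds[name] = (("time", "lat", "lon"), f.values)
            ds = ds.assign_coords(time=f.times)
        ds[name].attrs["units"] = f.units
        ds[name].encoding["_FillValue"] = np.nan
    return ds


def write_field(fields: dict[str, DailyField | MonthlyField | StaticField],
                path: str | Path) -> Path:
    """Write one or more same-grid fields to a NetCDF file."""
    path = Path(path)
    to_dataset(fields).to_netcdf(path, engine="scipy")
    return path


def _grid_of(ds: xr.Dataset) -> Grid:
    lat = np.asarray(ds["lat"].values, dtype=float)
    size = float(ds.attrs.get("cell_size_deg",
                              np.diff(lat).mean() if lat.size > 1 else 0.25))
    return Grid(lat=lat, lon=np.asarray(ds["lon"].values, dtype=float),
                cell_size=size)


def read_field(path: str | Path, name: str,
               kind: str = "monthly") -> DailyField | MonthlyField | StaticField:
    """Read one variable back as the requested carrier kind.

    ``kind`` is one of ``"daily"``, ``"monthly"``, ``"static"``.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    grid = _grid_of(ds)
    da = ds[name]
    units = str(da.attrs.get("units", ""))
    values = np.asarray(da.values, dtype=float)
    if kind == "static":
        return StaticField(values=values, grid=grid, units=units)
    times = pd.DatetimeIndex(ds["time"].values)
    if kind == "daily":
        return DailyField(values=values, grid=grid, units=units,
                          start=str(times[0].date()))
    if kind == "monthly":
        return MonthlyField(values=values, grid=grid, units=units,
                            start=(int(times[0].year), int(times[0].month)))
    raise ValueError(f"unknown field kind {kind!r}")
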