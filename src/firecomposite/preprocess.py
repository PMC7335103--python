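"""Temporal aggregation, regridding, climatology and z-score anomalies.

The analysis works on monthly fields at a common grid resolution. Daily
satellite retrievals (soil moisture, vegetation optical depth) are averaged
to calendar months, requiring a minimum number of valid days; every variable
is then expressed as a z-score anomaly relative to its month-of-year
climatology over the reference period, so that values from different cells
and seasons are comparable.
"""

from __future__ import annotations

import warnings

import numpy as np

from .fields import (
    AnomalyField,
    ClimatologyStats,
    DailyField,
    Grid,
    MonthlyField,
    StaticField,
    month_number,
)

__all__ = [
    "daily_to_monthly",
    "regrid",
    "monthly_climatology",
    "normalize_anomaly",
    "AnomalyField",
    "ClimatologyStats",
    "MonthlyField",
]


def daily_to_monthly(daily: DailyField, min_days: int = 15) -> MonthlyField:
    """Average daily values to calendar months.

    A month's value is the arithmetic mean of its valid (unmasked) days and is
    masked when fewer than ``min_days`` valid days are available — the
    screening applied to daily satellite retrievals before any anomaly is
    computed.

    Parameters
    ----------
    daily
        Daily field; the record may start or end mid-month, partial months are
        aggregated over the days present.
    min_days
        Minimum number of valid days for a monthly mean (default 15).
    """
    if min_days < 1 or min_days > 31:
        raise ValueError(f"min_days={min_days} impossible for any calendar month")
    times = daily.times
    codes = times.year.values * 12 + times.month.values - 1
    starts = np.flatnonzero(np.r_[True, np.diff(codes) != 0])
    valid = ~daily.mask
    filled = np.where(valid, daily.values, 0.0)
    sums = np.add.reduceat(filled, starts, axis=0)
    counts = np.add.reduceat(valid.astype(np.int64), starts, axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= min_days, sums / np.maximum(counts, 1), np.nan)
    return MonthlyField(values=means, grid=daily.grid, units=daily.units,
                        start=(int(times[0].year), int(times[0].month)))


# ---------------------------------------------------------------------------
# regridding
# ---------------------------------------------------------------------------

def _target_index(coords: np.ndarray, grid: Grid, axis: str) -> np.ndarray:
    centers = grid.lat if axis == "lat" else grid.lon
    origin = centers[0] - grid.cell_size / 2
    idx = np.floor((coords - origin) / grid.cell_size).astype(np.int64)
    idx[(coords < origin) | (coords > centers[-1] + grid.cell_size / 2)] = -1
    return np.clip(idx, -1, centers.size - 1)


def regrid(field, target: Grid, method: str = "cell-average"):
    """Map a gridded field onto ``target``.

    ``cell-average`` pools all source cells whose centers fall inside each
    target cell (mask-aware mean; empty target cells come out masked) and is
    meant for coarsening continuous fields. ``nearest`` picks the source cell
    containing each target center and also refines coarse layers such as the
    0.5° population grid onto 0.25° cells.
    """
    if field.grid == target:
        return field

    def rebuild(values):
        kwargs = dict(values=values, grid=target, units=getattr(field, "units", ""))
        if isinstance(field, StaticField):
            return StaticField(**kwargs)
        if isinstance(field, MonthlyField):
            return MonthlyField(start=field.start, **kwargs)
        if isinstance(field, DailyField):
            return DailyField(start=field.start, **kwargs)
        raise TypeError(f"cannot regrid {type(field).__name__}")

    values = field.values
    static = values.ndim == 2
    stacked = values[None] if static else values
    n_lat_t, n_lon_t = target.shape

    if method == "cell-average":
        if target.cell_size < field.grid.cell_size:
            raise ValueError("cell-average requires a target at least as coarse "
                             "as the source; use method='nearest' to refine")
        ilat = _target_index(field.grid.lat, target, "lat")
        ilon = _target_index(field.grid.lon, target, "lon")
        inside = (ilat[:, None] >= 0) & (ilon[None, :] >= 0)
        flat = (np.maximum(ilat, 0)[:, None] * n_lon_t + np.maximum(ilon, 0)[None, :])
        flat = flat.ravel()
        sel = inside.ravel()
        out = np.full((stacked.shape[0], n_lat_t * n_lon_t), np.nan)
        for t in range(stacked.shape[0]):
            vals = stacked[t].ravel()[sel]
            ok = np.isfinite(vals)
            sums = np.bincount(flat[sel][ok], weights=vals[ok],
                               minlength=n_lat_t * n_lon_t)
            cnts = np.bincount(flat[sel][ok], minlength=n_lat_t * n_lon_t)
            out[t] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
        out = out.reshape(stacked.shape[0], n_lat_t, n_lon_t)
    elif method == "nearest":
        ilat = _target_index(target.lat, field.grid, "lat")
        ilon = _target_index(target.lon, field.grid, "lon")
        out = np.where((ilat[:, None] >= 0) & (ilon[None, :] >= 0),
                       stacked[:, np.maximum(ilat, 0)[:, None],
                               np.maximum(ilon, 0)[None, :]],
                       np.nan)
    else:
        raise ValueError(f"unknown regrid method {method!r}")

    return rebuild(out[0] if static else out)


# ---------------------------------------------------------------------------
# climatology and anomalies
# ---------------------------------------------------------------------------

def monthly_climatology(field: MonthlyField,
                        period: tuple[int, int] | None = None) -> ClimatologyStats:
    """Month-of-year mean and standard deviation over a reference period.

    The standard deviation uses the sample (n−1) denominator. Month-of-year
    cells with fewer than two valid years, or zero spread, are masked so they
    can never be used as a z-score denominator.
    """
    years = field.years
    if period is None:
        period = (int(years.min()), int(years.max()))
    y0, y1 = period
    if y1 - y0 + 1 < 2:
        raise ValueError("climatology reference period must span >= 2 years")
    in_period = (years >= y0) & (years <= y1)
    if not in_period.any():
        raise ValueError("reference period outside the field calendar")

    moy = field.month_of_year
    shape = field.values.shape[1:]
    mean = np.full((12,) + shape, np.nan)
    sd = np.full((12,) + shape, np.nan)
    n = np.zeros((12,) + shape, dtype=np.int64)
    for m in range(1, 13):
        sel = in_period & (moy == m)
        if not sel.any():
            continue
        sample = field.values[sel]
        cnt = np.isfinite(sample).sum(axis=0)
        n[m - 1] = cnt
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            mean[m - 1] = np.where(cnt > 0, np.nanmean(sample, axis=0), np.nan)
            sd[m - 1] = np.where(cnt > 1, np.nanstd(sample, axis=0, ddof=1), np.nan)
    return ClimatologyStats(mean=mean, sd=sd, n=n, period=(y0, y1))


def normalize_anomaly(field: MonthlyField, clim: ClimatologyStats) -> AnomalyField:
    """z-score anomalies: value minus month-of-year mean over month-of-year sd.

    Entries are masked wherever the input is masked or the climatology cell is
    masked (undefined sd). An unmasked zero sd would violate the climatology
    contract and raises.
    """
    moy_idx = field.month_of_year - 1
    mean = clim.mean[moy_idx]
    sd = clim.sd[moy_idx]
    cmask = clim.mask[moy_idx]
    if np.any(~cmask & ~(sd > 0)):
        raise RuntimeError("climatology contract violated: unmasked sd <= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (field.values - mean) / sd
    z = np.where(field.mask | cmask, np.nan, z)
    return AnomalyField(z=z, grid=field.grid, start=field.start)
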