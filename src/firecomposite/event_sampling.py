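"""Largest-burned-area event extraction and the filter cascade.

Each grid cell contributes at most one event: the calendar month with the
highest burned area among months whose observed-area fraction exceeds the
reliability threshold. The candidate events are then filtered down to the
analysis set by (a) completeness of the soil-moisture anomaly record over the
event window, (b) a long-term mean-temperature floor that removes cells where
freezing degrades the soil-moisture retrievals, and (c) a population-density
ceiling that restricts the analysis to sparsely populated, near-natural
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import AnomalyField, MonthlyField, StaticField, month_number, month_tuple

__all__ = ["FireEvent", "FilterReport", "select_largest_events",
           "filter_events", "population_threshold", "events_to_frame"]

#: reporting order for first-failure attribution; survival itself is the
#: order-independent conjunction of all filters
FILTER_ORDER = ("obs_fraction", "sm_window_complete", "warm_enough", "low_population")


@dataclass
class FireEvent:
    """One retained (or candidate) largest-fire event of a grid cell."""

    cell: tuple[int, int]               # (lat_idx, lon_idx)
    event_time: tuple[int, int]         # (year, 1-based month)
    ba_fraction: float                  # burned area / land area
    filters_passed: dict = field(default_factory=dict)

    @property
    def passed_all(self) -> bool:
        return all(self.filters_passed.get(k, True) for k in FILTER_ORDER)


@dataclass
class FilterReport:
    """Counts of the event funnel with first-failure attribution."""

    n_candidates: int
    removed: dict
    retained: int
    population_threshold: float | None = None

    def check_conservation(self) -> bool:
        return self.retained + sum(self.removed.values()) == self.n_candidates


def select_largest_events(burned_area: MonthlyField,
                          observed_fraction: MonthlyField,
                          land_area: StaticField,
                          min_obs_fraction: float = 0.8) -> list[FireEvent]:
    """Per cell, the month with the maximum burned area.

    Months whose observed-area fraction is not strictly above
    ``min_obs_fraction`` are excluded from the maximisation (the burned-area
    product is unreliable there). Cells with no admissible month of positive
    burned area, or non-positive land area, yield no event. Ties on the
    maximum go to the earliest month.
    """
    if burned_area.grid != observed_fraction.grid or \
            burned_area.start != observed_fraction.start or \
            burned_area.n_months != observed_fraction.n_months:
        raise ValueError("burned area and observed fraction must share "
                         "grid and calendar")
    admissible = (~burned_area.mask
                  & ~observed_fraction.mask
                  & (observed_fraction.values > min_obs_fraction))
    ba = np.where(admissible, burned_area.values, -np.inf)
    best = np.argmax(ba, axis=0)                 # first occurrence wins ties
    best_val = np.take_along_axis(ba, best[None], axis=0)[0]
    land_ok = ~land_area.mask & (land_area.values > 0)

    events: list[FireEvent] = []
    y0, m0 = burned_area.start
    start_num = month_number(y0, m0)
    for i, j in np.argwhere((best_val > 0) & land_ok):
        t = int(best[i, j])
        events.append(FireEvent(
            cell=(int(i), int(j)),
            event_time=month_tuple(start_num + t),
            ba_fraction=float(best_val[i, j] / land_area.values[i, j]),
            filters_passed={"obs_fraction": True},
        ))
    return events


def population_threshold(population: StaticField,
                         availability: np.ndarray,
                         percentile: float = 25.0) -> float:
    """Empirical population-density percentile over available cells.

    ``availability`` marks cells that have any soil-moisture data; the
    percentile (linear interpolation between order statistics) is taken over
    that base set, not only over event cells.
    """
    sel = availability & ~population.mask
    if not sel.any():
        raise ValueError("no cells with population and soil-moisture data")
    return float(np.percentile(population.values[sel], percentile))


def filter_events(events: list[FireEvent],
                  sm_anomaly: AnomalyField,
                  temperature_mean: StaticField | np.ndarray,
                  population: StaticField,
                  window: tuple[int, int] = (-5, 1),
                  temp_min: float = 0.0,
                  pop_percentile: float = 25.0,
                  ) -> tuple[list[FireEvent], FilterReport]:
    """Apply the window-completeness, temperature and population filters.

    An event survives iff every soil-moisture anomaly between ``window[0]``
    and ``window[1]`` months of the event is present (lags reaching outside
    the record fail this filter, they do not raise), the cell's long-term
    mean temperature is at least ``temp_min`` (°C), and its population
    density is strictly below the ``pop_percentile``-th percentile over all
    cells with soil-moisture data. Every event's ``filters_passed`` flags are
    filled in; the report attributes each removal to its first failing
    filter in :data:`FILTER_ORDER`.
    """
    tmean = temperature_mean.values if isinstance(temperature_mean, StaticField) \
        else np.asarray(temperature_mean)
    availability = (~sm_anomaly.mask).any(axis=0)
    threshold = population_threshold(population, availability, pop_percentile)

    start_num = month_number(*sm_anomaly.start)
    n_months = sm_anomaly.n_months
    lo, hi = window
    retained: list[FireEvent] = []
    removed = {k: 0 for k in FILTER_ORDER[1:]}
    for ev in events:
        i, j = ev.cell
        t0 = month_number(*ev.event_time) - start_num
        lags = np.arange(t0 + lo, t0 + hi + 1)
        inside = (lags >= 0) & (lags < n_months)
        complete = bool(inside.all()
                        and not sm_anomaly.mask[lags, i, j].any())
        warm = bool(np.isfinite(tmean[i, j]) and tmean[i, j] >= temp_min)
        sparse = bool(~population.mask[i, j]
                      and population.values[i, j] < threshold)
        ev.filters_passed.update(sm_window_complete=complete,
                                 warm_enough=warm,
                                 low_population=sparse)
        if complete and warm and sparse:
            retained.append(ev)
        elif not complete:
            removed["sm_window_complete"] += 1
        elif not warm:
            removed["warm_enough"] += 1
        else:
            removed["low_population"] += 1

    report = FilterReport(n_candidates=len(events), removed=removed,
                          retained=len(retained),
                          population_threshold=threshold)
    return retained, report


def events_to_frame(events: list[FireEvent], grid=None) -> pd.DataFrame:
    """Tabulate events (tab-separated friendly)."""
    rows = []
    for ev in events:
        row = {
            "lat_idx": ev.cell[0], "lon_idx": ev.cell[1],
            "year": ev.event_time[0], "month": ev.event_time[1],
            "ba_fraction": ev.ba_fraction,
        }
        if grid is not None:
            row["lat"] = grid.lat[ev.cell[0]]
            row["lon"] = grid.lon[ev.cell[1]]
        row.update({k: ev.filters_passed.get(k) for k in FILTER_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)
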