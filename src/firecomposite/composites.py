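"""Superposed-epoch (event-relative) lag matrices and composite statistics.

Anomaly series from many fire events are aligned on the event month (lag 0)
and summarised per lag by the median and interquartile range — the composite
isolates the systematic pre- and post-fire anomaly evolution from cell-level
noise. Composites can be taken per climate box at fixed lags, per
humid/arid regime over a full lag range, or over stratified event subsets
(burned-area size classes, population-density quartiles).

All quantiles here and elsewhere in the package use linear interpolation
between order statistics (numpy's default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate_classes import ClimateBox
from .event_sampling import FireEvent
from .fields import AnomalyField, month_number

__all__ = ["LagMatrix", "CompositeSeries", "event_lag_matrix",
           "composite_median", "box_composites_at_lag", "stratify"]


@dataclass
class LagMatrix:
    """Event × lag matrix of anomalies.

    Row ``e`` holds the anomaly series of event ``e`` shifted so that column
    ``lags == 0`` is the event month itself; entries falling outside the
    record (or masked in the source field) are NaN.
    """

    values: np.ndarray                  # (n_events, n_lags)
    lags: np.ndarray                    # ordered ints, lag 0 = event month
    events: list[FireEvent]

    def lag_column(self, lag: int) -> np.ndarray:
        pos = np.flatnonzero(self.lags == lag)
        if pos.size == 0:
            raise KeyError(f"lag {lag} not in matrix (lags {self.lags.tolist()})")
        return self.values[:, pos[0]]

    def row_of(self) -> dict[tuple[int, int], int]:
        """Map cell index -> row (one event per cell by construction)."""
        return {ev.cell: r for r, ev in enumerate(self.events)}


@dataclass
class CompositeSeries:
    """Per-lag median with interquartile bounds and contributing counts."""

    lags: np.ndarray
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag": self.lags, "median": self.median,
                             "q25": self.q25, "q75": self.q75, "n": self.n})


def event_lag_matrix(anomalies: AnomalyField, events: list[FireEvent],
                     lags=range(-12, 7)) -> LagMatrix:
    """Extract each event's anomaly at every requested lag.

    Entry (e, ℓ) is the anomaly ``ℓ`` calendar months after (negative:
    before) event e's month, in event e's cell; lags outside the record give
    NaN rather than dropping the event.
    """
    if not events:
        raise ValueError("empty event set")
    lags = np.asarray(list(lags), dtype=int)
    start_num = month_number(*anomalies.start)
    n_months = anomalies.n_months
    t0 = np.array([month_number(*ev.event_time) - start_num for ev in events])
    ii = np.array([ev.cell[0] for ev in events])
    jj = np.array([ev.cell[1] for ev in events])
    tt = t0[:, None] + lags[None, :]
    inside = (tt >= 0) & (tt < n_months)
    vals = np.full((len(events), lags.size), np.nan)
    vals[inside] = anomalies.z[tt[inside],
                               np.broadcast_to(ii[:, None], tt.shape)[inside],
                               np.broadcast_to(jj[:, None], tt.shape)[inside]]
    return LagMatrix(values=vals, lags=lags, events=list(events))


def composite_median(matrix: LagMatrix,
                     subset: np.ndarray | list[int] | None = None) -> CompositeSeries:
    """Median and interquartile range per lag over an event subset.

    ``subset`` selects rows (default: all events). Lags where every selected
    entry is missing yield NaN statistics with n = 0.
    """
    vals = matrix.values if subset is None else matrix.values[np.asarray(subset)]
    if vals.shape[0] == 0:
        raise ValueError("empty event subset")
    n = np.isfinite(vals).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(vals, axis=0)
        q25 = np.nanpercentile(vals, 25, axis=0)
        q75 = np.nanpercentile(vals, 75, axis=0)
    return CompositeSeries(lags=matrix.lags.copy(), median=med,
                           q25=q25, q75=q75, n=n)


def box_composites_at_lag(matrix: LagMatrix, boxes: list[ClimateBox],
                          lag: int) -> dict[str, float]:
    """Median anomaly at one lag for each retained (non-discarded) box."""
    row = matrix.row_of()
    out: dict[str, float] = {}
    for box in boxes:
        if box.discarded:
            continue
        rows = [row[c] for c in box.members if c in row]
        if not rows:
            continue
        col = matrix.lag_column(lag)[rows]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[box.label] = float(np.nanmedian(col))
    return out


def stratify(events: list[FireEvent], key,
             scheme: str | tuple = "quartiles") -> dict[str, np.ndarray]:
    """Split events into disjoint, exhaustive subsets by a per-event key.

    ``key`` is either an attribute name (``"ba_fraction"``) or an array of
    one value per event (e.g. population density at the event cell).
    ``scheme`` is ``"quartiles"`` (equal-count 0–25/25–50/50–75/75–100th
    percentile groups) or an explicit sequence of bin edges (half-open bins,
    last bin closed above). Returns label -> row-index array. A degenerate
    key (all values equal) collapses to a single group labelled
    ``"all (degenerate)"``.
    """
    if isinstance(key, str):
        x = np.array([getattr(ev, key) for ev in events], dtype=float)
    else:
        x = np.asarray(key, dtype=float)
        if x.size != len(events):
            raise ValueError("key array must have one value per event")
    if not np.isfinite(x).all():
        raise ValueError("stratification key undefined for some events")

    if isinstance(scheme, str) and scheme == "quartiles":
        if np.ptp(x) == 0:
            return {"all (degenerate)": np.arange(x.size)}
        edges = np.percentile(x, [0, 25, 50, 75, 100])
        labels = ["0-25%", "25-50%", "50-75%", "75-100%"]
    else:
        edges = np.asarray(scheme, dtype=float)
        labels = [f"[{edges[k]:g},{edges[k + 1]:g})"
                  for k in range(len(edges) - 1)]

    idx = np.searchsorted(edges, x, side="right") - 1
    idx = np.clip(idx, 0, len(edges) - 2)          # top edge closed
    out = {}
    for k, lab in enumerate(labels):
        rows = np.flatnonzero(idx == k)
        if rows.size:
            out[lab] = rows
    return out
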