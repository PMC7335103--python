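"""Resampling-based significance for composite anomalies.

The null model replaces every event's month by a randomly selected month in
the same season (within ±1 of the event's month-of-year, with December ↔
January wrap-around) but in a different calendar year, and recomputes the
identical composite statistic. Repeating this 1,000 times yields an
empirical 5th–95th percentile envelope per composite cell; an observed
composite median strictly outside that band is flagged significant (a
two-sided 90% level).

Randomness uses one master seed; each repetition draws from a substream
spawned deterministically from it, so bands are reproducible and the
repetitions could be evaluated in any order or in parallel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .event_sampling import FireEvent
from .fields import AnomalyField, month_number, month_tuple

__all__ = ["NullBand", "sample_null_month", "candidate_months",
           "null_band", "flag_significant"]


@dataclass
class NullBand:
    """Empirical per-cell percentile envelope of the null composite.

    ``lower``/``upper`` have shape (n_groups, n_lags); rows follow
    ``group_labels``, columns ``lags``.
    """

    lower: np.ndarray
    upper: np.ndarray
    group_labels: list[str]
    lags: np.ndarray
    n_boot: int
    percentile_pair: tuple[float, float] = (5.0, 95.0)


def candidate_months(event: FireEvent, period: tuple[int, int]) -> list[int]:
    """Admissible null months for one event, as serial month numbers.

    All calendar months inside ``period`` (inclusive years) whose
    month-of-year lies within ±1 of the event's (wrapping December↔January)
    and whose calendar year differs from the event year.
    """
    y0, y1 = period
    ev_year, ev_month = event.event_time
    moys = {(ev_month - 2) % 12 + 1, ev_month, ev_month % 12 + 1}
    out = []
    for y in range(y0, y1 + 1):
        if y == ev_year:
            continue
        for m in moys:
            out.append(month_number(y, m))
    return sorted(out)


def sample_null_month(event: FireEvent, period: tuple[int, int],
                      rng: np.random.Generator) -> tuple[int, int]:
    """Draw one admissible null (year, month), uniformly."""
    cands = candidate_months(event, period)
    if not cands:
        raise ValueError("no admissible null month (period too short)")
    return month_tuple(cands[rng.integers(len(cands))])


def _group_stat(values: np.ndarray, groups: dict[str, np.ndarray]) -> np.ndarray:
    """Median per group and lag; values shaped (..., n_events, n_lags)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.stack([np.nanmedian(values[..., rows, :], axis=-2)
                         for rows in groups.values()], axis=-2)


def null_band(anomalies: AnomalyField, events: list[FireEvent],
              groups: dict[str, np.ndarray], lags,
              n_boot: int = 1000,
              percentile_pair: tuple[float, float] = (5.0, 95.0),
              rng_seed: int = 0,
              period: tuple[int, int] | None = None) -> NullBand:
    """Empirical null envelope of the per-group composite median.

    For each of ``n_boot`` repetitions every event's month is independently
    replaced by a same-season different-year month, the per-group median at
    every lag is recomputed from the anomaly field, and the envelope is the
    per-cell (group × lag) pair of empirical percentiles across repetitions.

    ``groups`` maps a label to the row indices of its member events (e.g.
    climate-box membership or a regime split). ``period`` defaults to the
    anomaly field's full calendar span.
    """
    if not events:
        raise ValueError("empty event set")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100: percentile band estimates "
                      "will be unstable", stacklevel=2)
    lags = np.asarray(list(lags), dtype=int)
    if period is None:
        years = anomalies.years
        period = (int(years.min()), int(years.max()))

    start_num = month_number(*anomalies.start)
    n_months = anomalies.n_months
    n_events = len(events)
    cand = [np.asarray(candidate_months(ev, period)) - start_num
            for ev in events]
    cand = [c[(c >= 0) & (c < n_months)] for c in cand]
    if any(c.size == 0 for c in cand):
        raise ValueError("an event has no admissible null month inside the record")
    n_cand = np.array([c.size for c in cand])
    # pad the ragged candidate lists into one rectangle for vectorised lookup
    rect = np.zeros((n_events, n_cand.max()), dtype=int)
    for e, c in enumerate(cand):
        rect[e, :c.size] = c

    ii = np.array([ev.cell[0] for ev in events])
    jj = np.array([ev.cell[1] for ev in events])

    stats = np.empty((n_boot, len(groups), lags.size))
    master = np.random.SeedSequence(rng_seed)
    for b, child in enumerate(master.spawn(n_boot)):
        rng = np.random.default_rng(child)
        pick = (rng.random(n_events) * n_cand).astype(int)
        t0 = rect[np.arange(n_events), pick]
        tt = t0[:, None] + lags[None, :]
        inside = (tt >= 0) & (tt < n_months)
        vals = np.full((n_events, lags.size), np.nan)
        vals[inside] = anomalies.z[tt[inside],
                                   np.broadcast_to(ii[:, None], tt.shape)[inside],
                                   np.broadcast_to(jj[:, None], tt.shape)[inside]]
        stats[b] = _group_stat(vals, groups)

    lo_p, hi_p = percentile_pair
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lower = np.nanpercentile(stats, lo_p, axis=0)
        upper = np.nanpercentile(stats, hi_p, axis=0)
    all_nan = np.isnan(stats).all(axis=0)
    lower[all_nan] = np.nan
    upper[all_nan] = np.nan
    return NullBand(lower=lower, upper=upper,
                    group_labels=list(groups.keys()), lags=lags,
                    n_boot=n_boot, percentile_pair=(float(lo_p), float(hi_p)))


def flag_significant(observed: np.ndarray, band: NullBand) -> np.ndarray:
    """Boolean per composite cell: observed strictly outside the band.

    An observation exactly on a band edge is not significant; cells where
    either the observation or the band is undefined come back False-masked
    as NaN-safe ``False`` with a separate mask available via isnan checks.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != band.lower.shape:
        raise ValueError(f"observed shape {observed.shape} does not match "
                         f"band shape {band.lower.shape}")
    with np.errstate(invalid="ignore"):
        sig = (observed < band.lower) | (observed > band.upper)
    sig[~np.isfinite(observed) | ~np.isfinite(band.lower)
        | ~np.isfinite(band.upper)] = False
    return sig
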