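"""Aridity index, climate-box binning and the humid/arid regime split.

Aridity is the ratio of period-mean net radiation, expressed as equivalent
evaporation depth through the latent heat of vaporisation, to period-mean
precipitation. Cells with aridity above 2 are labelled arid, at or below 2
humid. For the climate-box composite, cells are grouped into half-open
(long-term temperature bin × aridity bin) boxes; boxes with too few members
are discarded from any composite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import MonthlyField, StaticField

__all__ = ["ClimateBox", "compute_aridity", "long_term_mean",
           "assign_boxes", "regime_labels",
           "DEFAULT_TEMP_EDGES", "DEFAULT_ARIDITY_EDGES", "ARIDITY_SPLIT",
           "LATENT_HEAT_VAPORISATION"]

#: latent heat of vaporisation, J/kg (typical value near 20 °C)
LATENT_HEAT_VAPORISATION = 2.45e6

#: humid/arid boundary of the aridity index
ARIDITY_SPLIT = 2.0

#: default long-term temperature bin edges, °C
DEFAULT_TEMP_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)

#: default aridity bin edges (log-spaced, keeping 2 as a mandatory edge)
DEFAULT_ARIDITY_EDGES = (0.5, 1.0, 2.0, 4.0, 8.0)


@dataclass
class ClimateBox:
    """One (temperature bin × aridity bin) group of grid cells.

    ``overflow`` marks edge bins that catch cells outside the configured
    ranges; ``discarded`` marks boxes below the minimum membership and is
    honoured by every composite.
    """

    temp_bin: tuple[float, float]
    aridity_bin: tuple[float, float]
    members: list = field(default_factory=list)
    discarded: bool = False
    overflow: bool = False

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        return (f"T[{self.temp_bin[0]:g},{self.temp_bin[1]:g})"
                f"xA[{self.aridity_bin[0]:g},{self.aridity_bin[1]:g})")


def long_term_mean(field_: MonthlyField,
                   period: tuple[int, int] | None = None) -> StaticField:
    """Per-cell mean over the study period, ignoring masked months."""
    years = field_.years
    if period is None:
        sel = np.ones(field_.n_months, dtype=bool)
    else:
        sel = (years >= period[0]) & (years <= period[1])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(field_.values[sel], axis=0)
    return StaticField(values=mean, grid=field_.grid, units=field_.units)


def compute_aridity(net_radiation: MonthlyField,
                    precipitation: MonthlyField,
                    period: tuple[int, int] | None = None,
                    latent_heat: float = LATENT_HEAT_VAPORISATION) -> StaticField:
    """Static aridity index per cell.

    Net radiation in W/m² is converted to equivalent evaporation in mm/day,
    E = Rn · 86400 / λ (λ in J/kg; the water-density and m→mm factors
    cancel), and aridity is the ratio of the period means::

        aridity = mean_t E / mean_t P

    Cells with non-positive mean precipitation or negative mean net
    radiation are masked.
    """
    if net_radiation.units and net_radiation.units not in ("W m-2", "W/m2", "W/m^2"):
        raise ValueError(f"net radiation units {net_radiation.units!r} "
                         "not recognised (expected W m-2)")
    if precipitation.units and precipitation.units not in ("mm day-1", "mm/day"):
        raise ValueError(f"precipitation units {precipitation.units!r} "
                         "not recognised (expected mm day-1)")
    rn_mean = long_term_mean(net_radiation, period).values
    p_mean = long_term_mean(precipitation, period).values
    evap = rn_mean * 86400.0 / latent_heat          # mm/day
    with np.errstate(divide="ignore", invalid="ignore"):
        aridity = np.where((p_mean > 0) & (evap >= 0), evap / p_mean, np.nan)
    return StaticField(values=aridity, grid=net_radiation.grid, units="1")


def regime_labels(aridity: StaticField,
                  split: float = ARIDITY_SPLIT) -> np.ndarray:
    """"humid" (aridity ≤ split) / "arid" (aridity > split) per cell."""
    labels = np.where(aridity.values > split, "arid", "humid")
    labels[aridity.mask] = ""
    return labels


def _bins_with_overflow(edges: np.ndarray) -> list[tuple[float, float]]:
    bins = [(-np.inf, edges[0])]
    bins += [(edges[k], edges[k + 1]) for k in range(len(edges) - 1)]
    bins.append((edges[-1], np.inf))
    return bins


def assign_boxes(temperature_mean: StaticField,
                 aridity: StaticField,
                 cells: list[tuple[int, int]],
                 temp_edges=DEFAULT_TEMP_EDGES,
                 aridity_edges=DEFAULT_ARIDITY_EDGES,
                 min_box_size: int = 25) -> list[ClimateBox]:
    """Assign cells to half-open temperature × aridity boxes.

    Cells outside the configured edges land in open-ended overflow bins at
    the margins, so each cell belongs to exactly one box. Boxes with fewer
    than ``min_box_size`` members are flagged ``discarded`` (and excluded
    from composites, mirroring how under-populated climate boxes are dropped
    from the box figure). Cells with undefined temperature or aridity raise.
    """
    t_edges = np.asarray(temp_edges, dtype=float)
    a_edges = np.asarray(aridity_edges, dtype=float)
    t_bins = _bins_with_overflow(t_edges)
    a_bins = _bins_with_overflow(a_edges)
    boxes = {(ti, ai): ClimateBox(
                temp_bin=t_bins[ti], aridity_bin=a_bins[ai],
                overflow=(ti in (0, len(t_bins) - 1)
                          or ai in (0, len(a_bins) - 1)))
             for ti in range(len(t_bins)) for ai in range(len(a_bins))}
    for cell in cells:
        t = temperature_mean.values[cell]
        a = aridity.values[cell]
        if not (np.isfinite(t) and np.isfinite(a)):
            raise ValueError(f"cell {cell} has undefined temperature or aridity")
        ti = int(np.searchsorted(t_edges, t, side="right"))
        ai = int(np.searchsorted(a_edges, a, side="right"))
        boxes[(ti, ai)].members.append(cell)
    out = [b for b in boxes.values() if b.n > 0]
    for b in out:
        b.discarded = b.n < min_box_size
    return out


def boxes_to_frame(boxes: list[ClimateBox]) -> pd.DataFrame:
    rows = [{"temp_lo": b.temp_bin[0], "temp_hi": b.temp_bin[1],
             "aridity_lo": b.aridity_bin[0], "aridity_hi": b.aridity_bin[1],
             "n": b.n, "discarded": b.discarded, "overflow": b.overflow}
            for b in boxes]
    return pd.DataFrame(rows)
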