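"""Self-contained synthetic scenes with the statistical structure the
fire-composite analysis assumes.

A scene bundles every input the pipeline consumes — daily surface soil
moisture and vegetation optical depth (VOD, a biomass proxy) with random
retrieval gaps, monthly 2 m temperature, precipitation and net radiation,
a monthly burned-area field with one dominant fire per designated cell plus
its observed-area fraction, and static population-density and land-area
layers — together with a truth record of where events and signals were
injected, so every downstream stage can be tested without downloading any
satellite product.

Construction, per cell:

* soil moisture = baseline + sinusoidal seasonal cycle + AR(1) monthly
  anomalies (lag-1 coefficient 0.5) + white daily noise, clipped to [0, 1],
  with independent Bernoulli daily gaps;
* climate regime is set by drawing a target aridity either below (humid) or
  above (arid) the conventional threshold of 2, and generating net radiation
  so that equivalent evaporation over precipitation reproduces that target;
* each fire cell receives a heavy-tailed burned-area maximum at a random
  month, strictly above every other month of that cell;
* optionally, a fire-preceding soil-moisture signal (a z-score profile over
  the lags ending at the event month) is written into the event cells in
  z-space and mapped back through the cell's own climatology, so a correct
  z-score implementation recovers the profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import (
    DailyField,
    Grid,
    MonthlyField,
    StaticField,
    month_number,
    month_tuple,
    write_field,
    read_field,
)
from .preprocess import daily_to_monthly, monthly_climatology

__all__ = ["SceneConfig", "TruthRecord", "Scene", "generate_scene",
           "write_scene", "read_scene"]

#: latent heat of vaporisation used throughout, J/kg
LATENT_HEAT = 2.45e6

#: convert net radiation in W/m^2 to equivalent evaporation in mm/day
RN_TO_MM_DAY = 86400.0 / LATENT_HEAT


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene.

    Defaults describe a 20×20-cell 0.25° region over the 2001–2018 study
    period with 300 fire cells and no injected fire-preceding signal (a null
    scene). ``signal_profile`` holds z-score values at consecutive lags
    ending at the event month (the last entry is lag 0).
    """

    grid_shape: tuple[int, int] = (20, 20)
    cell_size_deg: float = 0.25
    period: tuple[int, int] = (2001, 2018)
    sm_seasonal_amp: float = 0.08       # volumetric fraction
    sm_noise_sd: float = 0.04           # stationary sd of monthly anomalies
    sm_daily_noise_sd: float = 0.01
    daily_gap_prob: float = 0.1
    obs_fraction: float | None = None   # default: 1 - daily_gap_prob
    n_fire_cells: int = 300
    signal_profile: tuple[float, ...] = ()
    signal_mode: str = "replace"        # "replace" or "add" in z-space
    humid_fraction: float = 0.5
    pop_lognormal_params: tuple[float, float] = (1.0, 1.5)
    rng_seed: int = 0
    # secondary knobs (climate and biomass structure)
    temp_base_range: tuple[float, float] = (10.0, 20.0)   # °C long-term means
    temp_seasonal_amp: float = 5.0
    temp_noise_sd: float = 0.8
    cold_fraction: float = 0.0          # cells with long-term mean < 0 °C
    vod_base_range: tuple[float, float] = (0.3, 0.9)
    vod_seasonal_amp: float = 0.1
    vod_noise_sd: float = 0.05
    ar1_coef: float = 0.5

    def validate(self) -> None:
        y0, y1 = self.period
        if y1 - y0 + 1 < 2:
            raise ValueError("period must span at least 2 calendar years "
                             "(climatology needs >= 2 samples per month-of-year)")
        if not 0.0 <= self.daily_gap_prob < 1.0:
            raise ValueError("daily_gap_prob must lie in [0, 1)")
        if len(self.signal_profile) > 12:
            raise ValueError("signal_profile may cover at most 12 lags")
        n_cells = self.grid_shape[0] * self.grid_shape[1]
        if self.n_fire_cells > n_cells:
            raise ValueError(f"n_fire_cells={self.n_fire_cells} exceeds the "
                             f"{n_cells}-cell grid")
        if self.n_fire_cells < 0:
            raise ValueError("n_fire_cells must be non-negative")
        n_months = 12 * (y1 - y0 + 1)
        lo = max(5, len(self.signal_profile) - 1)
        if lo > n_months - 2:
            raise ValueError("signal injection window does not fit inside the period")
        if self.obs_fraction is not None and not 0.0 <= self.obs_fraction <= 1.0:
            raise ValueError("obs_fraction must lie in [0, 1]")
        if self.signal_mode not in ("replace", "add"):
            raise ValueError("signal_mode must be 'replace' or 'add'")
        if not 0.0 <= self.humid_fraction <= 1.0:
            raise ValueError("humid_fraction must lie in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth of a generated scene.

    ``event_cells`` are (lat_idx, lon_idx) pairs, one per fire cell;
    ``event_months`` the matching (year, month) of each injected maximum;
    ``regime_labels`` the humid/arid label of every grid cell.
    """

    event_cells: list[tuple[int, int]]
    event_months: list[tuple[int, int]]
    injected_profile: tuple[float, ...]
    regime_labels: np.ndarray           # (n_lat, n_lon) of "humid"/"arid"
    event_ba_fraction: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class Scene:
    """All inputs of one synthetic (or real-format) analysis run."""

    soil_moisture: DailyField
    vod: DailyField
    temperature: MonthlyField
    precipitation: MonthlyField
    net_radiation: MonthlyField
    burned_area: MonthlyField           # km^2 per month
    observed_fraction: MonthlyField
    population: StaticField             # people/km^2
    land_area: StaticField              # km^2
    truth: TruthRecord | None = None
    config: SceneConfig | None = None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _seasonal_daily(times: pd.DatetimeIndex, phase: np.ndarray) -> np.ndarray:
    """Unit-amplitude annual cycle per day (rows) and cell (columns)."""
    doy = times.dayofyear.values / 365.25
    return np.sin(2 * np.pi * doy[:, None] + phase[None, :])


def _ar1_monthly(rng: np.random.Generator, n_months: int, n_cells: int,
                 phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) anomalies, shape (n_months, n_cells)."""
    innov_sd = sd * np.sqrt(1.0 - phi ** 2)
    out = np.empty((n_months, n_cells))
    out[0] = rng.normal(0.0, sd, n_cells)
    shocks = rng.normal(0.0, innov_sd, (n_months - 1, n_cells))
    for t in range(1, n_months):
        out[t] = phi * out[t - 1] + shocks[t - 1]
    return out


def _daily_variable(rng: np.random.Generator, times: pd.DatetimeIndex,
                    day_month: np.ndarray, n_cells: int, base: np.ndarray,
                    amp: float, monthly_sd: float, daily_sd: float,
                    phi: float, lo: float, hi: float) -> np.ndarray:
    phase = rng.uniform(0.0, 2 * np.pi, n_cells)
    monthly = _ar1_monthly(rng, day_month.max() + 1, n_cells, phi, monthly_sd)
    vals = (base[None, :]
            + amp * _seasonal_daily(times, phase)
            + monthly[day_month]
            + rng.normal(0.0, daily_sd, (times.size, n_cells)))
    return np.clip(vals, lo, hi)


def _inject_signal(sm: np.ndarray, valid: np.ndarray, day_month: np.ndarray,
                   cells_flat: np.ndarray, event_idx: np.ndarray,
                   profile: np.ndarray, mode: str, n_iter: int = 4) -> None:
    """Write the z-profile into the event cells' monthly means, in place.

    The target anomaly for lag ``l`` is ``profile[l]`` (replace mode) or the
    cell's pre-injection anomaly plus ``profile[l]`` (add mode). Because the
    injected months themselves enter the month-of-year climatology, the
    mapping back to absolute values is solved by fixed-point iteration: each
    pass recomputes the climatology and shifts all valid daily values of the
    target month by a constant. The per-pass correction shrinks by ~1/n_years,
    so a few passes reach numerical exactness for practical purposes.
    """
    L = profile.size
    lags = np.arange(-L + 1, 1)
    months = event_idx[:, None] + lags[None, :]        # (n_events, L)

    def monthly_stats():
        monthly = daily_to_monthly_from_daymonth(
            np.where(valid, sm, np.nan), day_month, min_days=1)
        return monthly, _clim_from_monthly(monthly)

    monthly0, clim0 = monthly_stats()
    moy = months % 12
    base_z = np.zeros((event_idx.size, L))
    if mode == "add":
        m0 = monthly0[months, cells_flat[:, None]]
        base_z = ((m0 - clim0[0][moy, cells_flat[:, None]])
                  / clim0[1][moy, cells_flat[:, None]])
    target_z = base_z + profile[None, :]

    for _ in range(n_iter):
        monthly, (mean, sd) = monthly_stats()
        cur = monthly[months, cells_flat[:, None]]
        want = (mean[moy, cells_flat[:, None]]
                + target_z * sd[moy, cells_flat[:, None]])
        delta = want - cur                              # (n_events, L)
        # spread each month's constant shift over that month's valid days
        for e in range(event_idx.size):
            c = cells_flat[e]
            for j in range(L):
                if not np.isfinite(delta[e, j]):
                    continue
                sel = (day_month == months[e, j]) & valid[:, c]
                sm[sel, c] += delta[e, j]


def daily_to_monthly_from_daymonth(values_3d: np.ndarray, day_month: np.ndarray,
                                   min_days: int) -> np.ndarray:
    """Monthly valid-day means, flattened cells; NaN below ``min_days``."""
    flat = values_3d.reshape(values_3d.shape[0], -1)
    ok = np.isfinite(flat)
    starts = np.flatnonzero(np.r_[True, np.diff(day_month) != 0])
    sums = np.add.reduceat(np.where(ok, flat, 0.0), starts, axis=0)
    cnts = np.add.reduceat(ok.astype(np.int64), starts, axis=0)
    with np.errstate(invalid="ignore"):
        return np.where(cnts >= min_days, sums / np.maximum(cnts, 1), np.nan)


def _clim_from_monthly(monthly: np.ndarray):
    """Month-of-year mean and n−1 sd per flattened cell."""
    mean = np.empty((12, monthly.shape[1]))
    sd = np.empty_like(mean)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for m in range(12):
            sample = monthly[m::12]
            mean[m] = np.nanmean(sample, axis=0)
            sd[m] = np.nanstd(sample, axis=0, ddof=1)
    return mean, sd


def generate_scene(config: SceneConfig) -> Scene:
    """Generate a full synthetic scene from a validated configuration.

    Returns a :class:`Scene` whose gridded members share one grid and
    calendar, plus the :class:`TruthRecord` of injected events. Fixing
    ``rng_seed`` makes every output bit-reproducible.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_lat, n_lon = config.grid_shape
    n_cells = n_lat * n_lon
    grid = Grid.regular(n_lat, n_lon, config.cell_size_deg)
    y0, y1 = config.period
    n_years = y1 - y0 + 1
    n_months = 12 * n_years
    times = pd.date_range(f"{y0}-01-01", f"{y1}-12-31", freq="D")
    day_month = (times.year.values - y0) * 12 + times.month.values - 1

    # --- climate regime per cell -------------------------------------------
    humid = rng.random(n_cells) < config.humid_fraction
    aridity_target = np.where(humid,
                              rng.uniform(0.8, 1.8, n_cells),
                              rng.uniform(2.3, 6.0, n_cells))
    regime = np.where(humid, "humid", "arid").reshape(n_lat, n_lon)

    # --- soil moisture and biomass proxy (daily, gappy) --------------------
    sm_base = rng.uniform(0.15, 0.35, n_cells)
    sm = _daily_variable(rng, times, day_month, n_cells, sm_base,
                         config.sm_seasonal_amp, config.sm_noise_sd,
                         config.sm_daily_noise_sd, config.ar1_coef, 0.0, 1.0)
    vod_base = rng.uniform(*config.vod_base_range, n_cells)
    vod = _daily_variable(rng, times, day_month, n_cells, vod_base,
                          config.vod_seasonal_amp, config.vod_noise_sd,
                          config.vod_noise_sd / 4, config.ar1_coef, 0.0, 3.0)
    gaps = rng.random((times.size, n_cells)) < config.daily_gap_prob
    vod_gaps = rng.random((times.size, n_cells)) < config.daily_gap_prob

    # --- monthly meteorology ----------------------------------------------
    moy_axis = np.arange(n_months) % 12
    t_base = rng.uniform(*config.temp_base_range, n_cells)
    n_cold = int(round(config.cold_fraction * n_cells))
    if n_cold:
        cold_cells = rng.choice(n_cells, n_cold, replace=False)
        t_base[cold_cells] = rng.uniform(-10.0, -2.0, n_cold)
    t_phase = rng.uniform(0.0, 2 * np.pi, n_cells)
    seasonal = np.sin(2 * np.pi * moy_axis[:, None] / 12 + t_phase[None, :])
    temperature = (t_base[None, :] + config.temp_seasonal_amp * seasonal
                   + rng.normal(0.0, config.temp_noise_sd, (n_months, n_cells)))

    p_base = np.where(humid, rng.uniform(3.0, 6.0, n_cells),
                      rng.uniform(0.5, 2.0, n_cells))
    p_seas = 1.0 + 0.3 * np.sin(2 * np.pi * moy_axis[:, None] / 12
                                + rng.uniform(0, 2 * np.pi, n_cells)[None, :])
    precip = np.clip(p_base[None, :] * p_seas
                     + rng.normal(0.0, 0.05, (n_months, n_cells))
                     * p_base[None, :], 0.01, None)
    e_base = aridity_target * precip.mean(axis=0)      # mm/day equivalent
    rn_equiv = e_base[None, :] * (1.0 + 0.2 * seasonal)
    net_radiation = rn_equiv / RN_TO_MM_DAY            # back to W/m^2

    # --- population and land area ------------------------------------------
    mu, sigma = config.pop_lognormal_params
    population = rng.lognormal(mu, sigma, n_cells)
    land_area = grid.cell_area_km2()

    # --- fire events --------------------------------------------------------
    profile = np.asarray(config.signal_profile, dtype=float)
    lo = max(5, profile.size - 1)
    fire_cells = np.sort(rng.choice(n_cells, config.n_fire_cells, replace=False))
    event_idx = rng.integers(lo, n_months - 1, config.n_fire_cells)

    burned = np.zeros((n_months, n_cells))
    area_flat = land_area.ravel()
    # heavy-tailed maximum burned fraction per event cell
    event_frac = np.clip(np.exp(rng.normal(np.log(0.02), 1.0,
                                           config.n_fire_cells)), 1e-4, 0.9)
    # background burns strictly below the injected maximum
    bg_months = rng.random((n_months, config.n_fire_cells)) < 0.2
    bg = bg_months * rng.uniform(0.0, 0.5, (n_months, config.n_fire_cells))
    burned[:, fire_cells] = bg * (event_frac * area_flat[fire_cells])[None, :]
    burned[event_idx, fire_cells] = event_frac * area_flat[fire_cells]

    obs_level = (1.0 - config.daily_gap_prob if config.obs_fraction is None
                 else config.obs_fraction)
    observed = np.full((n_months, n_cells), obs_level)

    # --- signal injection ---------------------------------------------------
    if profile.size and config.n_fire_cells:
        _inject_signal(sm, ~gaps, day_month, fire_cells,
                       event_idx, profile, config.signal_mode)

    def as_daily(arr, gap, units):
        vals = np.where(gap, np.nan, arr).reshape(times.size, n_lat, n_lon)
        return DailyField(values=vals, grid=grid, start=f"{y0}-01-01", units=units)

    def as_monthly(arr, units):
        return MonthlyField(values=arr.reshape(n_months, n_lat, n_lon),
                            grid=grid, start=(y0, 1), units=units)

    truth = TruthRecord(
        event_cells=[divmod(int(c), n_lon) for c in fire_cells],
        event_months=[month_tuple(month_number(y0, 1) + int(t))
                      for t in event_idx],
        injected_profile=tuple(profile.tolist()),
        regime_labels=regime,
        event_ba_fraction=event_frac,
    )
    return Scene(
        soil_moisture=as_daily(sm, gaps, "m3 m-3"),
        vod=as_daily(vod, vod_gaps, "1"),
        temperature=as_monthly(temperature, "degC"),
        precipitation=as_monthly(precip, "mm day-1"),
        net_radiation=as_monthly(net_radiation, "W m-2"),
        burned_area=as_monthly(burned, "km2"),
        observed_fraction=as_monthly(observed, "1"),
        population=StaticField(values=population.reshape(n_lat, n_lon),
                               grid=grid, units="km-2"),
        land_area=StaticField(values=land_area, grid=grid, units="km2"),
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_FILES = {
    "soil_moisture.nc": [("soil_moisture", "soil_moisture", "daily")],
    "vod.nc": [("vod", "vod", "daily")],
    "temperature.nc": [("temperature", "temperature", "monthly")],
    "precipitation.nc": [("precipitation", "precipitation", "monthly")],
    "net_radiation.nc": [("net_radiation", "net_radiation", "monthly")],
    "fire.nc": [("burned_area", "burned_area", "monthly"),
                ("observed_fraction", "observed_fraction", "monthly")],
    "population.nc": [("population", "population", "static")],
    "land_area.nc": [("land_area", "land_area", "static")],
}


def write_scene(scene: Scene, directory: str | Path) -> list[Path]:
    """Write a scene as one NetCDF file per variable plus a truth table.

    Returns the manifest: eight variable files (burned area and its
    observed fraction share ``fire.nc``) and ``truth.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for fname, entries in _FILES.items():
        bundle = {var: getattr(scene, attr) for attr, var, _ in entries}
        manifest.append(write_field(bundle, directory / fname))

    truth_path = directory / "truth.tsv"
    if scene.truth is not None:
        t = scene.truth
        df = pd.DataFrame({
            "lat_idx": [c[0] for c in t.event_cells],
            "lon_idx": [c[1] for c in t.event_cells],
            "year": [m[0] for m in t.event_months],
            "month": [m[1] for m in t.event_months],
            "ba_fraction": t.event_ba_fraction,
            "regime": [t.regime_labels[c] for c in t.event_cells],
        })
        with open(truth_path, "w") as fh:
            fh.write("# signal_profile\t" +
                     ",".join(f"{v:.6g}" for v in t.injected_profile) + "\n")
            fh.write("# regimes\t" +
                     ",".join(t.regime_labels.ravel().tolist()) + "\n")
            df.to_csv(fh, sep="\t", index=False)
        manifest.append(truth_path)
    return manifest


def read_scene(directory: str | Path) -> Scene:
    """Read back a scene written by :func:`write_scene`."""
    directory = Path(directory)
    loaded: dict[str, object] = {}
    for fname, entries in _FILES.items():
        for attr, var, kind in entries:
            loaded[attr] = read_field(directory / fname, var, kind)

    truth = None
    truth_path = directory / "truth.tsv"
    if truth_path.exists():
        with open(truth_path) as fh:
            profile_line = fh.readline().rstrip("\n").split("\t", 1)[1]
            regime_line = fh.readline().rstrip("\n").split("\t", 1)[1]
            df = pd.read_csv(fh, sep="\t")
        shape = loaded["population"].values.shape
        profile = tuple(float(v) for v in profile_line.split(",")) \
            if profile_line else ()
        truth = TruthRecord(
            event_cells=list(zip(df["lat_idx"].astype(int),
                                 df["lon_idx"].astype(int))),
            event_months=list(zip(df["year"].astype(int),
                                  df["month"].astype(int))),
            injected_profile=profile,
            regime_labels=np.array(regime_line.split(",")).reshape(shape),
            event_ba_fraction=df["ba_fraction"].to_numpy(),
        )
    return Scene(truth=truth, config=None, **loaded)
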