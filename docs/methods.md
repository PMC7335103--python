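# Methods

`firecomposite` implements a superposed-epoch (composite) analysis of
gridded soil-moisture, temperature and biomass-proxy anomalies around the
largest local wildfire on record in each grid cell, together with a
Monte-Carlo resampling test of the composites' significance. This note
documents the model assumptions, the tunable parameters, the synthetic-data
generator used to exercise the chain, and the numerical conventions.

## The analysis

**Event sampling.** The unit of analysis is the grid cell. From a monthly
burned-area record, each cell contributes the single month with the highest
burned area — restricted to months whose observed-area fraction is strictly
above `min_obs_fraction` (default 0.8), since burned-area retrievals over
poorly observed cells are unreliable. Ties on the maximum go to the earliest
month (a deterministic, documented convention; burned-area values are
continuous, so ties are measure-zero in practice). Cells whose admissible
months all have zero burned area contribute no event.

Candidate events then pass a three-stage filter cascade:

1. *window completeness* — every monthly soil-moisture anomaly from 5 months
   before to 1 month after the event must be present (`sm_window`,
   default (−5, +1)); windows reaching outside the record fail this filter
   rather than raising;
2. *temperature* — the cell's long-term mean 2 m temperature must be at
   least `temp_min` (default 0 °C), removing cells where freezing degrades
   microwave soil-moisture retrievals;
3. *population* — the cell's population density must be strictly below the
   `pop_percentile`-th percentile (default 25) of density over **all** cells
   with soil-moisture data, not only event cells, confining the analysis to
   sparsely populated areas where fire suppression and infrastructure do not
   mask natural soil-moisture–fire coupling.

Survival is the conjunction of the filters and hence order-independent; the
run report attributes each removal to its first failing filter in the fixed
order obs-fraction → window → temperature → population, so the per-stage
counts always sum to the candidate count.

**Anomalies.** All variables are averaged to calendar months (daily inputs
need `min_days` = 15 valid days per month), brought to a common grid
(mask-aware cell-average for continuous fields; nearest-neighbour when
refining the coarse population layer), and converted to z-scores: the value
minus its month-of-year mean, divided by the month-of-year standard
deviation over the reference period. The standard deviation uses the sample
(n − 1) denominator — the choice is conventional, and with an 18-year
reference the alternative differs by ~3%. Month-of-year cells with fewer
than two valid years or (numerically) zero spread are masked rather than
producing infinities. The event month itself is *not* excluded from the
climatology, which introduces a mild self-influence of order 1/n_years; the
alternative (leave-one-out climatologies) would decouple the null resamples
from the observed statistic and is not used.

**Climate classification.** Aridity is period-mean net radiation, converted
to equivalent evaporation depth, over period-mean precipitation:
E [mm/day] = Rn [W/m²] · 86400 / λ with λ = 2.45 × 10⁶ J/kg (a fixed,
configurable constant typical of ~20 °C; the water density and m→mm factors
cancel). Aridity > 2 defines the arid regime, ≤ 2 humid. For the box
composite, event cells are grouped into half-open long-term-temperature ×
aridity bins (defaults: 0–30 °C in 5 °C steps; aridity edges 0.5, 1, 2, 4, 8
with the humid/arid boundary kept as a mandatory edge; cells outside the
ranges land in flagged overflow bins so membership counts are conserved).
Boxes with fewer than `min_box_size` = 25 cells are discarded from every
composite.

**Composites.** Anomaly series are aligned on the event month (lag 0) into
an event × lag matrix; lags outside the record contribute missing entries
rather than dropping the event from other lags. Composites report the
median and interquartile range per lag (lags −12…+6 for evolutions; −5 and
−1 as the headline fixed lags). Stratified variants split events by maximum
burned-area fraction (quartiles by default; explicit edges supported) and by
population density; the population stratification uses the
pre-population-filter event set, so all cells with soil-moisture data
participate, and is restricted to arid cells. Every quantile in the package
— medians, IQRs, the population threshold, quartile edges — uses linear
interpolation between order statistics (numpy's default), stated once here
and applied uniformly.

**Significance.** For each of `n_boot` = 1,000 repetitions, every event's
month is independently replaced by a month drawn uniformly from the same
season (month-of-year within ±1, wrapping December↔January across calendar
years) in a *different* year inside the study period, and the identical
composite statistic is recomputed. The per-cell empirical 5th–95th
percentile envelope across repetitions forms the null band; an observed
median strictly outside the band is significant at the two-sided 90% level.
Draws are uniform over all admissible (year, month) pairs; months whose
burned area is nonzero are *not* excluded (the different-year rule is the
only explicit exclusion; an optional burned-area exclusion would be a
straightforward extension but changes the null's interpretation). Bands are
computed per (box, lag) cell independently; no multiple-testing correction
is applied across boxes — deliberately, so the nominal per-cell level is
interpretable, and noted here rather than silently added. Randomness uses
one master seed with per-repetition substreams spawned deterministically
(`numpy` `SeedSequence`), so results are reproducible and repetitions are
order-independent.

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes, not
any particular satellite product:

- **Soil moisture / VOD (daily):** per-cell baseline (uniform 0.15–0.35
  volumetric for soil moisture) + sinusoidal seasonal cycle (amplitude
  `sm_seasonal_amp` = 0.08) + AR(1) monthly anomalies (lag-1 coefficient
  0.5, stationary sd `sm_noise_sd` = 0.04) + white daily noise (sd 0.01),
  clipped to [0, 1]. Daily gaps are independent Bernoulli
  (`daily_gap_prob` = 0.1) per day and cell; clustered orbit-geometry gaps
  are deliberately not modelled.
- **Climate regime by construction:** each cell draws a target aridity
  either in (0.8, 1.8) (humid, probability `humid_fraction`) or (2.3, 6.0)
  (arid), and net radiation is generated so that the computed aridity
  reproduces the target — the humid/arid threshold of 2 is straddled with a
  buffer, so regime truth labels are unambiguous. Long-term mean
  temperatures are drawn from 10–20 °C (a warm band keeping the default
  temperature-bin occupancy high); a configurable `cold_fraction` of cells
  gets sub-zero means to exercise the temperature filter.
- **Fires:** `n_fire_cells` cells receive one event month (uniform over the
  admissible interior of the period) whose burned-area fraction is
  heavy-tailed lognormal (median 2% of the cell, σ = 1 in log space) and
  strictly exceeds every other month of that cell; other months carry
  sub-maximal background burns. The observed-area fraction is simulated as
  the constant 1 − `daily_gap_prob` per month, with an independent
  `obs_fraction` override for tests that need gappy soil moisture under a
  passing observed-area fraction.
- **Population:** iid lognormal (`pop_lognormal_params` = (1.0, 1.5)),
  heavy-tailed like real density fields, independent of fire placement.
- **Signal injection:** an optional z-score profile over the lags ending at
  the event month is written into each fire cell in z-space and mapped back
  through the cell's own month-of-year climatology. Because injected months
  themselves shift that climatology, the mapping is solved by fixed-point
  iteration (4 passes; the correction contracts by ~1/n_years per pass), so
  a correct z-score implementation recovers the profile essentially
  exactly. The default mode *replaces* the month's anomaly with the profile
  value, which makes recovery deterministic; an additive mode
  (`signal_mode="add"`) shifts the cell's own anomaly instead and leaves
  the generator's O(1) per-cell noise in the composite.
- **Default scene:** 20×20 cells of 0.25°, calendar years 2001–2018
  (18 years, matching the reference-period length the climatology assumes),
  300 fire cells — the largest round number of fire cells that leaves
  head-room on a 400-cell grid.

What passing tests on these scenes do **not** show: robustness to spatially
correlated noise, to clustered retrieval gaps, to trends or regime shifts in
the climatology, or to the heterogeneous quality of merged multi-sensor
products. The generator is deliberately stationary and spatially
independent, so test outcomes isolate the correctness of the statistical
machinery rather than its robustness to real-data pathology.

## Study conditions of the calibration and recovery experiments

- *Null calibration* (`null_coverage_experiment`, also run by
  `scripts/acceptance.py`): 20 seeded repetitions of a null scene on a
  40×40 grid with 1000 fire cells. The larger grid is needed because the
  25th-percentile population filter by construction retains about a quarter
  of randomly placed events; 1000 candidates leave ≈250 retained events,
  enough for several retained climate boxes per repetition. Coverage is
  pooled over boxes × headline lags × repetitions and compared with the
  nominal 90% within 3 binomial standard errors.
- *Signal recovery:* the reference profile (+0.5, +0.3, 0, −0.3, −0.5,
  −0.6) at lags −5…0 is injected into 500 fire cells of an all-arid 30×30
  scene, with the population filter disabled (`pop_percentile` = 100) —
  the experiment probes compositing and significance, not the filter
  cascade, and disabling the filter keeps all 500 injected events in the
  composite. Headline lags (−5, 0) are flagged against the 1,000-resample
  band in each of 10 seeded reruns.

## Numerical conventions and degenerate inputs

- Missing data are NaN plus a boolean mask; every reduction is mask-aware.
- A month-of-year sd is "zero" (and masked) when sd ≤ 1e-12 · max(|mean|, 1),
  so constant series are degenerate despite rounding residue.
- An observation exactly on a null-band edge is **not** significant.
- Empty target cells under cell-average regridding are masked, not errors;
  cell-average refuses refinement (use nearest).
- Degenerate stratification keys (all equal) collapse to a single labelled
  group instead of erroring.
- Configuration validation collects *all* violations before raising.

## Known limitations

- One event per cell: repeated large fires in a cell are not analysed.
- The aridity conversion uses a fixed λ; a temperature-dependent latent heat
  would change aridity by a few percent at climate extremes.
- The null band treats events as independent; spatially clustered events in
  real data would make the band anti-conservative.
- No multiple-testing correction across climate boxes (by design, see
  above).
- NetCDF I/O uses the NetCDF3 (64-bit offset) format via the scipy backend;
  NetCDF4/HDF5-specific features (groups, compression) are not supported.
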