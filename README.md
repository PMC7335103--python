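# firecomposite

Superposed-epoch analysis of soil-moisture and biomass anomalies preceding
the largest local wildfires, with a Monte-Carlo resampling significance
test.

## The problem

Surface soil moisture shapes wildfire hazard through two competing
pathways: wet soils grow the biomass that later fuels fires, while dry
soils cure that biomass into flammable fuel and create ignition-friendly
conditions. Satellite records — microwave surface soil moisture, burned
area, and vegetation optical depth (VOD, a proxy for above-ground biomass)
— make it possible to ask, globally and per climate regime, what the
*typical* soil-moisture anomaly looks like in the months before a cell's
largest fire on record.

`firecomposite` is a reusable pipeline for that question, aimed at
ecohydrologists and fire scientists working with gridded monthly/daily
satellite products. Its stages:

1. **Event sampling** — per 0.25° grid cell, the month with the maximum
   burned area, using only months with observed-area fraction > 80%;
2. **Filter cascade** — events must have complete soil-moisture anomalies
   from 5 months before to 1 month after the fire, a long-term mean
   temperature ≥ 0 °C, and population density below the 25th percentile of
   all cells with soil-moisture data (near-natural areas only);
3. **z-score anomalies** — every variable becomes
   z(t) = (x(t) − μ_moy) / σ_moy, with month-of-year climatology μ, σ over
   the reference period (sample sd, n−1);
4. **Climate classification** — aridity = mean Rn-equivalent evaporation /
   mean precipitation (E [mm/day] = Rn [W/m²]·86400/λ, λ = 2.45 MJ/kg);
   aridity > 2 is arid, ≤ 2 humid; events are grouped into temperature ×
   aridity boxes (boxes with < 25 cells discarded);
5. **Composites** — median and interquartile range of anomalies per
   event-relative lag (lag 0 = fire month), per box at the headline lags −5
   and −1, per regime over lags −12…+6, and stratified by fire size or
   population density;
6. **Significance** — each event month is replaced by a random same-season
   (month-of-year ± 1, December↔January wrapping) different-year month and
   the composite recomputed; 1,000 repetitions give an empirical 5th–95th
   percentile null band, and observed medians outside it are significant at
   the two-sided 90% level.

Because the real satellite archives are terabyte-scale, the package ships a
synthetic-scene generator that emulates their statistical structure
(seasonal cycles, AR(1) interannual noise, daily retrieval gaps, one
dominant burn per fire cell, heavy-tailed population density, and an
optionally injected fire-preceding z-score profile with a truth record), so
the entire chain is testable end to end. See `docs/methods.md` for the full
model description and conventions.

## Worked example

Inject the reference fire-preceding profile (+0.5 z at lag −5 falling to
−0.6 at lag 0) into 500 arid cells and run the pipeline:

```python
from firecomposite import PipelineConfig, SceneConfig, run_pipeline

profile = (0.5, 0.3, 0.0, -0.3, -0.5, -0.6)
scene = SceneConfig(grid_shape=(30, 30), n_fire_cells=500, humid_fraction=0.0,
                    signal_profile=profile, rng_seed=11)
result = run_pipeline(PipelineConfig(scene=scene, pop_percentile=100.0,
                                     rng_seed=11))
print(result.report.to_text())
print(result.box_table[["box", "lag", "median", "lower", "upper",
                        "significant"]].to_string(index=False))
```

which prints

```
pipeline run report
  version:              0.1.0
  grid cells:           900
  soil-moisture cells:  900
  candidate events:     500
  removed (sm_window_complete): 0
  removed (warm_enough): 0
  removed (low_population): 1
  retained events:      499
  population threshold: 229.8 /km2
  climate boxes:        6 (4 retained)
  composite cells:      8 (8 significant)
  wall time:            9.5 s

            box  lag    median     lower    upper  significant
T[10,15)xA[2,4)   -5  0.499991 -0.244941 0.206156         True
T[10,15)xA[2,4)   -1 -0.499987 -0.188184 0.265938         True
T[10,15)xA[4,8)   -5  0.499990 -0.198274 0.174294         True
T[10,15)xA[4,8)   -1 -0.499985 -0.159004 0.221775         True
T[15,20)xA[2,4)   -5  0.499988 -0.210160 0.178916         True
T[15,20)xA[2,4)   -1 -0.499989 -0.172781 0.210042         True
T[15,20)xA[4,8)   -5  0.499988 -0.177986 0.152448         True
T[15,20)xA[4,8)   -1 -0.499992 -0.143624 0.210242         True
```

Reading the table: in every retained climate box the composite median
soil-moisture anomaly at lag −5 is +0.50 z (the injected wet phase,
recovered to ~1e-5) and at lag −1 is −0.50 z (the drying phase); both lie
far outside the resampling null band (`lower`, `upper`), so all 8 composite
cells are flagged significant. One event was lost to the population filter
(its density equalled the 100th-percentile threshold, and the comparison is
strict).

A shell interface mirrors the library:
`firecomposite simulate|run|composite|signif` (see `--help`).

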