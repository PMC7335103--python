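"""Largest-event selection, filter cascade, and the population threshold."""

import numpy as np
import pytest

from firecomposite import (
    AnomalyField,
    Grid,
    MonthlyField,
    StaticField,
    daily_to_monthly,
    filter_events,
    monthly_climatology,
    normalize_anomaly,
    population_threshold,
    select_largest_events,
)
from firecomposite.event_sampling import FILTER_ORDER
from firecomposite.fields import month_number

GRID1 = Grid.regular(1, 1, 0.25)


def fire_cell(burns, obs, start=(2001, 1)):
    ba = MonthlyField(values=np.asarray(burns, float)[:, None, None],
                      grid=GRID1, start=start)
    of = MonthlyField(values=np.asarray(obs, float)[:, None, None],
                      grid=GRID1, start=start)
    land = StaticField(values=np.array([[1.0]]), grid=GRID1)
    return ba, of, land


class TestSelectLargestEvents:
    def test_plain_argmax(self):
        ba, of, land = fire_cell([0, 5, 3, 9, 2], [1, 1, 1, 1, 1])
        (ev,) = select_largest_events(ba, of, land)
        assert ev.event_time == (2001, 4)
        assert ev.ba_fraction == pytest.approx(9.0)

    def test_poorly_observed_month_excluded(self):
        # the 9 km² month has only 70% observed -> the 5 km² month wins
        ba, of, land = fire_cell([0, 5, 3, 9, 2], [1, 1, 1, 0.7, 1])
        (ev,) = select_largest_events(ba, of, land)
        assert ev.event_time == (2001, 2)

    def test_threshold_is_strict(self):
        # observed fraction exactly 0.8 is NOT "higher than 80%"
        ba, of, land = fire_cell([0, 5, 3, 9, 2], [1, 1, 1, 0.8, 1])
        (ev,) = select_largest_events(ba, of, land)
        assert ev.event_time == (2001, 2)

    def test_tie_breaks_to_earliest_month(self):
        ba, of, land = fire_cell([0, 9, 3, 9, 2], [1, 1, 1, 1, 1])
        (ev,) = select_largest_events(ba, of, land)
        assert ev.event_time == (2001, 2)
        # both candidates enumerate to the same max; choice is deterministic
        again, = select_largest_events(ba, of, land)
        assert again.event_time == ev.event_time

    def test_all_zero_or_inadmissible_yields_no_event(self):
        ba, of, land = fire_cell([0, 0, 0], [1, 1, 1])
        assert select_largest_events(ba, of, land) == []
        ba, of, land = fire_cell([1, 2, 3], [0.5, 0.5, 0.5])
        assert select_largest_events(ba, of, land) == []

    def test_nonpositive_land_area_masks_cell(self):
        ba, of, _ = fire_cell([0, 5, 3], [1, 1, 1])
        land = StaticField(values=np.array([[0.0]]), grid=GRID1)
        assert select_largest_events(ba, of, land) == []


class TestPopulationThreshold:
    def test_linear_interpolation_quartile(self):
        grid = Grid.regular(2, 2, 0.25)
        pop = StaticField(values=np.array([[1.0, 2.0], [3.0, 4.0]]), grid=grid)
        avail = np.ones((2, 2), dtype=bool)
        assert population_threshold(pop, avail, 25) == pytest.approx(1.75)
        assert population_threshold(pop, avail, 0) == pytest.approx(1.0)

    def test_uniform_density(self):
        grid = Grid.regular(2, 2, 0.25)
        pop = StaticField(values=np.full((2, 2), 5.0), grid=grid)
        avail = np.ones((2, 2), dtype=bool)
        assert population_threshold(pop, avail, 25) == pytest.approx(5.0)

    def test_restricted_to_available_cells(self):
        grid = Grid.regular(2, 2, 0.25)
        pop = StaticField(values=np.array([[1.0, 2.0], [3.0, 100.0]]), grid=grid)
        avail = np.array([[True, True], [True, False]])
        assert population_threshold(pop, avail, 100) == pytest.approx(3.0)

    def test_no_available_cells(self):
        pop = StaticField(values=np.ones((1, 1)), grid=GRID1)
        with pytest.raises(ValueError):
            population_threshold(pop, np.zeros((1, 1), dtype=bool), 25)


def scene_inputs(scene, min_days=15):
    monthly = daily_to_monthly(scene.soil_moisture, min_days)
    anom = normalize_anomaly(monthly, monthly_climatology(monthly))
    from firecomposite import long_term_mean
    tmean = long_term_mean(scene.temperature)
    return anom, tmean


class TestFilterEvents:
    def test_window_reaching_before_record_start_fails(self, null_anomalies,
                                                       null_scene):
        from firecomposite import FireEvent, long_term_mean
        ev = FireEvent(cell=(3, 3), event_time=(2001, 3), ba_fraction=0.1)
        tmean = long_term_mean(null_scene.temperature)
        kept, report = filter_events([ev], null_anomalies, tmean,
                                     null_scene.population)
        assert kept == []
        assert report.removed["sm_window_complete"] == 1

    def test_cold_cell_removed(self, null_scene, null_anomalies):
        from firecomposite import FireEvent, long_term_mean
        tmean = long_term_mean(null_scene.temperature)
        cold = np.argwhere(tmean.values < 0)
        assert cold.size, "scene should contain cold cells"
        i, j = cold[0]
        # pick an interior month with a complete anomaly window
        t0 = month_number(*null_anomalies.start)
        ok_t = next(t for t in range(6, null_anomalies.n_months - 1)
                    if not null_anomalies.mask[t - 5:t + 2, i, j].any())
        yy, mm = divmod(t0 + ok_t, 12)
        ev = FireEvent(cell=(int(i), int(j)), event_time=(yy, mm + 1),
                       ba_fraction=0.1)
        kept, report = filter_events([ev], null_anomalies, tmean,
                                     null_scene.population)
        assert kept == [] and report.removed["warm_enough"] == 1

    def test_survivors_match_brute_force(self, null_scene, null_anomalies):
        """Filter cascade equals a direct loop applying (a)-(c) per event."""
        from firecomposite import long_term_mean, select_largest_events
        tmean = long_term_mean(null_scene.temperature)
        cands = select_largest_events(null_scene.burned_area,
                                      null_scene.observed_fraction,
                                      null_scene.land_area)
        kept, report = filter_events(cands, null_anomalies, tmean,
                                     null_scene.population)

        avail = (~null_anomalies.mask).any(axis=0)
        thr = np.percentile(null_scene.population.values[avail], 25)
        start = month_number(*null_anomalies.start)
        expected = []
        for ev in cands:
            i, j = ev.cell
            t = month_number(*ev.event_time) - start
            window_ok = (t - 5 >= 0 and t + 1 < null_anomalies.n_months
                         and not any(null_anomalies.mask[l, i, j]
                                     for l in range(t - 5, t + 2)))
            if window_ok and tmean.values[i, j] >= 0 \
                    and null_scene.population.values[i, j] < thr:
                expected.append(ev.cell)
        assert [ev.cell for ev in kept] == expected
        assert report.check_conservation()

    def test_filters_are_monotone(self, null_scene, null_anomalies):
        """Tightening any threshold never adds events."""
        from firecomposite import long_term_mean, select_largest_events
        tmean = long_term_mean(null_scene.temperature)

        def survivors(min_obs=0.8, temp_min=0.0, pop_pct=25.0):
            cands = select_largest_events(null_scene.burned_area,
                                          null_scene.observed_fraction,
                                          null_scene.land_area, min_obs)
            kept, _ = filter_events(cands, null_anomalies, tmean,
                                    null_scene.population,
                                    temp_min=temp_min, pop_percentile=pop_pct)
            return {ev.cell for ev in kept}

        base = survivors()
        assert survivors(min_obs=0.9) <= base
        assert survivors(temp_min=5.0) <= base
        assert survivors(pop_pct=10.0) <= base

    def test_flags_and_report_consistency(self, null_scene, null_anomalies):
        from firecomposite import long_term_mean, select_largest_events
        tmean = long_term_mean(null_scene.temperature)
        cands = select_largest_events(null_scene.burned_area,
                                      null_scene.observed_fraction,
                                      null_scene.land_area)
        kept, report = filter_events(cands, null_anomalies, tmean,
                                     null_scene.population)
        assert report.n_candidates == len(cands)
        assert report.retained == len(kept)
        for ev in kept:
            assert all(ev.filters_passed[k] for k in FILTER_ORDER)
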