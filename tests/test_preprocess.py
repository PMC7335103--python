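"""Monthly aggregation, regridding, climatology and z-score contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from firecomposite import (
    DailyField,
    Grid,
    MonthlyField,
    StaticField,
    daily_to_monthly,
    monthly_climatology,
    normalize_anomaly,
    regrid,
)

GRID1 = Grid.regular(1, 1, 0.25)


def daily_field(values_1d, start="2001-01-01"):
    vals = np.asarray(values_1d, dtype=float)[:, None, None]
    return DailyField(values=vals, grid=GRID1, start=start)


class TestDailyToMonthly:
    def test_below_min_days_masked_at_threshold(self):
        # January 2001: 14 valid days -> masked, 15 valid -> kept
        vals = np.full(31, 0.3)
        vals[14:] = np.nan
        assert daily_to_monthly(daily_field(vals), 15).mask[0, 0, 0]
        vals[14] = 0.3
        out = daily_to_monthly(daily_field(vals), 15)
        assert not out.mask[0, 0, 0]
        assert out.values[0, 0, 0] == pytest.approx(0.3)

    def test_constant_month_mean(self):
        out = daily_to_monthly(daily_field(np.full(30, 0.2), "2001-04-01"), 15)
        assert out.values[0, 0, 0] == pytest.approx(0.2)
        assert out.start == (2001, 4)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(0)
        vals = rng.random(31)
        vals[rng.choice(31, 11, replace=False)] = np.nan   # 20 valid days
        out = daily_to_monthly(daily_field(vals), 15)
        expected = np.mean([v for v in vals if np.isfinite(v)])
        assert out.values[0, 0, 0] == pytest.approx(expected, abs=1e-14)

    def test_multi_month_split(self):
        # Jan=0.1 (31d), Feb=0.5 (28d)
        vals = np.r_[np.full(31, 0.1), np.full(28, 0.5)]
        out = daily_to_monthly(daily_field(vals), 15)
        assert out.n_months == 2
        np.testing.assert_allclose(out.values[:, 0, 0], [0.1, 0.5])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_permutation_invariant_and_monotone_in_min_days(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(31)
        vals[rng.random(31) < 0.5] = np.nan
        a = daily_to_monthly(daily_field(vals), 10)
        b = daily_to_monthly(daily_field(rng.permutation(vals)), 10)
        np.testing.assert_array_equal(np.isnan(a.values), np.isnan(b.values))
        if not a.mask[0, 0, 0]:
            assert a.values[0, 0, 0] == pytest.approx(b.values[0, 0, 0])
        # raising min_days never unmasks
        for lo, hi in [(5, 10), (10, 20), (20, 31)]:
            m_lo = daily_to_monthly(daily_field(vals), lo).mask
            m_hi = daily_to_monthly(daily_field(vals), hi).mask
            assert not (m_lo & ~m_hi).any()

    def test_rejects_impossible_min_days(self):
        with pytest.raises(ValueError):
            daily_to_monthly(daily_field(np.ones(31)), 32)


class TestRegrid:
    def test_identity_on_same_grid(self):
        grid = Grid.regular(3, 3, 0.25)
        f = StaticField(values=np.arange(9.0).reshape(3, 3), grid=grid)
        assert regrid(f, grid) is f

    def test_nearest_refines_half_degree_into_four_children(self):
        # hand-enumerated 2x2 -> 4x4 center containment
        coarse = Grid.regular(2, 2, 0.5)
        fine = Grid.regular(4, 4, 0.25)
        f = StaticField(values=np.array([[1.0, 2.0], [3.0, 4.0]]), grid=coarse)
        out = regrid(f, fine, "nearest")
        expected = np.array([[1, 1, 2, 2], [1, 1, 2, 2],
                             [3, 3, 4, 4], [3, 3, 4, 4]], dtype=float)
        np.testing.assert_array_equal(out.values, expected)

    def test_cell_average_of_four_cells(self):
        fine = Grid.regular(2, 2, 0.25)
        coarse = Grid.regular(1, 1, 0.5)
        f = StaticField(values=np.array([[1.0, 2.0], [3.0, 6.0]]), grid=fine)
        out = regrid(f, coarse, "cell-average")
        assert out.values[0, 0] == pytest.approx(3.0)

    def test_cell_average_is_mask_aware_and_conservative(self):
        rng = np.random.default_rng(3)
        fine = Grid.regular(4, 6, 0.25)
        coarse = Grid.regular(2, 3, 0.5)
        vals = rng.random((5, 4, 6))
        f = MonthlyField(values=vals, grid=fine, start=(2001, 1))
        out = regrid(f, coarse, "cell-average")
        # fully observed uniform grid: coarse mean == fine mean
        assert out.values.mean() == pytest.approx(vals.mean(), abs=1e-12)
        # masked source cells are excluded, empty target cells masked
        vals2 = vals.copy()
        vals2[:, :2, :2] = np.nan
        out2 = regrid(MonthlyField(values=vals2, grid=fine, start=(2001, 1)),
                      coarse, "cell-average")
        assert out2.mask[:, 0, 0].all()
        assert np.isfinite(out2.values[:, 1, :]).all()

    def test_cell_average_refinement_rejected(self):
        f = StaticField(values=np.ones((2, 2)), grid=Grid.regular(2, 2, 0.5))
        with pytest.raises(ValueError, match="nearest"):
            regrid(f, Grid.regular(4, 4, 0.25), "cell-average")


def monthly_cell(series, start=(2001, 1)):
    return MonthlyField(values=np.asarray(series, dtype=float)[:, None, None],
                        grid=GRID1, start=start)


class TestClimatology:
    def test_constant_field_masked_sd(self):
        f = monthly_cell(np.full(36, 0.4))
        clim = monthly_climatology(f)
        np.testing.assert_allclose(clim.mean[:, 0, 0], 0.4)
        np.testing.assert_allclose(clim.sd[:, 0, 0], 0.0, atol=1e-12)
        assert clim.mask.all()          # sd = 0 -> unusable for z-scores

    def test_eighteen_januaries_closed_form(self):
        vals = np.full(18 * 12, np.nan)
        vals[::12] = np.arange(1, 19)            # Jan = 1..18
        clim = monthly_climatology(monthly_cell(vals))
        assert clim.mean[0, 0, 0] == pytest.approx(9.5)
        # sample sd of 1..n is sqrt(n*(n+1)/12)
        assert clim.sd[0, 0, 0] == pytest.approx(np.sqrt(18 * 19 / 12))
        assert clim.n[0, 0, 0] == 18

    def test_masked_years_reduce_n(self):
        rng = np.random.default_rng(1)
        vals = rng.random(18 * 12)
        vals[[0, 24, 60]] = np.nan               # three masked Januaries
        clim = monthly_climatology(monthly_cell(vals))
        assert clim.n[0, 0, 0] == 15
        assert clim.n[1, 0, 0] == 18

    def test_rejects_short_period(self):
        with pytest.raises(ValueError):
            monthly_climatology(monthly_cell(np.ones(24)), period=(2001, 2001))


class TestNormalizeAnomaly:
    def test_mean_and_one_sigma(self):
        rng = np.random.default_rng(5)
        f = monthly_cell(rng.normal(0.3, 0.05, 18 * 12))
        clim = monthly_climatology(f)
        at_mean = monthly_cell(np.tile(clim.mean[:, 0, 0], 18))
        z0 = normalize_anomaly(at_mean, clim)
        np.testing.assert_allclose(z0.z[~z0.mask], 0.0, atol=1e-12)
        plus_one = monthly_cell(np.tile(clim.mean[:, 0, 0] + clim.sd[:, 0, 0], 18))
        z1 = normalize_anomaly(plus_one, clim)
        np.testing.assert_allclose(z1.z[~z1.mask], 1.0, atol=1e-12)

    def test_matches_per_month_loop(self):
        rng = np.random.default_rng(6)
        series = rng.normal(0.3, 0.05, 18 * 12)
        f = monthly_cell(series)
        z = normalize_anomaly(f, monthly_climatology(f))
        # independent brute-force z-score per month-of-year
        for t in range(series.size):
            moy = t % 12
            sample = series[moy::12]
            expect = (series[t] - sample.mean()) / sample.std(ddof=1)
            assert z.z[t, 0, 0] == pytest.approx(expect, abs=1e-12)

    def test_self_consistency_on_synthetic_scene(self, null_anomalies):
        """Per cell and month-of-year, z has mean 0 and sd 1 over the period."""
        z = null_anomalies.z
        for moy in range(12):
            sample = z[moy::12]
            ok = np.isfinite(sample)
            enough = ok.sum(axis=0) >= 2
            mean = np.nanmean(sample, axis=0)[enough]
            sd = np.nanstd(sample, axis=0, ddof=1)[enough]
            np.testing.assert_allclose(mean, 0.0, atol=1e-10)
            np.testing.assert_allclose(sd, 1.0, atol=1e-10)
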