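"""Conditioning of moored sensor series: bursts, blow-downs, filtering."""

import numpy as np
import pandas as pd
import pytest

from moorbloom import timeseries as ts
from moorbloom.timeseries import MooringSeries, QCFlag


def make_series(values, index, actual_depth=None, nominal=30.0, **kw):
    return MooringSeries(
        time=index[: len(values)],
        values=np.asarray(values, dtype=float),
        units="test units",
        nominal_depth=nominal,
        actual_depth=actual_depth,
        **kw,
    )


class TestBurstAverage:
    @pytest.mark.parametrize(
        "samples, expected",
        [
            ([1, 1, 1, 1, 1], 1.0),
            ([0, 2, 4, 6, 8], 4.0),
            ([0.0], 0.0),
        ],
    )
    def test_arithmetic_mean(self, samples, expected):
        assert ts.burst_average(samples) == pytest.approx(expected)

    def test_masked_samples_excluded(self):
        # 8-sample burst, 2 masked; mean of the remaining six is 3.5
        samples = [2, 3, 4, 5, 3, 4, 100, 200]
        mask = [False] * 6 + [True, True]
        assert ts.burst_average(samples, mask) == pytest.approx(3.5)

    def test_empty_burst_is_missing(self):
        assert np.isnan(ts.burst_average([], None))
        assert np.isnan(ts.burst_average([np.nan, np.nan]))

    def test_burst_series_stamps_burst_hour(self):
        t = pd.DatetimeIndex(
            ["2018-06-01 00:00:00", "2018-06-01 00:00:01", "2018-06-01 01:00:00"]
        )
        out = ts.burst_series_to_hourly(t, [1.0, 3.0, 5.0], units="u")
        assert list(out.values) == [2.0, 5.0]
        assert out.time[0] == pd.Timestamp("2018-06-01 00:00:00")


class TestBlowdownMasking:
    def test_deep_excursion_flagged(self, hourly_index):
        # instruments were dragged down intermittently by up to 200 m
        s = make_series([1.0, 2.0], hourly_index, actual_depth=[230.0, 31.0])
        out = ts.mask_blowdowns(s, threshold_m=10.0)
        assert out.qc[0] == QCFlag.BLOWDOWN
        assert out.qc[1] == QCFlag.OK

    def test_zero_threshold_identity_depths(self, hourly_index):
        s = make_series([1.0, 2.0], hourly_index, actual_depth=[30.0, 30.0])
        out = ts.mask_blowdowns(s, threshold_m=0.0)
        assert not np.any(out.qc == QCFlag.BLOWDOWN)

    def test_missing_depth_warns_noop(self, hourly_index):
        s = make_series([1.0, 2.0], hourly_index)
        with pytest.warns(UserWarning):
            out = ts.mask_blowdowns(s)
        assert np.array_equal(out.qc, s.qc)

    def test_masked_values_never_reach_daily_mean(self, hourly_index):
        vals = np.ones(48)
        depth = np.full(48, 30.0)
        depth[5] = 300.0
        s = make_series(vals, hourly_index, actual_depth=depth)
        s.values[5] = 1e9  # garbage during the blow-down
        out = ts.daily_mean(ts.mask_blowdowns(s))
        assert np.allclose(out.values, 1.0)


class TestLowpass:
    def test_constant_preserved(self, hourly_index):
        s = make_series(np.full(1200, 3.7), hourly_index)
        out = ts.lowpass(s, cutoff_days=5.0)
        assert np.allclose(out.values, 3.7, atol=1e-9)

    def test_one_day_period_strongly_attenuated(self, hourly_index):
        t = np.arange(1200)
        s = make_series(np.sin(2 * np.pi * t / 24.0), hourly_index)
        out = ts.lowpass(s, cutoff_days=5.0)
        interior = out.values[200:-200]
        assert np.nanmax(np.abs(interior)) < 0.1  # >= 10x attenuation

    def test_thirty_day_period_passes(self):
        idx = pd.date_range("2018-01-01", periods=24 * 120, freq="h")
        t = np.arange(len(idx))
        s = make_series(np.sin(2 * np.pi * t / (24.0 * 30.0)), idx)
        out = ts.lowpass(s, cutoff_days=5.0)
        interior = out.values[500:-500]
        assert np.nanmax(np.abs(interior)) > 0.95  # within 5% of input

    def test_too_short_raises(self):
        idx = pd.date_range("2018-01-01", periods=50, freq="h")
        with pytest.raises(ValueError):
            ts.lowpass(make_series(np.ones(50), idx))

    def test_linearity_on_gap_free_input(self, hourly_index, rng):
        x = rng.normal(size=1200)
        y = rng.normal(size=1200)
        fx = ts.lowpass(make_series(x, hourly_index)).values
        fy = ts.lowpass(make_series(y, hourly_index)).values
        fxy = ts.lowpass(make_series(2.0 * x + 3.0 * y, hourly_index)).values
        assert np.allclose(fxy, 2.0 * fx + 3.0 * fy, atol=1e-8)


class TestDailyMean:
    def test_full_day_mean(self, hourly_index):
        out = ts.daily_mean(make_series([5.0] * 24, hourly_index))
        assert out.values[0] == pytest.approx(5.0)

    def test_half_zeros_half_twos(self, hourly_index):
        out = ts.daily_mean(make_series([0.0] * 12 + [2.0] * 12, hourly_index))
        assert out.values[0] == pytest.approx(1.0)

    def test_sparse_day_missing(self, hourly_index):
        vals = np.full(24, np.nan)
        vals[:2] = 1.0
        out = ts.daily_mean(make_series(vals, hourly_index), min_samples=6)
        assert np.isnan(out.values[0])


class TestInvariantsAndIO:
    def test_time_must_increase(self):
        idx = pd.DatetimeIndex(["2018-01-02", "2018-01-01"])
        with pytest.raises(ValueError):
            MooringSeries(time=idx, values=[1.0, 2.0], units="u")

    def test_units_required(self, hourly_index):
        with pytest.raises(ValueError):
            MooringSeries(time=hourly_index[:2], values=[1.0, 2.0], units="")

    def test_csv_roundtrip_bit_exact(self, tmp_path, hourly_index, rng):
        s = make_series(rng.normal(size=48), hourly_index,
                        actual_depth=np.full(48, 30.5))
        s.qc[3] = QCFlag.BLOWDOWN
        p = tmp_path / "series.csv"
        ts.to_csv(s, p)
        back = ts.from_csv(p)
        assert np.array_equal(back.values, s.values)
        assert np.array_equal(back.qc, s.qc)
        assert back.units == s.units
        assert back.nominal_depth == s.nominal_depth
        assert (back.time == s.time).all()

    def test_netcdf_roundtrip_bit_exact(self, tmp_path, hourly_index, rng):
        s = make_series(rng.normal(size=48), hourly_index, name="nitrate")
        s.qc[7] = QCFlag.MISSING
        p = tmp_path / "series.nc"
        ts.to_netcdf(s, p)
        back = ts.from_netcdf(p)
        assert np.array_equal(back.values, s.values)
        assert np.array_equal(back.qc, s.qc)
        assert back.units == s.units
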