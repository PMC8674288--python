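"""Bloom onset/end detection, growth fits, regressions, regime logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from moorbloom import phenology as ph


def daily_index(start="2018-03-01", n=150):
    return pd.date_range(start, periods=n, freq="D")


class TestOnset:
    def test_single_crossing(self):
        idx = daily_index()
        cross = pd.Timestamp("2018-05-01")
        flux = pd.Series(np.where(idx < cross, -50.0, 30.0), index=idx)
        assert ph.detect_bloom_onset(flux) == cross

    def test_short_positive_excursion_ignored(self):
        idx = daily_index(n=60)
        vals = np.full(60, -20.0)
        vals[10:13] = 15.0  # 3 positive days < persistence 5
        vals[40:] = 25.0
        onset = ph.detect_bloom_onset(pd.Series(vals, index=idx))
        assert onset == idx[40]

    def test_always_positive_returns_first_date(self):
        idx = daily_index(n=30)
        flux = pd.Series(10.0, index=idx)
        assert ph.detect_bloom_onset(flux) == idx[0]

    def test_never_positive_raises(self):
        idx = daily_index(n=30)
        with pytest.raises(ValueError):
            ph.detect_bloom_onset(pd.Series(-5.0, index=idx))


class TestBloomEnd:
    def test_depletion_date(self):
        idx = daily_index("2018-05-01", 60)
        vals = np.linspace(12.0, 0.0, 60)
        end = ph.detect_bloom_end(pd.Series(vals, index=idx), onset=idx[0])
        # first value < 1 umol/l
        expected = idx[np.argmax(vals < 1.0)]
        assert end == expected

    def test_never_depleted_returns_missing(self):
        idx = daily_index("2017-05-10", 90)
        end = ph.detect_bloom_end(pd.Series(10.0, index=idx), onset=idx[0])
        assert end is None

    def test_zero_threshold_never_triggers_on_positive_series(self):
        idx = daily_index("2018-05-01", 30)
        end = ph.detect_bloom_end(
            pd.Series(0.5, index=idx), onset=idx[0], depletion_threshold=0.0
        )
        assert end is None


class TestGrowthRate:
    def test_noiseless_exponential_recovered(self):
        idx = daily_index("2018-05-01", 20)
        t = np.arange(20)
        chl = pd.Series(0.1 * np.exp(0.2 * t), index=idx)
        assert ph.efolding_growth_rate(chl) == pytest.approx(0.2, abs=1e-12)

    def test_noisy_exponential_within_band(self):
        idx = daily_index("2018-05-01", 14)
        t = np.arange(14)
        rng = np.random.default_rng(42)
        chl = pd.Series(0.1 * np.exp(0.2 * t) * np.exp(rng.normal(0, 0.1, 14)),
                        index=idx)
        assert ph.efolding_growth_rate(chl) == pytest.approx(0.2, abs=0.05)

    def test_constant_series_zero_rate(self):
        idx = daily_index("2018-05-01", 10)
        assert ph.efolding_growth_rate(pd.Series(1.0, index=idx)) == pytest.approx(0.0)

    def test_nonpositive_excluded_with_warning(self):
        idx = daily_index("2018-05-01", 10)
        vals = 0.1 * np.exp(0.2 * np.arange(10))
        vals[3] = 0.0
        with pytest.warns(UserWarning):
            rate = ph.efolding_growth_rate(pd.Series(vals, index=idx))
        assert rate == pytest.approx(0.2, abs=0.01)


class TestRegressions:
    def test_exact_line(self):
        idx = daily_index("2018-05-01", 20)
        x = pd.Series(np.linspace(0, 10, 20), index=idx)
        fit = ph.regress_pair(x, 7.0 * x + 1.0)
        assert fit.m == pytest.approx(7.0)
        assert fit.b == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_insufficient_pairs_raise(self):
        idx = daily_index("2018-05-01", 5)
        x = pd.Series(np.arange(5.0), index=idx)
        with pytest.raises(ValueError):
            ph.regress_pair(x, x)

    def test_parameter_recovery_with_noise(self):
        """Known coupling recovered within 2 standard errors across seeds."""
        idx = daily_index("2018-05-01", 45)
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            no3 = pd.Series(np.linspace(12.0, 0.4, 45), index=idx)
            aou = -7.0 * (12.0 - no3) + rng.normal(0, 2.0, 45)
            fit = ph.regress_pair(no3, aou)
            se = 2.0 / (np.std(no3.to_numpy()) * np.sqrt(45))  # analytic slope se
            if abs(fit.m - 7.0) <= 2.0 * se:
                hits += 1
        assert hits >= 90  # ~95% nominal coverage


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "mld, ds, expected",
        [
            (10.0, 4.5, "MW"),
            (45.0, 0.2, "ML"),
            (60.0, 2.0, "unstratified"),
            (49.9, 1.0, "ML"),  # dS boundary goes to ML
            (50.0, 4.0, "unstratified"),
        ],
    )
    def test_examples(self, mld, ds, expected):
        assert ph.classify_regime(mld, ds) == expected

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ph.classify_regime(float("nan"), 1.0)

    @given(st.floats(min_value=0, max_value=300, allow_nan=False),
           st.floats(min_value=-1, max_value=6, allow_nan=False))
    def test_every_state_in_exactly_one_class(self, mld, ds):
        assert ph.classify_regime(mld, ds) in ("MW", "ML", "unstratified")

    def test_regime_area_matches_cell_enumeration(self, rng):
        mld = rng.uniform(0, 120, size=(15, 20))
        ds = rng.uniform(-0.5, 4, size=(15, 20))
        areas = rng.uniform(10, 50, size=(15, 20))
        got = ph.regime_area(mld, ds, areas)
        want = {"MW": 0.0, "ML": 0.0, "unstratified": 0.0}
        for i in range(15):
            for j in range(20):
                want[ph.classify_regime(mld[i, j], ds[i, j])] += areas[i, j]
        for key in want:
            assert got[key] == pytest.approx(want[key])
        assert sum(got.values()) == pytest.approx(areas.sum())

    def test_uniform_grid_single_class(self):
        got = ph.regime_area([[10.0, 20.0]], [[3.0, 2.0]], [[100.0, 100.0]])
        assert got == {"MW": 200.0, "ML": 0.0, "unstratified": 0.0}


class TestExportLag:
    def test_six_week_lag(self):
        onset = pd.Timestamp("2018-05-01")
        idx = daily_index("2018-04-01", 200)
        t = (idx - onset) / pd.Timedelta(days=1)
        flux = pd.Series(np.exp(-0.5 * ((t - 42.0) / 10.0) ** 2), index=idx)
        peaks, lags, retention = ph.export_lag(onset, {2600.0: flux})
        assert peaks[2600.0] == onset + pd.Timedelta(days=42)
        assert lags[2600.0] == pytest.approx(42 / 30.44, rel=1e-6)
        assert retention == lags[2600.0]

    def test_monotone_decreasing_flux_zero_lag(self):
        onset = pd.Timestamp("2018-05-01")
        idx = daily_index("2018-05-01", 60)
        flux = pd.Series(np.linspace(10.0, 1.0, 60), index=idx)
        _, lags, _ = ph.export_lag(onset, {200.0: flux})
        assert lags[200.0] == 0.0

    def test_no_post_onset_data_raises(self):
        idx = daily_index("2018-01-01", 30)
        flux = pd.Series(1.0, index=idx)
        with pytest.raises(ValueError):
            ph.export_lag("2019-01-01", {200.0: flux})

    def test_date_outputs_shift_with_dataset(self):
        onset = pd.Timestamp("2018-05-01")
        idx = daily_index("2018-04-01", 120)
        t = (idx - onset) / pd.Timedelta(days=1)
        flux = pd.Series(np.exp(-0.5 * ((t - 30.0) / 8.0) ** 2), index=idx)
        _, lags_a, _ = ph.export_lag(onset, {200.0: flux})
        shift = pd.Timedelta(days=365)
        _, lags_b, _ = ph.export_lag(
            onset + shift, {200.0: flux.set_axis(idx + shift)}
        )
        assert lags_a == lags_b
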