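"""Synthetic regime-year generator: backbone exactness, noise, fixtures."""

import numpy as np
import pandas as pd
import pytest

from moorbloom import synthetic
from moorbloom.synthetic import ScenarioConfig


class TestBackbone:
    def test_ml_chlorophyll_ceiling(self, ml_noiseless):
        assert ml_noiseless.hourly["chl_30m"].max() == pytest.approx(7.0, abs=1e-6)

    def test_ml_nitrate_depletes(self, ml_noiseless):
        ni = ml_noiseless.hourly["nitrate_30m"]
        assert ni.iloc[0] == pytest.approx(12.0, abs=0.01)
        assert ni.min() < 1.0

    def test_exact_stoichiometric_coupling(self, ml_noiseless):
        h = ml_noiseless.hourly
        dno3 = 12.0 - h["nitrate_30m"]
        assert np.allclose(h["aou_30m"], -7.0 * dno3, atol=1e-9)

    def test_pco2_drawdown_magnitude(self, ml_noiseless):
        pco2 = ml_noiseless.hourly["pco2_30m"]
        assert pco2.iloc[0] == pytest.approx(400.0, abs=0.1)
        assert pco2.min() == pytest.approx(220.0, abs=0.1)

    def test_mw_30m_channels_nearly_flat(self, mw_noiseless):
        h = mw_noiseless.hourly
        assert 12.0 - h["nitrate_30m"].min() < 3.0
        assert h["aou_30m"].min() > -20.0
        assert h["chl_30m"].max() < 2.0

    def test_mw_par_shading_two_orders(self, mw_noiseless):
        h = mw_noiseless.hourly
        # compare daily-noon PAR at 30 m before and at the shading peak
        par = h["par_30m"].resample("D").max()
        pre = par.loc["2017-05-01":"2017-05-05"].mean()
        shaded = par.loc["2017-08-05":"2017-08-15"].mean()  # peak shading
        assert pre / shaded > 50.0  # almost two orders of magnitude

    def test_mw_surface_salinity_reaches_meltwater_minimum(self, mw_noiseless):
        assert mw_noiseless.hourly["salinity_surface"].min() == pytest.approx(
            30.5, abs=0.1
        )

    def test_heat_flux_crosses_zero_at_onset(self, ml_noiseless):
        q = ml_noiseless.daily["heat_flux"]
        first_pos = q[q > 0].index[0]
        assert first_pos == pd.Timestamp("2018-05-01")

    def test_inconsistent_dates_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(bloom_start="2018-06-15", bloom_end="2018-05-01")


class TestDeterminismAndNoise:
    def test_same_seed_identical(self):
        a = synthetic.generate_scenario(regime="ML", seed=5)
        b = synthetic.generate_scenario(regime="ML", seed=5)
        pd.testing.assert_frame_equal(a.hourly, b.hourly)
        pd.testing.assert_frame_equal(a.fluxes, b.fluxes)

    def test_different_seed_same_backbone(self):
        a = synthetic.generate_scenario(regime="ML", seed=1)
        b = synthetic.generate_scenario(regime="ML", seed=2)
        assert not np.allclose(a.hourly["nitrate_30m"], b.hourly["nitrate_30m"])
        an = synthetic.generate_scenario(regime="ML", seed=1, noise=False)
        bn = synthetic.generate_scenario(regime="ML", seed=2, noise=False)
        pd.testing.assert_frame_equal(an.hourly, bn.hourly)

    def test_ar1_autocorrelation_matches_coefficient(self):
        rng = np.random.default_rng(0)
        x = synthetic.ar1_noise(730, 0.6, 1.0, rng)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.6, abs=0.05)

    def test_seed_averaging_converges_to_backbone(self, ml_noiseless):
        """Noise is additive: the mean over seeds approaches the backbone."""
        n_seeds = 12
        sel = slice("2018-05-01", "2018-06-15")
        acc = None
        for seed in range(n_seeds):
            ni = synthetic.generate_scenario(regime="ML", seed=seed).hourly[
                "nitrate_30m"
            ].loc[sel]
            acc = ni if acc is None else acc + ni
        mean = acc / n_seeds
        backbone = ml_noiseless.hourly["nitrate_30m"].loc[sel]
        sd = 0.3  # configured nitrate channel noise SD
        rms = float(np.sqrt(np.mean((mean - backbone) ** 2)))
        assert rms < 3.0 * sd / np.sqrt(n_seeds)


class TestForcing:
    def test_noiseless_crossing_at_regime_onset(self):
        _, daily_q = synthetic.generate_forcing("ML", seed=0, noise=False)
        first_pos = daily_q[daily_q > 0].index[0]
        assert first_pos == pd.Timestamp("2018-05-01")

    def test_annual_mean_matches_configured_mean(self):
        idx = pd.date_range("2018-01-01", periods=365, freq="D")
        q = synthetic.seasonal_heat_flux(idx, "2018-05-01", amplitude=150.0, mean=0.0)
        assert np.mean(q) == pytest.approx(0.0, abs=1.0)

    def test_short_span_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_forcing("ML", span=("2018-05-01", "2018-05-20"))

    def test_forcing_columns_complete(self):
        f, _ = synthetic.generate_forcing("MW", seed=1)
        assert set(f.columns) == {"wind_u", "wind_v", "q_nonpen", "q_sw", "emp"}


class TestExports:
    def test_export_integrals_match_observed_contrasts(
        self, ml_noiseless, mw_noiseless
    ):
        def g_per_window(ds, a, b):
            return ds.fluxes["poc_2600m"].loc[a:b].sum() / 1000.0

        ml_spring = g_per_window(ml_noiseless, "2018-03-01", "2018-08-31")
        ml_autumn = g_per_window(ml_noiseless, "2018-09-01", "2018-11-30")
        mw_spring = g_per_window(mw_noiseless, "2017-03-01", "2017-08-31")
        mw_autumn = g_per_window(mw_noiseless, "2017-09-01", "2017-11-30")
        assert ml_spring == pytest.approx(3.4, rel=0.05)
        assert ml_autumn == pytest.approx(1.1, rel=0.05)
        assert mw_spring == pytest.approx(1.3, rel=0.05)
        assert mw_autumn == pytest.approx(2.1, rel=0.05)

    def test_exponential_backbone_for_growth_fits(self):
        s = synthetic.exponential_chl(14, rate=0.2, noise_sd=0.0)
        assert np.allclose(np.diff(np.log(s.to_numpy())), 0.2)


class TestFixtures:
    def test_write_read_roundtrip(self, tmp_path, mw_noiseless):
        out = synthetic.write_fixture(mw_noiseless, tmp_path / "mw")
        back = synthetic.read_fixture(out)
        pd.testing.assert_frame_equal(back.hourly, mw_noiseless.hourly,
                                      check_freq=False)
        pd.testing.assert_frame_equal(back.fluxes, mw_noiseless.fluxes,
                                      check_freq=False)
        assert back.config.seed == mw_noiseless.config.seed
        assert back.config.regime == "MW"

    def test_manifest_records_seed(self, tmp_path):
        ds = synthetic.generate_scenario(regime="ML", seed=99)
        out = synthetic.write_fixture(ds, tmp_path / "ml")
        import json

        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["seed"] == 99
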