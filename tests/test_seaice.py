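"""Gridded sea-ice metrics: percent ice days, edge distance, gate export."""

import numpy as np
import pandas as pd
import pytest

from moorbloom import seaice
from moorbloom.seaice import Gate, GriddedIceField


def make_field(conc, lat=None, lon=None, u=None, v=None, start="2017-04-01"):
    conc = np.asarray(conc, dtype=float)
    n_days, nlat, nlon = conc.shape
    return GriddedIceField(
        time=pd.date_range(start, periods=n_days, freq="D"),
        lat=lat if lat is not None else np.linspace(78.0, 80.0, nlat),
        lon=lon if lon is not None else np.linspace(0.0, 8.0, nlon),
        conc=conc,
        u=u,
        v=v,
    )


class TestPctIceDays:
    def test_always_icy(self):
        field = make_field(np.full((10, 3, 3), 100.0))
        assert np.allclose(seaice.pct_ice_days(field), 100.0)

    def test_never_icy(self):
        field = make_field(np.zeros((10, 3, 3)))
        assert np.allclose(seaice.pct_ice_days(field), 0.0)

    def test_counting_rule(self):
        conc = np.zeros((10, 1, 1))
        conc[:3] = 50.0
        field = make_field(conc)
        assert seaice.pct_ice_days(field)[0, 0] == pytest.approx(30.0)

    def test_day_order_invariance(self, rng):
        conc = rng.uniform(0, 100, size=(30, 4, 4))
        a = seaice.pct_ice_days(make_field(conc))
        b = seaice.pct_ice_days(make_field(conc[::-1]))
        assert np.allclose(a, b)

    def test_month_selection(self):
        conc = np.zeros((61, 1, 1))
        conc[:30] = 100.0  # April all icy, May open
        field = make_field(conc, start="2017-04-01")
        april = seaice.pct_ice_days(field, months=(4,))
        assert april[0, 0] == pytest.approx(100.0)


class TestDistanceToEdge:
    def _field_with_edge(self):
        # ice (conc 50) in the west half, open water (conc 10) in the east
        conc = np.zeros((1, 5, 8))
        conc[0, :, :4] = 50.0
        conc[0, :, 4:] = 10.0
        return make_field(conc, lat=np.linspace(79.0, 79.4, 5),
                          lon=np.linspace(0.0, 7.0, 8))

    def test_sign_negative_inside_ice(self):
        field = self._field_with_edge()
        d = seaice.distance_to_edge(field, field.time[0], 79.2, 1.0)
        assert d < 0

    def test_sign_positive_in_open_water(self):
        field = self._field_with_edge()
        d = seaice.distance_to_edge(field, field.time[0], 79.2, 6.0)
        assert d > 0

    def test_magnitude_matches_brute_force(self, rng):
        conc = rng.uniform(0, 100, size=(1, 6, 7))
        field = make_field(conc)
        point = (float(field.lat[2]), float(field.lon[3]))
        d = seaice.distance_to_edge(field, field.time[0], *point)
        # exhaustive scan over every opposite-class cell
        in_ice = conc[0, 2, 3] > 20.0
        best = np.inf
        for i in range(6):
            for j in range(7):
                opposite = (conc[0, i, j] <= 20.0) if in_ice else (conc[0, i, j] > 20.0)
                if opposite:
                    best = min(best, float(seaice.great_circle_km(
                        point[0], point[1], field.lat[i], field.lon[j])))
        assert abs(d) == pytest.approx(best, rel=1e-12)
        assert (d < 0) == in_ice

    def test_sign_flips_when_cell_crosses_threshold(self):
        conc = np.zeros((2, 3, 3))
        conc[:, :, 0] = 80.0  # permanent ice column to the west
        conc[0, 1, 1] = 10.0  # point cell open on day 1
        conc[1, 1, 1] = 30.0  # above threshold on day 2
        field = make_field(conc)
        lat, lon = float(field.lat[1]), float(field.lon[1])
        d0 = seaice.distance_to_edge(field, field.time[0], lat, lon)
        d1 = seaice.distance_to_edge(field, field.time[1], lat, lon)
        assert d0 > 0 > d1

    def test_uniform_field_missing_with_warning(self):
        field = make_field(np.full((1, 3, 3), 50.0))
        with pytest.warns(UserWarning):
            d = seaice.distance_to_edge(field, field.time[0], 79.0, 4.0)
        assert np.isnan(d)


class TestAreaExport:
    def _uniform_field(self, conc_pct=100.0, v_kmday=-10.0, n_days=1):
        shape = (n_days, 5, 9)
        lat = np.linspace(81.0, 83.0, 5)
        lon = np.linspace(-2.0, 2.0, 9)
        return make_field(
            np.full(shape, conc_pct), lat=lat, lon=lon,
            u=np.zeros(shape), v=np.full(shape, v_kmday),
        )

    def _zonal_gate(self):
        return Gate(vertices=[(82.0, -1.0), (82.0, 1.0)], positive_normal="south")

    def test_closed_form_uniform_southward_drift(self):
        # 100% ice moving south at 10 km/day across a zonal gate
        field = self._uniform_field()
        gate = self._zonal_gate()
        gate_length = seaice.great_circle_km(82.0, -1.0, 82.0, 1.0)
        out = seaice.area_export(field, gate)
        assert out.iloc[0] == pytest.approx(10.0 * gate_length, rel=1e-9)

    def test_zero_concentration_zero_flux(self):
        field = self._uniform_field(conc_pct=0.0)
        out = seaice.area_export(field, self._zonal_gate())
        assert out.iloc[0] == 0.0

    def test_linear_in_concentration_and_drift(self):
        gate = self._zonal_gate()
        full = seaice.area_export(self._uniform_field(100.0, -10.0), gate).iloc[0]
        half_conc = seaice.area_export(self._uniform_field(50.0, -10.0), gate).iloc[0]
        half_drift = seaice.area_export(self._uniform_field(100.0, -5.0), gate).iloc[0]
        assert half_conc == pytest.approx(0.5 * full, rel=1e-9)
        assert half_drift == pytest.approx(0.5 * full, rel=1e-9)

    def test_matches_per_cell_brute_force(self, rng):
        shape = (2, 5, 9)
        lat = np.linspace(81.0, 83.0, 5)
        lon = np.linspace(-2.0, 2.0, 9)
        field = make_field(
            rng.uniform(0, 100, shape), lat=lat, lon=lon,
            u=rng.normal(0, 5, shape), v=rng.normal(0, 5, shape),
        )
        gate = self._zonal_gate()
        got = seaice.area_export(field, gate, samples_per_segment=40)
        # brute force: enumerate the same sample points cell by cell
        pts, lens = seaice._segment_samples(gate, 40)
        for d in range(2):
            total = 0.0
            for (plat, plon), dl in zip(pts, lens):
                i = int(np.argmin(np.abs(lat - plat)))
                j = int(np.argmin(np.abs(lon - plon)))
                total += -field.v[d, i, j] * (field.conc[d, i, j] / 100.0) * dl
            assert got.iloc[d] == pytest.approx(total, rel=1e-9)

    def test_missing_drift_rejected(self):
        field = make_field(np.full((1, 3, 3), 50.0))
        with pytest.raises(ValueError):
            seaice.area_export(field, self._zonal_gate())
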