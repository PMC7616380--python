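"""Feature engineering: LOO-IDW surfaces, monitor distances, derived
meteorology, calendar features, raster harmonisation, road density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airstack.features import (assemble_feature_table, derive_meteorology,
                               harmonize_to_grid, loo_idw_surface,
                               nearest_monitor_distance, road_density,
                               temporal_features)
from airstack.grids import GridDomain, RasterField
from airstack.qc import Monitor


def _mon(i, x, y, mtype="background"):
    return Monitor(f"M{i}", "AURN", x, y, mtype)


def _brute_idw(px, py, monitors, means, power, exclude=None):
    num = den = 0.0
    for m in monitors:
        if m.id == exclude:
            continue
        d = np.hypot(px - m.x, py - m.y)
        if d == 0:
            return means[m.id]
        num += means[m.id] / d ** power
        den += 1.0 / d ** power
    return num / den


class TestLooIdw:
    def test_single_monitor_gives_its_mean(self):
        mon = [_mon(0, 500.0, 500.0)]
        for power in (1, 2):
            v = loo_idw_surface(np.array([[3000.0, 4000.0]]), mon, {"M0": 7.5},
                                "background", power)
            assert v[0] == pytest.approx(7.5)

    def test_worked_example_two_monitors(self):
        """Means 10 and 20 at distances 1 and 2 m: 13.333 (p=1), 12.0 (p=2)."""
        mon = [_mon(0, 1.0, 0.0), _mon(1, 2.0, 0.0)]
        means = {"M0": 10.0, "M1": 20.0}
        q = np.array([[0.0, 0.0]])
        assert loo_idw_surface(q, mon, means, "background", 1)[0] == pytest.approx(40.0 / 3.0)
        assert loo_idw_surface(q, mon, means, "background", 2)[0] == pytest.approx(12.0)

    def test_leave_one_out_excludes_self(self):
        mon = [_mon(0, 0.0, 0.0, "hotspot"), _mon(1, 1000.0, 0.0, "hotspot")]
        means = {"M0": 100.0, "M1": 30.0}
        v = loo_idw_surface(np.array([[0.0, 0.0]]), mon, means, "hotspot", 2,
                            exclude_ids=["M0"])
        assert v[0] == pytest.approx(30.0)  # self excluded; only M1 remains

    def test_excluding_only_monitor_flags_missing(self):
        mon = [_mon(0, 0.0, 0.0, "hotspot")]
        v = loo_idw_surface(np.array([[0.0, 0.0]]), mon, {"M0": 5.0}, "hotspot", 1,
                            exclude_ids=["M0"])
        assert np.isnan(v[0])

    def test_matches_brute_force_on_random_layouts(self, rng):
        for _ in range(100):
            n = rng.integers(2, 12)
            mon = [_mon(i, *rng.uniform(0, 50000, 2)) for i in range(n)]
            means = {m.id: float(rng.uniform(1, 60)) for m in mon}
            q = rng.uniform(0, 50000, 2)
            power = int(rng.integers(1, 3))
            got = loo_idw_surface(q[None, :], mon, means, "background", power)[0]
            exp = _brute_idw(q[0], q[1], mon, means, power)
            assert got == pytest.approx(exp, rel=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 100), power=st.sampled_from([1, 2]))
    def test_scale_equivariance(self, scale, power):
        mon = [_mon(0, 0.0, 0.0), _mon(1, 900.0, 400.0), _mon(2, 200.0, 700.0)]
        means = {"M0": 4.0, "M1": 11.0, "M2": 25.0}
        q = np.array([[500.0, 500.0]])
        base = loo_idw_surface(q, mon, means, "background", power)[0]
        scaled = loo_idw_surface(q, mon, {k: v * scale for k, v in means.items()},
                                 "background", power)[0]
        assert scaled == pytest.approx(base * scale, rel=1e-9)


class TestNearestDistance:
    def test_three_four_five(self):
        mon = [_mon(0, 0.0, 0.0, "hotspot"), _mon(1, 3000.0, 4000.0, "background")]
        d = nearest_monitor_distance(np.array([[0.0, 0.0]]), mon, "background")
        assert d[0] == pytest.approx(5000.0)

    def test_self_exclusion_gives_next_nearest(self):
        mon = [_mon(0, 0.0, 0.0), _mon(1, 700.0, 0.0), _mon(2, 5000.0, 0.0)]
        d = nearest_monitor_distance(np.array([[0.0, 0.0]]), mon, "background",
                                     exclude_ids=["M0"])
        assert d[0] == pytest.approx(700.0)

    def test_matches_brute_force(self, rng):
        for _ in range(100):
            n = rng.integers(1, 10)
            mon = [_mon(i, *rng.uniform(0, 10000, 2)) for i in range(n)]
            q = rng.uniform(0, 10000, 2)
            got = nearest_monitor_distance(q[None, :], mon, "background")[0]
            exp = min(np.hypot(q[0] - m.x, q[1] - m.y) for m in mon)
            assert got == pytest.approx(exp, rel=1e-12)

    def test_empty_monitor_set_errors(self):
        with pytest.raises(ValueError):
            nearest_monitor_distance(np.array([[0.0, 0.0]]), [], "hotspot")


class TestMeteorology:
    def test_saturation_gives_100(self):
        rh, _, _ = derive_meteorology(np.array([290.0]), np.array([290.0]),
                                      np.array([0.0]), np.array([0.0]))
        assert rh[0] == pytest.approx(100.0)

    def test_wind_speed_pythagoras(self):
        _, speed, _ = derive_meteorology(np.array([290.0]), np.array([285.0]),
                                         np.array([3.0]), np.array([4.0]))
        assert speed[0] == pytest.approx(5.0)

    def test_magnus_oracle(self):
        """20 °C with a 10 °C dewpoint: RH from an independent evaluation of
        the Magnus ratio (≈ 52.5 %)."""
        expected = 100.0 * (np.exp(17.625 * 10.0 / (243.04 + 10.0))
                            / np.exp(17.625 * 20.0 / (243.04 + 20.0)))
        rh, _, _ = derive_meteorology(np.array([293.15]), np.array([283.15]),
                                      np.array([0.0]), np.array([0.0]))
        assert rh[0] == pytest.approx(expected, rel=1e-12)
        assert rh[0] == pytest.approx(52.5, abs=0.1)

    @pytest.mark.parametrize("u,v,expected", [
        (0.0, -1.0, 0.0),     # air moving south => wind from the north
        (-1.0, 0.0, 90.0),    # easterly
        (0.0, 1.0, 180.0),    # southerly
        (1.0, 0.0, 270.0),    # westerly
    ])
    def test_wind_from_direction_convention(self, u, v, expected):
        _, _, wd = derive_meteorology(np.array([290.0]), np.array([285.0]),
                                      np.array([u]), np.array([v]))
        assert wd[0] == pytest.approx(expected)

    def test_superadiabatic_dewpoint_rejected(self):
        with pytest.raises(ValueError):
            derive_meteorology(np.array([280.0]), np.array([285.0]),
                               np.array([0.0]), np.array([0.0]))


class TestTemporalFeatures:
    def test_calendar_values(self):
        f = temporal_features(["2018-01-01", "2018-06-02", "2016-12-31"])
        assert f["yday"].tolist() == [1, 153, 366]  # leap-year 31 Dec = 366
        assert f.loc[1, "dow"] == 6 and f.loc[1, "weekend"] == 1  # a Saturday
        assert f.loc[0, "weekend"] == 0  # 2018-01-01 is a Monday
        assert f["month"].tolist() == [1, 6, 12]


class TestHarmonize:
    def setup_method(self):
        self.grid = GridDomain(0.0, 0.0, 1000.0, 4, 3)

    def _fine(self, values, cell=100.0):
        values = np.asarray(values, dtype=float)
        g = GridDomain(0.0, 0.0, cell, values.shape[1], values.shape[0])
        return RasterField(g, values)

    def test_constant_mean_stays_constant(self):
        src = self._fine(np.full((30, 40), 7.0))
        out = harmonize_to_grid(src, self.grid, "mean")
        np.testing.assert_allclose(out.values, 7.0)

    def test_urban_fraction_counting(self):
        vals = np.zeros((30, 40))
        vals[:4, :10] = 1.0  # 40 of the 100 subcells of cell (0,0) are class 1
        src = self._fine(vals)
        frac = harmonize_to_grid(src, self.grid, "fraction", classes=[1.0])
        assert frac[1.0].values[0, 0] == pytest.approx(0.4)

    def test_fraction_sums_to_one(self, rng):
        vals = rng.integers(0, 4, size=(30, 40)).astype(float)
        src = self._fine(vals)
        fracs = harmonize_to_grid(src, self.grid, "fraction")
        total = sum(f.values for f in fracs.values())
        np.testing.assert_allclose(total, 1.0)

    def test_constant_elevation_sd_zero(self):
        out = harmonize_to_grid(self._fine(np.full((30, 40), 120.0)), self.grid, "sd")
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_coarser_source_nearest_assignment(self):
        coarse = RasterField(GridDomain(0.0, 0.0, 2000.0, 2, 2),
                             np.array([[1.0, 2.0], [3.0, 4.0]]))
        out = harmonize_to_grid(coarse, self.grid, "mean")
        assert out.values[0, 0] == 1.0 and out.values[0, 3] == 2.0
        assert out.values[2, 0] == 3.0

    def test_disjoint_extents_error(self):
        src = RasterField(GridDomain(1e6, 1e6, 100.0, 10, 10), np.ones((10, 10)))
        with pytest.raises(ValueError, match="disjoint"):
            harmonize_to_grid(src, self.grid, "mean")


class TestRoadDensity:
    def setup_method(self):
        self.grid = GridDomain(0.0, 0.0, 1000.0, 3, 2)

    def test_segment_within_one_cell(self):
        dens = road_density([([(0.0, 500.0), (1000.0, 500.0)], "highway")], self.grid)
        v = dens["highway"].values
        assert v[0, 0] == pytest.approx(1000.0)
        assert v.sum() == pytest.approx(1000.0)

    def test_segment_split_600_400(self):
        dens = road_density([([(400.0, 500.0), (1400.0, 500.0)], "local")], self.grid)
        v = dens["local"].values
        assert v[0, 0] == pytest.approx(600.0)
        assert v[0, 1] == pytest.approx(400.0)

    def test_total_length_conserved(self, rng):
        segs = []
        for k in range(5):
            pts = rng.uniform([0, 0], [3000, 2000], size=(3, 2))
            segs.append(([tuple(p) for p in pts], "secondary"))
        dens = road_density(segs, self.grid)
        total = sum(np.hypot(*(np.diff(np.array(c), axis=0).T)).sum()
                    for c, _ in segs)
        assert dens["secondary"].values.sum() == pytest.approx(total, rel=1e-9)


class TestAssembleFeatureTable:
    def test_join_and_missing_flags(self):
        grid = GridDomain(0.0, 0.0, 1000.0, 3, 3)
        dates = pd.date_range("2018-01-01", periods=3)
        static = {"ELEV": RasterField(grid, np.arange(9.0).reshape(3, 3))}
        vals = np.arange(27.0).reshape(3, 3, 3)
        daily = {"T2M": RasterField(grid, vals, dates=dates)}
        units = pd.DataFrame({
            "monitor_id": ["A", "A", "B"],
            "x": [500.0, 500.0, 2500.0],
            "y": [500.0, 500.0, 2500.0],
            "date": [dates[0], pd.Timestamp("2019-06-01"), dates[2]],
        })
        out = assemble_feature_table(units, static, daily)
        assert len(out) == 3
        assert out.loc[0, "ELEV"] == 0.0 and out.loc[2, "ELEV"] == 8.0
        assert out.loc[0, "T2M"] == vals[0, 0, 0]
        assert np.isnan(out.loc[1, "T2M"])  # outside coverage -> explicit NaN
        assert {"yday", "dow", "month", "weekend"} <= set(out.columns)

    def test_row_count_is_monitors_times_days(self, tiny_world):
        from airstack.synth import ObsParams, sample_monitor_observations
        obs = sample_monitor_observations(
            tiny_world, ObsParams(missing_fraction=0.0))
        no2 = obs[obs["pollutant"] == "NO2"]
        assert len(no2) == len(tiny_world.monitors) * len(tiny_world.dates)
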