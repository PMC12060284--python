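"""Synthetic environment: seasonal diffusivity structure, wind
statistics, dissolved-gas equilibria and the tracer simulator."""

import numpy as np
import pytest

from seepfate import environment as env
from seepfate.kinetics import predict_activity
from conftest import TRUE_PARAMS


@pytest.fixture(scope="module")
def grids():
    depth = np.arange(65) + 0.5
    time = np.arange(365, dtype=float)
    return depth, time


class TestSeasonalDiffusivity:
    def test_winter_column_near_uniform(self, grids):
        depth, time = grids
        K = env.make_seasonal_diffusivity(depth, time)
        jan = K[:, 15]
        assert jan.max() / jan.min() < 1.10

    def test_summer_minimum_in_interior(self, grids):
        depth, time = grids
        K = env.make_seasonal_diffusivity(depth, time)
        jul = K[:, 195]
        imin = np.argmin(jul)
        assert 0 < imin < len(depth) - 1
        assert jul[imin] < 0.1 * jul[0]          # pycnocline suppresses mixing

    def test_ceiling_respected(self, grids):
        depth, time = grids
        cfg = env.DiffusivityConfig(winter_K=5.0, ceiling=0.2)
        K = env.make_seasonal_diffusivity(depth, time, cfg)
        assert K.max() <= 0.2
        assert K.min() >= 0.0

    def test_bad_inputs_rejected(self, grids):
        depth, time = grids
        with pytest.raises(ValueError):
            env.make_seasonal_diffusivity(depth[::-1], time)
        with pytest.raises(ValueError):
            env.make_seasonal_diffusivity(
                depth, time, env.DiffusivityConfig(interior_K=-1.0))


class TestWind:
    def test_mean_calibration(self):
        t = np.arange(365)
        u = env.make_wind_series(t, seed=3, config=env.WindConfig(mean=8.0))
        se = 3.0 / np.sqrt(365)  # generous: ignores autocorrelation inflation
        assert abs(u.mean() - 8.0) < 3 * se * 3
        assert u.min() >= 0.0

    def test_deterministic_for_fixed_seed(self):
        t = np.arange(365)
        a = env.make_wind_series(t, seed=7)
        b = env.make_wind_series(t, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_zero_variability_constant(self):
        t = np.arange(100)
        u = env.make_wind_series(t, seed=0, config=env.WindConfig(mean=5.0, std=0.0))
        np.testing.assert_array_equal(u, np.full(100, 5.0))

    def test_negative_config_rejected(self):
        with pytest.raises(ValueError):
            env.make_wind_series(np.arange(10), 0, env.WindConfig(mean=-1.0))


class TestEquilibriumGases:
    def test_oxygen_near_measured_shelf_value(self):
        eq = env.equilibrium_dissolved_gases(7.0, 34.0)
        o2_mg_per_l = float(eq["O2"]) * 1000.0
        assert o2_mg_per_l == pytest.approx(8.0, rel=0.20)

    def test_solubility_retrograde_in_temperature(self):
        cold = env.equilibrium_dissolved_gases(5.0, 34.0)
        warm = env.equilibrium_dissolved_gases(20.0, 34.0)
        assert warm["O2"] < cold["O2"]
        assert warm["N2"] < cold["N2"]

    def test_dissolved_ratio_below_atmospheric(self):
        # O2 is more soluble than N2, so the water is O2-enriched
        eq = env.equilibrium_dissolved_gases(7.0, 34.0)
        molar_ratio = (eq["N2"] / 28.014e-3) / (eq["O2"] / 31.999e-3)
        assert molar_ratio < 0.7808 / 0.2095


class TestScenario:
    def test_invariants_and_volume(self, grids):
        scenario = env.make_scenario(env.station_preset(65), seed=1)
        scenario.validate()
        assert np.sum(np.diff(scenario.cell_edges)) == pytest.approx(65.0)
        assert scenario.cell_edges[-1] == 65.0

    def test_deterministic(self):
        a = env.make_scenario(env.station_preset(65), seed=5)
        b = env.make_scenario(env.station_preset(65), seed=5)
        np.testing.assert_array_equal(a.K, b.K)
        np.testing.assert_array_equal(a.U10, b.U10)

    def test_netcdf_round_trip(self, shelf_scenario, tmp_path):
        path = tmp_path / "env.nc"
        shelf_scenario.to_netcdf(path)
        back = env.EnvironmentScenario.from_netcdf(path)
        np.testing.assert_allclose(back.K, shelf_scenario.K)
        np.testing.assert_allclose(back.U10, shelf_scenario.U10)
        assert back.station_depth == shelf_scenario.station_depth

    def test_deep_station_never_homogeneous(self):
        deep = env.make_scenario(env.station_preset(303), seed=1)
        # interior stays weakly mixed even in winter
        jan = deep.K[:, 15]
        assert jan[-10:].max() < 0.1 * jan[:20].mean()


class TestTracerSimulator:
    def test_noise_free_lies_on_curve(self, tracer_noise_free):
        frame = tracer_noise_free.frame
        test = frame[frame["kind"] == "test"]
        expect = predict_activity(TRUE_PARAMS, test["day"].to_numpy(),
                                  test["temperature_C"].to_numpy())
        sup = np.max(np.abs(test["activity_normalized"].to_numpy() - expect))
        assert sup < 1e-12 * TRUE_PARAMS.Ctot
        controls = frame[frame["kind"] == "control"]["activity_normalized"]
        assert np.allclose(controls, TRUE_PARAMS.Cb)

    def test_warm_flasks_closer_to_asymptote(self, tracer_noise_free):
        frame = tracer_noise_free.frame
        test = frame[frame["kind"] == "test"]
        for day in (2.0, 13.0, 27.0):
            cold = test[(test["day"] == day) & (test["temperature_C"] == 5.0)]
            warm = test[(test["day"] == day) & (test["temperature_C"] == 8.5)]
            assert warm["activity_normalized"].iloc[0] > cold["activity_normalized"].iloc[0]

    def test_deterministic_and_csv_round_trip(self, tmp_path):
        a = env.simulate_tracer_experiment(seed=9)
        b = env.simulate_tracer_experiment(seed=9)
        assert a.frame.equals(b.frame)
        path = tmp_path / "tracer.csv"
        a.to_csv(path)
        from seepfate.kinetics import TracerDataset
        back = TracerDataset.from_csv(path)
        np.testing.assert_allclose(back.activities, a.activities)

    def test_background_normalisation(self):
        ds = env.simulate_tracer_experiment(seed=3)
        scaled = ds.frame.copy()
        scaled["activity_normalized"] *= 250.0   # raw counts
        from seepfate.kinetics import TracerDataset
        renorm = TracerDataset(scaled).normalized_by_background()
        ctl = renorm.frame[renorm.frame["kind"] == "control"]["activity_normalized"]
        assert ctl.mean() == pytest.approx(1.0)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            env.simulate_tracer_experiment(
                env.TracerExperimentDesign(replicates=0), seed=0)
        with pytest.raises(ValueError):
            env.simulate_tracer_experiment(
                env.TracerExperimentDesign(sampling_days=(-1.0,)), seed=0)
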