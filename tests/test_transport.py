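"""Diffusion-reaction solver: wind parametrization, conservation,
accuracy orders and seasonal fate runs."""

import numpy as np
import pytest

from seepfate import transport as tr


class TestWindParametrization:
    def test_zero_wind_zero_transfer(self):
        assert tr.kw_from_wind(0.0) == 0.0

    def test_quadratic_scaling(self):
        assert tr.kw_from_wind(8.0) / tr.kw_from_wind(4.0) == pytest.approx(4.0)

    def test_hand_evaluation(self):
        # direct arithmetic of the parametrization as printed
        expected = 6.97e-7 * 10.0**2 * (677.0 / 660.0) ** -0.5
        assert tr.kw_from_wind(10.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_wind_rejected(self):
        with pytest.raises(ValueError):
            tr.kw_from_wind(-1.0)


@pytest.fixture(scope="module")
def column65():
    grid = tr.Grid1D.uniform(65.0)
    solver = tr.CrankNicolsonSolver(grid)
    K = 0.05 * np.exp(-((grid.centers - 30.0) / 20.0) ** 2) + 1e-4
    return grid, solver, solver.faces_from_centers(K)


class TestStep:
    def test_closed_column_conserves_mass(self, column65):
        grid, solver, Kf = column65
        C = np.exp(-((grid.centers - 50.0) / 5.0) ** 2)
        m0 = np.dot(C, grid.dz)
        for _ in range(2000):
            C, b, v = solver.step(C, Kf, 0.01, 0.0, 0.0)
            assert b == 0.0 and v == 0.0
        assert abs(np.dot(C, grid.dz) - m0) / m0 < 1e-11

    def test_analytic_decay(self, column65):
        grid, _, _ = column65
        solver = tr.CrankNicolsonSolver(grid, enforce_nonnegative=False)
        Kf0 = solver.faces_from_centers(np.zeros(grid.n))
        C = np.ones(grid.n)
        t12 = 10.0
        k1 = np.log(2.0) / t12
        for _ in range(100):
            C, _, _ = solver.step(C, Kf0, t12 / 100.0, k1, 0.0)
        assert abs(np.dot(C, grid.dz) / 65.0 - np.exp(-k1 * t12)) < 1e-10

    def test_surface_flux_three_cell_budget(self):
        grid = tr.Grid1D(np.array([0.0, 1.0, 2.0, 3.0]))
        solver = tr.CrankNicolsonSolver(grid)
        Kf = np.zeros(4)               # no diffusion: only the surface cell acts
        kw = 1e-5
        C0 = np.ones(3)
        dt = 1e-3
        C1, b, v = solver.step(C0, Kf, dt, 0.0, kw)
        assert C1[0] < C0[0]
        np.testing.assert_array_equal(C1[1:], C0[1:])
        assert v == pytest.approx(kw * tr.SECONDS_PER_DAY * dt, rel=1e-2)
        # exact discrete closure
        assert np.dot(C1, grid.dz) + v + b == pytest.approx(np.dot(C0, grid.dz),
                                                            abs=1e-15)

    def test_full_closure_with_all_terms(self, column65):
        grid, solver, Kf = column65
        C = np.exp(-((grid.centers - 50.0) / 5.0) ** 2)
        m0 = np.dot(C, grid.dz)
        b_tot = v_tot = 0.0
        for _ in range(500):
            C, b, v = solver.step(C, Kf, 0.01, 0.05, 3e-5)
            b_tot += b
            v_tot += v
        assert abs(np.dot(C, grid.dz) + b_tot + v_tot - m0) / m0 < 1e-11
        assert C.min() >= 0.0

    def test_invalid_inputs(self, column65):
        grid, solver, Kf = column65
        C = np.ones(grid.n)
        with pytest.raises(ValueError):
            solver.step(C, Kf, -0.01, 0.0, 0.0)
        with pytest.raises(ValueError):
            solver.step(C, Kf, 0.01, -1.0, 0.0)


@pytest.fixture(scope="module")
def report():
    return tr.convergence_order()


class TestConvergence:

    def test_second_order_in_space(self, report):
        assert report.space_order == pytest.approx(2.0, abs=0.1)

    def test_second_order_in_time(self, report):
        assert report.time_order == pytest.approx(2.0, abs=0.1)

    def test_errors_monotone(self, report):
        assert report.monotone

    def test_first_order_scheme_detected(self):
        rep = tr.convergence_order(theta=1.0)
        assert rep.time_order == pytest.approx(1.0, abs=0.2)

    def test_decay_only_exact(self, column65):
        grid, _, _ = column65
        solver = tr.CrankNicolsonSolver(grid, enforce_nonnegative=False)
        Kf0 = solver.faces_from_centers(np.zeros(grid.n))
        k1 = 0.1
        errs = []
        for dt in (0.2, 0.1):
            C = np.ones(grid.n)
            for _ in range(int(round(2.0 / dt))):
                C, _, _ = solver.step(C, Kf0, dt, k1, 0.0)
            errs.append(abs(C[0] - np.exp(-k1 * 2.0)))
        assert max(errs) < 1e-12      # decay handled exactly, any step size


class TestRunUntilDepleted:
    def test_winter_release_mostly_ventilated(self, shelf_scenario, bubble_65):
        dep = bubble_65.deposition.regrid(shelf_scenario.cell_edges)
        k1 = np.log(2.0) / 50.0
        mb = tr.run_until_depleted(dep, shelf_scenario, k1, start_day=0.0)
        term = mb.terminal
        assert term["ventilated"] > term["biodegraded"]
        assert abs(sum(term.values()) - 1.0) < 1e-9

    def test_summer_release_biodegrades_more(self, shelf_scenario, bubble_65):
        dep = bubble_65.deposition.regrid(shelf_scenario.cell_edges)
        k1 = np.log(2.0) / 50.0
        jan = tr.run_until_depleted(dep, shelf_scenario, k1, start_day=0.0)
        jul = tr.run_until_depleted(dep, shelf_scenario, k1, start_day=181.0)
        assert jul.terminal["biodegraded"] > jan.terminal["biodegraded"]

    def test_closed_surface(self, mixed_box_scenario, uniform_box_deposition):
        mb = tr.run_until_depleted(uniform_box_deposition, mixed_box_scenario,
                                   k1=np.log(2.0) / 5.0, kw_override=0.0)
        term = mb.terminal
        assert term["ventilated"] == 0.0
        assert abs(sum(term.values()) - 1.0) < 1e-9

    def test_balance_series_invariants(self, shelf_scenario, bubble_65):
        dep = bubble_65.deposition.regrid(shelf_scenario.cell_edges)
        mb = tr.run_until_depleted(dep, shelf_scenario, np.log(2.0) / 30.0,
                                   start_day=300.0)   # wraps past new year
        total = mb.dissolved + mb.biodegraded + mb.ventilated + mb.bubble
        assert np.max(np.abs(total - 1.0)) < 1e-9
        assert np.all(np.diff(mb.biodegraded) >= -1e-12)
        assert np.all(np.diff(mb.ventilated) >= -1e-12)
        assert mb.dissolved[-1] < 1e-7

    def test_concentration_history_netcdf(self, mixed_box_scenario,
                                          uniform_box_deposition, tmp_path):
        mb = tr.run_until_depleted(uniform_box_deposition, mixed_box_scenario,
                                   k1=np.log(2.0) / 2.0,
                                   store_concentration=True)
        path = tmp_path / "conc.nc"
        mb.concentration_to_netcdf(path)
        import xarray as xr
        with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
            assert ds["C"].dims == ("depth", "time")
            assert ds["C"].shape[0] == mixed_box_scenario.K.shape[0]

    def test_non_termination_reported(self, mixed_box_scenario,
                                      uniform_box_deposition):
        with pytest.raises(tr.NonTerminationError) as err:
            tr.run_until_depleted(uniform_box_deposition, mixed_box_scenario,
                                  k1=0.0, kw_override=0.0, max_days=5.0)
        assert err.value.remaining > 0.99


class TestContainers:
    def test_grid_validation(self):
        with pytest.raises(ValueError):
            tr.Grid1D(np.array([1.0, 2.0]))       # must start at the surface
        with pytest.raises(ValueError):
            tr.Grid1D(np.array([0.0, 2.0, 1.0]))

    def test_mass_balance_closure_enforced(self):
        t = np.array([0.0, 1.0])
        with pytest.raises(ValueError):
            tr.MassBalanceSeries(time=t, dissolved=np.array([0.5, 0.4]),
                                 biodegraded=np.array([0.0, 0.05]),
                                 ventilated=np.array([0.0, 0.01]),
                                 bubble=0.5)
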