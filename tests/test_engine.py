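"""Iteration engine: initialization, stepping, symmetry, steady state, guards."""

import dataclasses

import numpy as np
import pytest

import coinvade as cv
from conftest import small_config
from coinvade.params import ParameterError


class TestInitialize:
    def test_default_introduction_is_one_center_cell(self):
        cfg = small_config()
        f = cv.initialize(cfg)
        c = f.landscape.center_index
        for name in ("P", "F1", "F2"):
            d = f.density(name)
            assert d[c] == 0.1
            assert np.count_nonzero(d) == 1

    def test_mutualist_absent_leaves_P_empty(self):
        f = cv.initialize(small_config(mutualist_present=False))
        assert np.all(f.P == 0)
        assert np.count_nonzero(f.F1) == 1

    def test_competitors_absent_leaves_only_P(self):
        f = cv.initialize(small_config(competitors_present=False))
        assert np.count_nonzero(f.P) == 1
        assert np.all(f.F1 == 0) and np.all(f.F2 == 0)

    def test_initial_mass_matches_definition(self):
        cfg = small_config(init_width_cells=5)
        f = cv.initialize(cfg)
        dx = f.landscape.dx
        assert f.F1.sum() * dx == pytest.approx(0.1 * 5 * dx)

    def test_introduction_wider_than_grid_rejected(self):
        with pytest.raises(ParameterError):
            cv.initialize(small_config(init_width_cells=10**6))


class TestStep:
    def test_all_zero_field_stays_zero(self):
        cfg = small_config()
        f = cv.initialize(cfg)
        for name in ("P", "F1", "F2"):
            f.density(name)[:] = 0.0
        out = cv.step(f, cfg.growth, cv.build_kernels(cfg))
        assert all(np.all(out.density(n) == 0) for n in ("P", "F1", "F2"))

    def test_uniform_equilibrium_interior_is_fixed_point(self):
        # uniform P at carrying capacity: growth is stationary and the
        # normalized kernel preserves constants away from the boundary
        cfg = small_config()
        f = cv.initialize(cfg)
        f.P[:] = 3.0
        f.F1[:] = 0.0
        f.F2[:] = 0.0
        kernels = cv.build_kernels(cfg)
        out = cv.step(f, cfg.growth, kernels)
        h = kernels["P"].half_width
        assert np.allclose(out.P[h:-h], 3.0, atol=1e-6)

    def test_symmetry_preserved(self):
        cfg = small_config(tau_12=0.2, tau_21=0.1)
        f = cv.initialize(cfg)
        kernels = cv.build_kernels(cfg)
        for _ in range(3):
            f = cv.step(f, cfg.growth, kernels)
        for name in ("P", "F1", "F2"):
            d = f.density(name)
            assert np.allclose(d, d[::-1], atol=1e-12)

    def test_step_increments_iteration(self):
        cfg = small_config()
        f = cv.initialize(cfg)
        assert cv.step(f, cfg.growth, cv.build_kernels(cfg)).iteration == 1


class TestRun:
    def test_windowed_run_matches_full_grid_stepping(self):
        cfg = small_config(tau_12=0.1, tau_21=0.05, n_iterations=15)
        res = cv.run(cfg)
        f = cv.initialize(cfg)
        kernels = cv.build_kernels(cfg)
        for _ in range(15):
            f = cv.step(f, cfg.growth, kernels)
        for name in ("P", "F1", "F2"):
            assert np.allclose(res.final.density(name), f.density(name),
                               atol=1e-12)

    def test_reruns_are_bit_identical(self):
        cfg = small_config(tau_12=0.15, tau_21=0.1, n_iterations=25)
        a, b = cv.run(cfg), cv.run(cfg)
        for name in ("P", "F1", "F2"):
            assert np.array_equal(a.final.density(name), b.final.density(name))
        assert np.array_equal(a.edges, b.edges, equal_nan=True)

    def test_mirror_symmetry_throughout(self):
        res = cv.run(small_config(tau_12=0.2, tau_21=0.15, n_iterations=30))
        for name in ("P", "F1", "F2"):
            d = res.final.density(name)
            assert np.allclose(d, d[::-1], atol=1e-10)
        assert np.allclose(res.edges[:, :, 0], -res.edges[:, :, 1],
                           equal_nan=True)

    def test_edges_are_nan_while_unoccupied(self):
        res = cv.run(small_config(mutualist_present=False, n_iterations=5))
        assert np.all(np.isnan(res.edges[:, 0, :]))  # P never present

    def test_boundary_clearance_guard_trips(self):
        cfg = small_config(n_iterations=10**4)  # tiny fixed domain, long run
        with pytest.raises(cv.BoundaryContactError):
            cv.run(cfg)

    def test_early_stop_truncates_trajectory(self):
        # auto-sized landscape: the small fixed test domain cannot clear
        # 300 iterations of spread
        cfg = cv.make_config(n_iterations=300, early_stop=True,
                             competitors_present=False)
        res = cv.run(cfg)
        assert res.steady_state_reached
        assert res.n_iterations_run == res.steady_state_iteration < 300

    def test_edge_and_snapshot_tables_roundtrip(self, tmp_path):
        cfg = small_config(n_iterations=8, snapshot_stride=4)
        res = cv.run(cfg)
        et = res.edge_table()
        assert set(et.columns) == {"iteration", "species", "left_edge",
                                   "right_edge", "mass"}
        assert len(et) == 9 * 3
        st = res.snapshot_table()
        assert set(st.columns) == {"iteration", "x", "P", "F1", "F2"}
        assert sorted(st["iteration"].unique()) == [0, 4, 8]
        p = tmp_path / "snap.csv"
        st.to_csv(p, index=False)
        assert p.exists()


class TestDetectSteadyState:
    def _series(self, disp, center):
        n = len(disp) + 1
        edges = np.full((n, 3, 2), np.nan)
        edges[:, :, 1] = np.concatenate([[0.0], np.cumsum(disp)])[:, None]
        edges[:, :, 0] = -edges[:, :, 1]
        dens = np.full((n, 3), center)
        return edges, dens

    def test_constant_speed_and_core_density_is_steady(self):
        edges, dens = self._series([0.2] * 60, 3.0)
        ok, it = cv.detect_steady_state(edges, dens, window=50,
                                        speed_tol=0.01, density_tol=1e-6)
        assert ok and it == 60

    def test_accelerating_front_is_not_steady(self):
        edges, dens = self._series(np.linspace(0.05, 0.4, 60), 3.0)
        ok, it = cv.detect_steady_state(edges, dens, window=50,
                                        speed_tol=0.01, density_tol=1e-6)
        assert not ok and it is None

    def test_single_species_run_settles_before_300(
            self, single_species_P_run):
        res = single_species_P_run
        dx = res.landscape.dx
        ok, _ = cv.detect_steady_state(res.edges, res.center_density,
                                       window=50, speed_tol=dx,
                                       density_tol=1e-6)
        assert ok
        assert res.steady_state_reached


class TestConfigIO:
    def test_flat_config_roundtrip(self, tmp_path):
        cfg = small_config(tau_12=0.2, tau_21=0.15, sigma2_P=0.075,
                           tradeoff_enabled=True)
        path = tmp_path / "run.cfg"
        cv.save_config(cfg, path)
        back = cv.load_config(path)
        assert back.growth == cfg.growth
        assert back.dispersal == cfg.dispersal
        assert back.landscape == cfg.landscape

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("tau_99: 0.1\n")
        with pytest.raises(ParameterError):
            cv.load_config(path)

    def test_tradeoff_shrinks_low_dependence_kernel(self):
        d = cv.DispersalParams(sigma2_F1=0.05, sigma2_F2=0.05,
                               tradeoff_enabled=True,
                               delta_F1=0.9, delta_F2=0.1)
        _, s1, s2 = d.effective_variances()
        assert s1 == pytest.approx(0.045)
        assert s2 == pytest.approx(0.005)
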