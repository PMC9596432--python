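"""Langevin rigid-body integrator: forces, schedule, conservation laws."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piliagg import dynamics as dyn
from piliagg._kernels import seed_rng_state
from piliagg.geometry import PairPotentialParams


def tiny_config(**kw):
    defaults = dict(n_cells=2, box_lengths=(80.0, 80.0, 80.0), seed=0)
    defaults.update(kw)
    return dyn.desk_config(**defaults)


class TestMinimumImage:
    def test_wraps_across_boundary(self):
        assert np.allclose(dyn.minimum_image([499.0, 0, 0], [500.0] * 3), [-1, 0, 0])

    def test_boundary_convention_is_half_open(self):
        # components map into (-L/2, L/2]: both +250 and -250 land on +250
        out = dyn.minimum_image([250.0, -250.0, 0.0], [500.0] * 3)
        assert np.allclose(out, [250.0, 250.0, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=3))
    def test_never_longer_than_input(self, d):
        out = dyn.minimum_image(d, [500.0, 300.0, 200.0])
        assert np.linalg.norm(out) <= np.linalg.norm(d) + 1e-9
        assert np.all(out > -np.array([250.0, 150.0, 100.0]) - 1e-9)
        assert np.all(out <= np.array([250.0, 150.0, 100.0]) + 1e-9)


class TestInitialization:
    def test_bodies_do_not_overlap(self, dispersed_template, params):
        cfg = tiny_config(seed=11)
        st_ = dyn.initialize_system(cfg, dispersed_template, params)
        d = dyn.minimum_image(st_.positions[0] - st_.positions[1], cfg.box)
        assert np.linalg.norm(d) >= 2 * params.sigma_B

    def test_same_seed_bit_identical(self, dispersed_template, params):
        cfg = tiny_config(seed=7)
        a = dyn.initialize_system(cfg, dispersed_template, params)
        b = dyn.initialize_system(cfg, dispersed_template, params)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.quaternions, b.quaternions)
        assert np.array_equal(a.velocities, b.velocities)

    def test_overpacked_box_raises(self, dispersed_template, params):
        cfg = dyn.desk_config(n_cells=64, box_lengths=(30.0, 30.0, 30.0), seed=0)
        with pytest.raises(dyn.InfeasibleDensityError):
            dyn.initialize_system(cfg, dispersed_template, params,
                                  max_attempts_per_cell=200)


class TestForces:
    def test_distant_cells_feel_nothing(self, dispersed_template, params):
        cfg = tiny_config()
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=1)
        st_.positions[:] = [[10.0, 10, 10], [50.0, 50, 50]]
        F, T, U = dyn.compute_forces(st_, dispersed_template, params)
        assert np.allclose(F, 0) and np.allclose(T, 0) and U == 0.0

    def test_neighbor_list_matches_all_pairs_oracle(self, dispersed_template, params):
        # 32 random cells, dense enough for many contacts
        cfg = dyn.desk_config(n_cells=32, box_lengths=(60.0, 60.0, 60.0), seed=3)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=3)
        F1, T1, U1 = dyn.compute_forces(st_, dispersed_template, params, method="neighbor")
        F2, T2, U2 = dyn.compute_forces(st_, dispersed_template, params, method="all_pairs")
        assert np.abs(F1 - F2).max() < 1e-10
        assert np.abs(T1 - T2).max() < 1e-10
        assert U1 == pytest.approx(U2, abs=1e-10)

    def test_total_force_is_zero(self, dispersed_template, params):
        cfg = dyn.desk_config(n_cells=16, box_lengths=(50.0, 50.0, 50.0), seed=5)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=5)
        F, _, _ = dyn.compute_forces(st_, dispersed_template, params)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-11)


class TestIntegrator:
    def test_cold_still_system_is_fixed_point(self, dispersed_template, params):
        cfg = tiny_config(kBT=0.0, thermostat=False)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=2)
        st_.positions[:] = [[10.0, 10, 10], [60.0, 60, 60]]
        st_.velocities[:] = 0.0
        st_.ang_velocities[:] = 0.0
        q0 = st_.quaternions.copy()
        out = dyn.advance(st_, cfg, dispersed_template, params, 100, seed_rng_state(0))[0]
        assert np.array_equal(out.positions, st_.positions)
        assert np.array_equal(out.quaternions, q0)

    def test_speed_decays_exponentially_at_zero_temperature(self, dispersed_template, params):
        cfg = tiny_config(n_cells=1, kBT=0.0)
        _, _, gamma_t, _ = dyn.rigid_body_coefficients(dispersed_template, params)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=2)
        st_.velocities[:] = [[0.4, 0.0, 0.0]]
        st_.ang_velocities[:] = 0.0
        n = 200
        out = dyn.advance(st_, cfg, dispersed_template, params, n, seed_rng_state(0))[0]
        expected = 0.4 * np.exp(-gamma_t * n * cfg.dt)
        assert out.velocities[0, 0] == pytest.approx(expected, rel=1e-9)

    def test_rigid_geometry_preserved_over_many_steps(self, dispersed_template, params):
        cfg = dyn.desk_config(n_cells=4, box_lengths=(40.0, 40.0, 40.0), seed=9)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=9)
        out = dyn.advance(st_, cfg, dispersed_template, params, 10_000, seed_rng_state(9))[0]
        assert np.allclose(np.linalg.norm(out.quaternions, axis=1), 1.0, atol=1e-9)
        arms = out.adhesin_world_coords(dispersed_template) - out.positions[:, None, :]
        assert np.allclose(np.linalg.norm(arms, axis=-1), 6.0, atol=1e-9)

    def test_momentum_conserved_without_thermostat(self, dispersed_template, params):
        cfg = dyn.desk_config(n_cells=8, box_lengths=(40.0, 40.0, 40.0),
                              thermostat=False, seed=4)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=4)
        p0 = st_.velocities.sum(axis=0)
        out = dyn.advance(st_, cfg, dispersed_template, params, 2_000, seed_rng_state(4))[0]
        assert np.allclose(out.velocities.sum(axis=0), p0, atol=1e-9)

    def test_identical_seed_gives_identical_trajectory(self, dispersed_template, params):
        cfg = tiny_config(seed=6)
        runs = []
        for _ in range(2):
            st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=6)
            out = dyn.advance(st_, cfg, dispersed_template, params, 500, seed_rng_state(6))[0]
            runs.append(out)
        assert np.array_equal(runs[0].positions, runs[1].positions)
        assert np.array_equal(runs[0].quaternions, runs[1].quaternions)


class TestPhases:
    def test_record_phase_snapshot_count(self, dispersed_template, params):
        cfg = tiny_config(t_record_window=50.0, record_interval=10.0)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=0)
        traj = dyn.run_phase(st_, cfg, dispersed_template, params, "record", seed_rng_state(0))
        assert len(traj) == 5  # window / interval
        assert np.all(np.diff(traj.times) > 0)

    def test_compression_confines_cells_between_plates(self, dispersed_template, params):
        # short compression at scaled schedule; bodies end inside the gap
        cfg = dyn.desk_config(n_cells=8, box_lengths=(60.0, 60.0, 60.0),
                              t_compress=2.0e3, plate_final_gap=20.0, seed=8)
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=8)
        traj = dyn.run_phase(st_, cfg, dispersed_template, params, "compress", seed_rng_state(8))
        final = traj.states[-1]
        zlo, zhi = final.plates
        assert zhi - zlo == pytest.approx(20.0)
        z = final.positions[:, 2]
        sigB = params.sigma_B
        assert np.all(z > zlo + sigB - 1.5) and np.all(z < zhi - sigB + 1.5)

    def test_unknown_phase_rejected(self, dispersed_template, params):
        cfg = tiny_config()
        st_ = dyn.initialize_system(cfg, dispersed_template, params, seed=0)
        with pytest.raises(ValueError):
            dyn.run_phase(st_, cfg, dispersed_template, params, "melt", seed_rng_state(0))


class TestConfig:
    def test_record_interval_must_divide_window(self):
        with pytest.raises(ValueError):
            dyn.desk_config(t_record_window=100.0, record_interval=33.0)

    def test_full_scale_preset_pins_reference_schedule(self):
        cfg = dyn.full_config()
        assert cfg.n_cells == 512
        assert cfg.box_lengths == (500.0, 500.0, 500.0)
        assert cfg.dt == pytest.approx(0.05)
        assert cfg.t_equilibrate == pytest.approx(8.0e8)
        assert cfg.n_snapshots == 300
        assert cfg.t_compress == pytest.approx(2.0e7)
        assert cfg.plate_final_gap == pytest.approx(50.0)
        assert cfg.n_replicates == 5
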