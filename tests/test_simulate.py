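"""Simulator physics: closed forms, conservation laws and thermostat."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist

from glycoflow.simulate import (Simulator, berendsen_scale, build_system,
                                count_ions, desk_config,
                                instantaneous_temperature, integrate_step,
                                run_simulation)
from glycoflow.units import KB, KCAL_PER_MOL_TO_AMU_A2_PS2 as ACC


class TestCountIons:
    @pytest.mark.parametrize("n, m, expected", [
        (6133, 0.15, 17),  # the reference composition
        (6133, 0.0, 0),
        (1000, 0.15, 3),  # round(1000*0.15/55.5)
    ])
    def test_water_molarity_convention(self, n, m, expected):
        assert count_ions(n, m) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            count_ions(-1, 0.15)
        with pytest.raises(ValueError):
            count_ions(100, -0.1)


class TestInstantaneousTemperature:
    def test_zero_velocities_give_zero_kelvin(self):
        assert instantaneous_temperature(np.zeros((5, 3)), np.full(5, 18.0)) == 0.0

    def test_single_particle_closed_form(self):
        # m v^2 = 3 k_B T  =>  T = 300 K
        m = 18.0
        speed = np.sqrt(3 * KB * 300.0 * ACC / m)
        v = np.array([[speed, 0.0, 0.0]])
        assert instantaneous_temperature(v, np.array([m])) == pytest.approx(300.0)

    def test_maxwell_boltzmann_sample(self):
        rng = np.random.default_rng(0)
        n, m = 20_000, 18.0
        v = rng.normal(scale=np.sqrt(ACC * KB * 300.0 / m), size=(n, 3))
        t = instantaneous_temperature(v, np.full(n, m))
        # relative sampling error ~ sqrt(2/(3n))
        assert t == pytest.approx(300.0, rel=4 * np.sqrt(2 / (3 * n)))

    def test_zero_dof_is_an_error(self):
        with pytest.raises(ValueError, match="degrees of freedom"):
            instantaneous_temperature(np.ones((1, 3)), np.ones(1), n_constraints=3)


class TestBerendsenScale:
    def test_at_target_no_rescale(self):
        assert berendsen_scale(300.0, 300.0, 0.002, 0.2) == 1.0

    def test_closed_form_sqrt2(self):
        # dt = tau and T = T0/2: lambda = sqrt(1 + (2 - 1)) = sqrt(2)
        assert berendsen_scale(150.0, 300.0, 0.2, 0.2) == pytest.approx(np.sqrt(2))

    def test_decoupling_limit(self):
        assert berendsen_scale(150.0, 300.0, 0.002, 1e12) == pytest.approx(1.0)

    def test_zero_temperature_rejected(self):
        with pytest.raises(ValueError):
            berendsen_scale(0.0, 300.0, 0.002, 0.2)

    @given(st.floats(10.0, 3000.0), st.floats(0.01, 10.0))
    def test_rescale_preserves_direction(self, t_inst, tau):
        """lambda > 0 for any physical T and tau: signs never flip."""
        lam = berendsen_scale(t_inst, 300.0, 0.002, tau)
        assert lam > 0
        v = np.array([1.0, -2.0, 3.0])
        assert np.all(np.sign(v * lam) == np.sign(v))


class TestBuildSystem:
    def test_solute_only(self, topology):
        cfg = desk_config(n_solvent=0, molarity=0.0)
        state = build_system(cfg, topology)
        assert state.n_atoms == topology.n_atoms
        assert set(state.kinds) == {"solute"}

    def test_reference_composition_counts(self, topology):
        cfg = desk_config(box=(62.0, 66.0, 61.0), n_solvent=6133,
                          molarity=0.15, cutoff=12.0)
        state = build_system(cfg, topology)
        non_solute = state.n_atoms - topology.n_atoms
        assert non_solute == 6133 + 17 + 17
        assert int((state.kinds == "cation").sum()) == 17
        assert int((state.kinds == "anion").sum()) == 17

    def test_minimum_separation_brute_force(self, topology):
        """O(N^2) scan: no bead pair closer than the overlap threshold."""
        cfg = desk_config(n_solvent=300, seed=7)
        state = build_system(cfg, topology)
        beads = state.positions[state.kinds != "solute"]
        assert pdist(beads).min() >= cfg.overlap_factor * cfg.sigma_solvent - 1e-9

    def test_packing_error_when_box_too_small(self):
        cfg = desk_config(box=(10.0, 10.0, 10.0), n_solvent=5000, cutoff=4.0)
        with pytest.raises(ValueError, match="packing"):
            build_system(cfg, None)

    def test_no_net_momentum_at_start(self, topology):
        state = build_system(desk_config(seed=2), topology)
        p = np.sum(state.velocities * state.masses[:, None], axis=0)
        assert np.allclose(p, 0.0, atol=1e-9)


class TestIntegration:
    def test_zero_force_zero_velocity_is_stationary(self):
        cfg = desk_config(n_solvent=2, molarity=0.0, box=(30.0, 30.0, 30.0),
                          cutoff=5.0, thermostat=False, body_force=(0, 0, 0))
        state = build_system(cfg, None)
        state.positions[:] = [[5.0, 5.0, 5.0], [25.0, 25.0, 25.0]]
        state.velocities[:] = 0.0
        new = integrate_step(state, cfg)
        assert np.allclose(new.positions, state.positions)

    def test_free_particle_under_constant_force(self):
        """v(k dt) = f k dt / m for a single solvent bead, thermostat off."""
        f = 0.01  # kcal/mol/Å
        cfg = desk_config(n_solvent=1, molarity=0.0, box=(30.0, 30.0, 30.0),
                          cutoff=5.0, thermostat=False, body_force=(f, 0, 0))
        state = build_system(cfg, None)
        state.velocities[:] = 0.0
        sim = Simulator(cfg, state, None)
        k = 250
        sim.step(k)
        expected = ACC * f * k * cfg.dt / state.masses[0]
        assert state.velocities[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_tether_restoring_force_is_hookean(self, topology):
        cfg = desk_config(n_solvent=0, molarity=0.0, eps=0.0, bond_k=0.0,
                          angle_k=0.0, torsion_k=0.0, tether_k=10.0)
        state = build_system(cfg, topology)
        sim = Simulator(cfg, state, topology)
        d = np.array([0.3, -0.2, 0.5])
        i = sim.tether_idx[0]
        state.positions[i] += d
        forces, _ = sim.compute_forces(state.positions)
        assert np.allclose(forces[i], -cfg.tether_k * d, atol=1e-10)

    def test_same_seed_reproduces_bitwise(self, topology):
        cfg = desk_config(duration=0.4, save_stride=0.1, n_solvent=80,
                          molarity=0.0, seed=9)
        t1 = run_simulation(cfg, topology)
        t2 = run_simulation(cfg, topology)
        for f1, f2 in zip(t1.frames, t2.frames):
            assert np.array_equal(f1.positions, f2.positions)
            assert np.array_equal(f1.velocities, f2.velocities)

    def test_duration_equal_to_stride_gives_one_frame(self):
        cfg = desk_config(duration=0.2, save_stride=0.2, n_solvent=30,
                          molarity=0.0)
        traj = run_simulation(cfg, None)
        assert traj.n_frames == 1
        assert traj.frames[0].time == pytest.approx(0.2)


class TestPhysicsInvariants:
    def test_momentum_balance_exact(self):
        """No solute, thermostat off: px after k steps = k dt f n, exactly."""
        f = 0.02
        cfg = desk_config(n_solvent=200, molarity=0.0, box=(22.0, 22.0, 22.0),
                          thermostat=False, body_force=(f, 0, 0), cutoff=8.0)
        state = build_system(cfg, None)
        px0 = float(np.sum(state.masses * state.velocities[:, 0]))
        sim = Simulator(cfg, state, None)
        k = 400
        sim.step(k)
        px = float(np.sum(state.masses * state.velocities[:, 0]))
        expected = k * cfg.dt * f * ACC * 200
        assert (px - px0) == pytest.approx(expected, rel=1e-9)

    def test_thermostat_relaxation_time_constant(self):
        """From 2 T0 the ensemble temperature decays with time constant tau."""
        cfg = desk_config(n_solvent=150, molarity=0.0, box=(30.0, 30.0, 30.0),
                          body_force=(0, 0, 0), cutoff=8.0, seed=4)
        state = build_system(cfg, None)
        state.velocities *= np.sqrt(2.0)
        sim = Simulator(cfg, state, None)
        ts, temps = [], []
        for _ in range(400):
            sim.step(1)
            ts.append(state.time)
            temps.append(sim.temperature())
        model = lambda t, dT, tau: cfg.temperature + dT * np.exp(-t / tau)
        (dT, tau_fit), _ = curve_fit(model, np.array(ts), np.array(temps),
                                     p0=(cfg.temperature, cfg.tau))
        assert tau_fit == pytest.approx(cfg.tau, rel=0.25)

    def test_mean_temperature_at_target(self, pair_runs):
        """Long thermostatted run holds <T> within 3 SE of 300 K."""
        traj = pair_runs["diffusion"]
        temps = np.array([
            instantaneous_temperature(f.velocities, traj.atoms.mass)
            for f in traj.frames[len(traj.frames) // 4:]])
        # block means absorb frame-to-frame correlation
        means = np.array([b.mean() for b in np.array_split(temps, 8)])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - 300.0) < 3 * se

    def test_zero_force_null_bulk_velocity(self, null_run_means):
        """Without body force the steady bulk v_x is 0 within 3 SE.

        The SE comes from independent replicate runs because the
        drift mode decorrelates slowly within any single run."""
        se = null_run_means.std(ddof=1) / np.sqrt(len(null_run_means))
        assert abs(null_run_means.mean()) < 3 * se

    def test_steady_velocity_monotone_in_force(self, force_series):
        v = [force_series[m] for m in (0.25, 1.0, 2.0)]
        assert v[0] < v[1] < v[2]
        assert v[0] > 0

    def test_energy_conservation_symplectic(self):
        """Thermostat and body force off: drift < 0.5 kcal/mol over 1e4 steps."""
        cfg = desk_config(n_solvent=250, molarity=0.0, box=(26.0, 30.0, 26.0),
                          thermostat=False, body_force=(0, 0, 0), cutoff=8.0,
                          seed=6)
        state = build_system(cfg, None)
        sim = Simulator(cfg, state, None)
        e0 = sim.potential_energy + sim.kinetic_energy()
        worst = 0.0
        for _ in range(10):
            sim.step(1000)
            worst = max(worst, abs(sim.potential_energy + sim.kinetic_energy() - e0))
        assert worst < 0.5
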