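"""Integration: rigid-body fidelity, conservation laws, thermostats."""

import numpy as np
import pytest

from conftest import free_config
from macroioncg import units
from macroioncg.builder import MacroionTemplate, SystemSpec, assemble_system
from macroioncg.forcefield import ForceFieldParams
from macroioncg.forces import ForceCalculator
from macroioncg.geometry import quat_to_matrix
from macroioncg.integrators import (BlowUpError, Protocol, Simulation,
                                    ThermoLog, minimize)


def _isolated_macroion(seed=1):
    spec = SystemSpec(n_macroions=1, template=MacroionTemplate(n_charged=0),
                      n_solvent=0, box_length=200.0, seed=seed)
    return assemble_system(spec)


class TestRigidBody:
    def test_free_body_moves_linearly_and_stays_rigid(self):
        cfg = _isolated_macroion()
        rb = cfg.rigid
        rb.com_vel[0] = [0.1, 0.2, -0.05]
        rb.ang_mom[0] = [500.0, 300.0, -200.0]
        sim = Simulation(cfg, ForceCalculator(coulomb="none"),
                         Protocol(ensemble="NVE", output_stride=0,
                                  log_stride=0))
        com0 = rb.com[0].copy()
        sim.run(10_000)
        expected = com0 + rb.com_vel[0] * 10_000 * 0.01
        assert np.linalg.norm(rb.com[0] - expected) < 1e-8
        radii = np.linalg.norm(cfg.positions[:68] - rb.com[0], axis=1)
        assert np.abs(radii - 12.5).max() / 12.5 < 1e-9

    def test_free_rotor_conserves_angular_momentum(self):
        # analytic free rotor: space-frame L is a constant of motion
        cfg = _isolated_macroion()
        rb = cfg.rigid
        rb.ang_mom[0] = [800.0, -350.0, 500.0]
        sim = Simulation(cfg, ForceCalculator(coulomb="none"),
                         Protocol(ensemble="NVE", output_stride=0,
                                  log_stride=0))
        l0 = quat_to_matrix(rb.quat[0]) @ rb.ang_mom[0]
        sim.run(10_000)
        l1 = quat_to_matrix(rb.quat[0]) @ rb.ang_mom[0]
        assert np.linalg.norm(l1 - l0) / np.linalg.norm(l0) < 1e-8

    def test_quaternion_stays_normalised(self):
        cfg = _isolated_macroion()
        cfg.rigid.ang_mom[0] = [900.0, 100.0, -400.0]
        sim = Simulation(cfg, ForceCalculator(coulomb="none"),
                         Protocol(ensemble="NVE", output_stride=0,
                                  log_stride=0))
        sim.run(5000)
        assert np.linalg.norm(cfg.rigid.quat[0]) == pytest.approx(1.0,
                                                                  abs=1e-12)

    def test_bead_distances_constant_during_interaction(self):
        # two shells colliding: intra-body distances must not drift
        tpl = MacroionTemplate(n_charged=0)
        spec = SystemSpec(n_macroions=2, template=tpl, n_solvent=0,
                          box_length=60.0, seed=3)
        pins = np.array([[14.0, 30, 30], [46.0, 30, 30]])
        cfg = assemble_system(spec, macroion_positions=pins)
        cfg.rigid.com_vel[0] = [0.2, 0, 0]
        cfg.rigid.com_vel[1] = [-0.2, 0, 0]
        sim = Simulation(cfg, ForceCalculator(coulomb="none"),
                         Protocol(ensemble="NVE", output_stride=0,
                                  log_stride=0))
        d0 = np.linalg.norm(cfg.positions[0] - cfg.positions[40])
        sim.run(5000)
        d1 = np.linalg.norm(cfg.positions[0] - cfg.positions[40])
        assert abs(d1 - d0) / d0 < 1e-8


class TestNVE:
    def test_energy_drift_bound_lj_pair(self):
        # symplectic-integrator contract: < 1e-4 relative over 1e5 steps
        p = ForceFieldParams(shift_lj=True)
        cfg = free_config([[30.0, 30, 30], [35.6, 30, 30]],
                          velocities=[[0.05, 0, 0], [-0.05, 0, 0]], box=60.0)
        sim = Simulation(cfg, ForceCalculator(params=p, coulomb="none"),
                         Protocol(ensemble="NVE", output_stride=0,
                                  log_stride=0))
        e0 = sim.total_energy()
        worst = 0.0
        for _ in range(10):
            sim.run(10_000)
            worst = max(worst, abs(sim.total_energy() - e0))
        assert worst / abs(e0) < 1e-4

    def test_momentum_conserved_with_deterministic_thermostat(self):
        spec = SystemSpec(n_macroions=0, n_solvent=100, box_length=40.0,
                          seed=9)
        cfg = assemble_system(spec)
        calc = ForceCalculator(coulomb="none")
        minimize(cfg, calc, 50)
        sim = Simulation(cfg, calc, Protocol(ensemble="NVT", tau_t_ps=1.0,
                                             output_stride=0, log_stride=0))
        sim.run(2000)
        assert np.abs(cfg.total_momentum()).max() < 1e-8

    def test_blow_up_detected(self):
        cfg = free_config([[10.0, 10, 10], [14.2, 10, 10]], box=40.0)
        cfg.velocities[0] = [400.0, 0, 0]  # absurd: > half sigma per step
        sim = Simulation(cfg, ForceCalculator(coulomb="none"),
                         Protocol(ensemble="NVE", output_stride=0,
                                  log_stride=0))
        with pytest.raises(BlowUpError):
            sim.run(10)


class TestThermostats:
    def test_langevin_free_particle_diffusion(self, rng):
        # fluctuation-dissipation: D = k_B T / (m gamma) within 5%
        from macroioncg.analysis import compute_msd, diffusion_coefficient
        n = 800
        cfg = free_config(rng.random((n, 3)) * 500.0, box=500.0)
        # thermalise velocities so the production MSD is purely diffusive
        cfg.velocities = rng.standard_normal((n, 3)) * \
            np.sqrt(units.KB * 300.0 / 72.0)
        calc = ForceCalculator(params=ForceFieldParams(epsilon=1e-10),
                               coulomb="none")
        prot = Protocol(ensemble="LANGEVIN", gamma_ps=1.0, temperature=300.0,
                        n_steps=15_000, output_stride=100, log_stride=0,
                        seed=4)
        traj = Simulation(cfg, calc, prot).run()
        msd = diffusion_coefficient(compute_msd(traj, "solvent"),
                                    fit_window=(0.1, 0.5), scale_factor=1.0)
        d_expected = units.KB * 300.0 / (72.0 * 1.0) * units.DIFFUSION_CM2S
        assert msd.d_reported == pytest.approx(d_expected, rel=0.05)

    def test_berendsen_holds_target_temperature(self):
        spec = SystemSpec(n_macroions=0, n_solvent=300, box_length=40.0,
                          seed=3)
        cfg = assemble_system(spec)
        calc = ForceCalculator(coulomb="none")
        minimize(cfg, calc, 100)
        thermo = ThermoLog()
        sim = Simulation(cfg, calc, Protocol(
            ensemble="NVT", temperature=300.0, tau_t_ps=1.0, n_steps=5000,
            output_stride=0, log_stride=50))
        sim.run(thermo=thermo)
        mean_t = np.mean(thermo.temperature[20:])
        assert mean_t == pytest.approx(300.0, rel=0.02)

    def test_dilute_gas_pressure_matches_ideal_law(self, rng):
        # virial pressure oracle: P -> rho k_B T for a near-ideal gas
        n, box, temp = 343, 210.0, 300.0
        grid = np.array([[i, j, k] for i in range(7) for j in range(7)
                         for k in range(7)], dtype=float) * 30.0 + 5.0
        cfg = free_config(grid + rng.standard_normal((n, 3)) * 2.0, box=box)
        cfg.velocities = rng.standard_normal((n, 3)) * \
            np.sqrt(units.KB * temp / 72.0)
        calc = ForceCalculator(params=ForceFieldParams(epsilon=1e-9),
                               coulomb="none")
        sim = Simulation(cfg, calc, Protocol(ensemble="NVE",
                                             output_stride=0, log_stride=0))
        t_actual = sim.temperature()
        p_ideal = n * units.KB * t_actual / box ** 3 * units.PRESSURE_BAR
        # a single configuration: kinetic part dominates, virial ~ 0
        assert sim.pressure_bar() == pytest.approx(p_ideal, rel=0.02)

    def test_npt_with_ewald_unsupported(self):
        cfg = free_config([[10.0, 10, 10], [20.0, 10, 10]],
                          charges=[1.0, -1.0], box=40.0)
        with pytest.raises(NotImplementedError):
            Simulation(cfg, ForceCalculator(coulomb="ewald"),
                       Protocol(ensemble="NPT", output_stride=0,
                                log_stride=0))


class TestCheckpoint:
    def test_configuration_roundtrip(self, tmp_path):
        spec = SystemSpec(n_macroions=1,
                          template=MacroionTemplate(n_charged=5),
                          n_solvent=50, box_length=40.0, seed=6)
        cfg = assemble_system(spec)
        path = tmp_path / "state.npz"
        cfg.save_npz(path)
        back = type(cfg).load_npz(path)
        assert np.array_equal(back.positions, cfg.positions)
        assert np.array_equal(back.velocities, cfg.velocities)
        assert np.array_equal(back.rigid.quat, cfg.rigid.quat)
        assert back.box == cfg.box

    def test_resumed_run_matches_uninterrupted(self, tmp_path):
        spec = SystemSpec(n_macroions=0, n_solvent=60, box_length=40.0,
                          seed=8)
        cfg_a = assemble_system(spec)
        calc = ForceCalculator(coulomb="none")
        minimize(cfg_a, calc, 30)
        cfg_b = cfg_a.copy()
        prot = Protocol(ensemble="NVE", output_stride=0, log_stride=0)
        sim_a = Simulation(cfg_a, calc, prot)
        sim_a.run(200)
        # checkpoint at step 100 via save/load, then continue
        sim_b = Simulation(cfg_b, ForceCalculator(coulomb="none"), prot)
        sim_b.run(100)
        path = tmp_path / "ck.npz"
        sim_b.config.save_npz(path)
        resumed = type(cfg_b).load_npz(path)
        sim_c = Simulation(resumed, ForceCalculator(coulomb="none"), prot)
        sim_c.run(100)
        assert np.allclose(sim_c.config.positions, cfg_a.positions,
                           atol=1e-10)
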