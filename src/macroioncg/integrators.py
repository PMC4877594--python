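"""Time integration: point particles + rigid macroions, several ensembles.

Point particles are advanced by velocity Verlet; each macroion is advanced
as a rigid body — COM translation plus quaternion rotation driven by the net
force and torque about the COM.  Free rotation uses the
Dullweber-Leimkuhler-McLachlan (DLM) splitting (exact axis-wise rotations,
so rigidity is exact by construction and the free rotor conserves angular
momentum to roundoff).

Ensembles
---------
NVE
    plain velocity Verlet / DLM.
NVT
    Berendsen velocity-rescale thermostat (deterministic; conserves the
    zero total momentum of the builder).
NPT
    NVT plus an isotropic Berendsen barostat on the pairwise virial
    pressure (LJ / DSF systems; full-Ewald NPT is not implemented).
LANGEVIN
    BAOAB splitting with an exact Ornstein-Uhlenbeck velocity update,
    applied to free particles, rigid COM velocities and body-frame angular
    momenta.  Used for the implicit-solvent surrogate mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from .forces import ForceCalculator, ForceResult
from .geometry import quat_from_axis_angle, quat_multiply, quat_to_matrix
from .system import Configuration
from .trajectory import Frame, Trajectory

_BERENDSEN_COMPRESSIBILITY = 4.5e-5  # 1/bar, water-like


class BlowUpError(RuntimeError):
    """A particle moved more than half a bead diameter in one step."""


@dataclass
class Protocol:
    """Run protocol: ensemble, step size, coupling constants, output."""

    ensemble: str = "NVT"
    timestep_fs: float = 10.0
    n_steps: int = 1000
    temperature: float = 300.0
    pressure: float = 1.0            # bar, NPT only
    tau_t_ps: float = 1.0            # Berendsen thermostat coupling
    tau_p_ps: float = 5.0            # Berendsen barostat coupling
    gamma_ps: float = 1.0            # Langevin friction
    output_stride: int = 100         # frames
    log_stride: int = 100            # thermo rows
    store_forces: bool = False       # keep decomposed forces in frames
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        self.ensemble = self.ensemble.upper()
        if self.ensemble not in ("NVE", "NVT", "NPT", "LANGEVIN"):
            raise ValueError(f"unknown ensemble {self.ensemble!r}")
        if self.ensemble == "NPT" and self.pressure is None:
            raise ValueError("NPT requires a target pressure")
        if self.ensemble == "LANGEVIN" and not self.gamma_ps > 0:
            raise ValueError("Langevin requires a positive friction gamma")

    @property
    def dt(self) -> float:
        """Timestep in ps."""
        return self.timestep_fs * 1e-3


@dataclass
class ThermoLog:
    """Per-interval thermodynamic record of a run."""

    step: list = field(default_factory=list)
    time: list = field(default_factory=list)
    temperature: list = field(default_factory=list)
    pressure: list = field(default_factory=list)
    density: list = field(default_factory=list)
    e_vdw: list = field(default_factory=list)
    e_coul: list = field(default_factory=list)
    e_kinetic: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: np.asarray(getattr(self, k)) for k in (
            "step", "time", "temperature", "pressure", "density",
            "e_vdw", "e_coul", "e_kinetic")}


class Simulation:
    """Advance one Configuration under a Protocol."""

    def __init__(self, config: Configuration, calculator: ForceCalculator,
                 protocol: Protocol):
        self.config = config
        self.calc = calculator
        self.protocol = protocol
        self.rng = np.random.default_rng(
            np.random.SeedSequence(protocol.seed).spawn(1)[0])
        if protocol.ensemble == "NPT" and \
                self.calc._mode(config) == 1:  # COUL_EWALD_REAL
            raise NotImplementedError(
                "NPT with full Ewald electrostatics is not supported; "
                "use DSF electrostatics or an NVT protocol")
        config.sync_rigid_beads()
        self.result: ForceResult = self.calc.compute(config)
        self._body_force = None
        self._body_torque = None
        self._update_body_forces()
        self.step_count = 0

    # --- rigid-body force reduction ---------------------------------------

    def _update_body_forces(self) -> None:
        rb = self.config.rigid
        if rb is None:
            return
        from ._kernels import rigid_reduce_forces
        if self._body_force is None:
            self._body_force = np.zeros((rb.n_bodies, 3))
            self._body_torque = np.zeros((rb.n_bodies, 3))
        rigid_reduce_forces(self.result.f_total, rb.quat, rb.body_coords,
                            self._body_force, self._body_torque)

    # --- sub-steps ---------------------------------------------------------

    def _kick(self, h: float) -> None:
        cfg = self.config
        free = cfg.free_mask
        cfg.velocities[free] += h * self.result.f_total[free] / \
            cfg.masses[free, None]
        rb = cfg.rigid
        if rb is not None:
            rb.com_vel += h * self._body_force / rb.mass[:, None]
            rb.ang_mom += h * self._body_torque

    def _drift(self, h: float) -> None:
        cfg = self.config
        free = cfg.free_mask
        dx = h * cfg.velocities[free]
        max_d = np.sqrt((dx ** 2).sum(axis=1).max()) if len(dx) else 0.0
        cfg.positions[free] += dx
        rb = cfg.rigid
        if rb is not None:
            dcom = h * rb.com_vel
            if len(dcom):
                max_d = max(max_d, np.sqrt((dcom ** 2).sum(axis=1).max()))
            rb.com += dcom
            self._rotate_bodies(h)
        if max_d > 0.5 * self.calc.params.sigma:
            raise BlowUpError(
                f"step {self.step_count}: displacement {max_d:.2f} A "
                f"exceeds half a bead diameter — reduce the timestep or "
                f"equilibrate with a capped minimizer first")

    def _rotate_bodies(self, h: float) -> None:
        """DLM free rotation of every body over time ``h``."""
        from ._kernels import rigid_dlm_rotate
        rb = self.config.rigid
        rigid_dlm_rotate(rb.quat, rb.ang_mom, rb.inertia, h)

    def _ou_step(self) -> None:
        """Exact Ornstein-Uhlenbeck update (Langevin O-part)."""
        p = self.protocol
        cfg = self.config
        c1 = np.exp(-p.gamma_ps * p.dt)
        c2 = np.sqrt(1.0 - c1 * c1)
        kt = units.KB * p.temperature
        free = cfg.free_mask
        n_free = int(free.sum())
        if n_free:
            sig = np.sqrt(kt / cfg.masses[free])[:, None]
            cfg.velocities[free] = c1 * cfg.velocities[free] + \
                c2 * sig * self.rng.standard_normal((n_free, 3))
        rb = cfg.rigid
        if rb is not None:
            sig = np.sqrt(kt / rb.mass)[:, None]
            rb.com_vel = c1 * rb.com_vel + \
                c2 * sig * self.rng.standard_normal((rb.n_bodies, 3))
            sig_l = np.sqrt(kt * np.maximum(rb.inertia, 0.0))
            noise = self.rng.standard_normal((rb.n_bodies, 3))
            rb.ang_mom = c1 * rb.ang_mom + c2 * sig_l * noise
            rb.ang_mom[rb.inertia <= 1e-9] = 0.0

    def _berendsen_thermostat(self) -> None:
        p = self.protocol
        cfg = self.config
        t = units.kinetic_temperature(cfg.kinetic_energy(), cfg.n_dof())
        if t <= 0:
            return
        lam = np.sqrt(max(0.64, min(1.5625,
            1.0 + p.dt / p.tau_t_ps * (p.temperature / t - 1.0))))
        cfg.velocities[cfg.free_mask] *= lam
        if cfg.rigid is not None:
            cfg.rigid.com_vel *= lam
            cfg.rigid.ang_mom *= lam

    def pressure_bar(self) -> float:
        """Instantaneous molecular-virial pressure, bar."""
        cfg = self.config
        free = cfg.free_mask
        ke2 = np.sum(cfg.masses[free, None] * cfg.velocities[free] ** 2)
        w = self.result.virial
        rb = cfg.rigid
        if rb is not None:
            from .geometry import quats_to_matrices
            ke2 += np.sum(rb.mass[:, None] * rb.com_vel ** 2)
            # molecular virial: remove the intra-body force moment
            arms = np.einsum("bij,bnj->bni", quats_to_matrices(rb.quat),
                             rb.body_coords)
            fb = self.result.f_total[:rb.n_bodies * rb.n_beads] \
                .reshape(rb.n_bodies, rb.n_beads, 3)
            w -= np.sum(fb * arms)
        vol = cfg.box ** 3
        return (ke2 + w) / (3.0 * vol) * units.PRESSURE_BAR

    def _berendsen_barostat(self) -> None:
        p = self.protocol
        cfg = self.config
        pr = self.pressure_bar()
        mu = (1.0 - _BERENDSEN_COMPRESSIBILITY * p.dt / p.tau_p_ps
              * (p.pressure - pr)) ** (1.0 / 3.0)
        mu = max(0.99, min(1.01, mu))
        cfg.box *= mu
        cfg.positions[cfg.free_mask] *= mu
        if cfg.rigid is not None:
            cfg.rigid.com *= mu
            cfg.sync_rigid_beads()
        # keep the neighbor list valid: scale its reference frame along with
        # the box (mu ~ 1 +- 1e-5 per step; the skin absorbs the distortion)
        if self.calc.nlist._ref_positions is not None:
            self.calc.nlist._ref_positions *= mu

    # --- main loop ---------------------------------------------------------

    def step(self) -> None:
        p = self.protocol
        dt = p.dt
        cfg = self.config
        self._kick(0.5 * dt)
        self._drift(0.5 * dt)
        if p.ensemble == "LANGEVIN":
            self._ou_step()
        self._drift(0.5 * dt)
        cfg.sync_rigid_beads()
        self.result = self.calc.compute(cfg)
        self._update_body_forces()
        self._kick(0.5 * dt)
        if p.ensemble in ("NVT", "NPT"):
            self._berendsen_thermostat()
        if p.ensemble == "NPT":
            self._berendsen_barostat()
        cfg.time += dt
        self.step_count += 1

    def total_energy(self) -> float:
        """KE + PE, internal units (NVE conservation diagnostic)."""
        return self.config.kinetic_energy() + self.result.e_total

    def temperature(self) -> float:
        return units.kinetic_temperature(
            self.config.kinetic_energy(),
            self.config.n_dof(remove_com=self.protocol.ensemble != "LANGEVIN"))

    def run(self, n_steps: int | None = None,
            trajectory: Trajectory | None = None,
            thermo: ThermoLog | None = None) -> Trajectory:
        """Advance ``n_steps`` (default: protocol.n_steps), recording frames
        every ``output_stride`` and thermo rows every ``log_stride``."""
        p = self.protocol
        n_steps = p.n_steps if n_steps is None else n_steps
        cfg = self.config
        if trajectory is None:
            trajectory = Trajectory(species=cfg.species.copy(),
                                    mol=cfg.mol.copy(),
                                    charges=cfg.charges.copy())
        for k in range(n_steps):
            self.step()
            if p.log_stride and self.step_count % p.log_stride == 0 \
                    and thermo is not None:
                self._log_thermo(thermo)
            if p.output_stride and self.step_count % p.output_stride == 0:
                trajectory.append(self._snapshot())
        return trajectory

    def _snapshot(self) -> Frame:
        cfg = self.config
        pos, images = cfg.wrapped_positions()
        frame = Frame(box=cfg.box, time=cfg.time, positions=pos,
                      images=images,
                      e_vdw=self.result.e_vdw_kjmol,
                      e_coul=self.result.e_coul_kjmol)
        if self.protocol.store_forces:
            frame.f_vdw = self.result.f_vdw * units.ENERGY_KJMOL
            frame.f_coul = self.result.f_coul * units.ENERGY_KJMOL
        return frame

    def _log_thermo(self, thermo: ThermoLog) -> None:
        cfg = self.config
        thermo.step.append(self.step_count)
        thermo.time.append(cfg.time)
        thermo.temperature.append(self.temperature())
        thermo.pressure.append(self.pressure_bar())
        thermo.density.append(
            units.mass_density_gcm3(cfg.total_mass(), cfg.box ** 3))
        thermo.e_vdw.append(self.result.e_vdw_kjmol)
        thermo.e_coul.append(self.result.e_coul_kjmol)
        thermo.e_kinetic.append(cfg.kinetic_energy() * units.ENERGY_KJMOL)


def minimize(config: Configuration, calculator: ForceCalculator,
             n_steps: int = 200, max_disp: float = 0.2,
             max_angle: float = 0.02) -> float:
    """Capped steepest-descent relaxation (removes build-time overlaps).

    Moves every free particle along its force and every rigid body along its
    net force/torque, with per-step caps, until ``n_steps`` are done.
    Returns the final potential energy in kJ/mol.
    """
    config.sync_rigid_beads()
    res = calculator.compute(config)
    for _ in range(n_steps):
        free = config.free_mask
        f = res.f_total[free]
        norm = np.maximum(np.linalg.norm(f, axis=1, keepdims=True), 1e-12)
        step = f / norm * np.minimum(norm * 1e-4, max_disp)
        config.positions[free] += step
        rb = config.rigid
        if rb is not None:
            for b in range(rb.n_bodies):
                sl = slice(rb.first[b], rb.first[b] + rb.n_beads)
                fb = res.f_total[sl]
                force = fb.sum(axis=0)
                fn = np.linalg.norm(force)
                if fn > 1e-12:
                    rb.com[b] += force / fn * min(fn * 1e-4, max_disp)
                rot = quat_to_matrix(rb.quat[b])
                arms = rb.body_coords[b] @ rot.T
                tau = np.cross(arms, fb).sum(axis=0)
                tn = np.linalg.norm(tau)
                if tn > 1e-12:
                    angle = min(tn * 1e-6, max_angle)
                    rb.quat[b] = quat_multiply(
                        quat_from_axis_angle(tau / tn, angle), rb.quat[b])
                    rb.quat[b] /= np.linalg.norm(rb.quat[b])
        config.sync_rigid_beads()
        res = calculator.compute(config)
    return res.e_total * units.ENERGY_KJMOL
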