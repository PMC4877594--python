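"""Deterministic test fixtures with independently computed sidecars.

Every fixture writes an extended-XYZ configuration plus a JSON sidecar of
expected values computed from closed forms (never from the engine), so the
engine can be validated against them.  Files are byte-identical for the
same (name, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .builder import MacroionTemplate, SystemSpec, assemble_system
from .forcefield import ForceFieldParams, coulomb_pair, lj_pair
from .system import Configuration
from .trajectory import Frame, Trajectory, write_xyz
from . import units

FIXTURE_NAMES = ("lj_dimer", "charged_triplet", "solvent_box_small",
                 "two_macroion_dimer", "sweep_mini")


class UnknownFixtureError(ValueError):
    def __init__(self, name):
        super().__init__(f"unknown fixture {name!r}; available: "
                         + ", ".join(FIXTURE_NAMES))


def _traj_of(config: Configuration) -> Trajectory:
    pos, images = config.wrapped_positions()
    return Trajectory(species=config.species.copy(), mol=config.mol.copy(),
                      charges=config.charges.copy(),
                      frames=[Frame(box=config.box, time=0.0, positions=pos,
                                    images=images)])


def generate_fixture(name: str, seed: int = 0, outdir=".") -> dict:
    """Write fixture ``name``; returns {"xyz": path, "sidecar": path}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = ForceFieldParams()
    if name == "lj_dimer":
        r = 2.0 ** (1.0 / 6.0) * params.sigma
        pos = np.array([[30.0, 30, 30], [30.0 + r, 30, 30]])
        config = _free_config(pos, np.zeros(2), box=60.0)
        pair = lj_pair(r, params)
        sidecar = {"separation_A": r, "energy_kjmol": pair.energy,
                   "force_kjmol_A": pair.force}
    elif name == "charged_triplet":
        pos = np.array([[25.0, 30, 30], [30.0, 30, 30], [35.0, 30, 30]])
        q = np.array([-1.0, 1.0, -1.0])
        config = _free_config(pos, q, box=60.0)
        energy = 0.0
        forces = np.zeros((3, 3))
        for i in range(3):
            for j in range(i + 1, 3):
                d = pos[i] - pos[j]
                r = float(np.linalg.norm(d))
                pair = coulomb_pair(r, q[i], q[j])
                energy += pair.energy
                forces[i] += pair.force * d / r
                forces[j] -= pair.force * d / r
        sidecar = {"coulomb_energy_kjmol": energy,
                   "coulomb_forces_kjmol_A": forces.tolist()}
    elif name == "solvent_box_small":
        n = 200
        volume = n * params.bead_mass * units.DENSITY_GCM3 / 0.97
        box = volume ** (1.0 / 3.0)
        spec = SystemSpec(n_macroions=0, n_solvent=n, box_length=box,
                          seed=seed)
        config = assemble_system(spec)
        sidecar = {"n_solvent": n, "box_A": box, "density_g_cm3": 0.97}
    elif name == "two_macroion_dimer":
        template = MacroionTemplate(n_charged=20, seed=seed)
        spec = SystemSpec(n_macroions=2, template=template, n_solvent=0,
                          box_length=60.0, seed=seed)
        pins = np.array([[15.0, 30, 30], [45.0, 30, 30]])
        config = assemble_system(spec, macroion_positions=pins)
        sidecar = {"n_counterions": 40, "n_particles": config.n_particles,
                   "total_charge_e": config.total_charge(),
                   "com_separation_A": 30.0}
    elif name == "sweep_mini":
        template = MacroionTemplate(n_charged=6, seed=seed)
        spec = SystemSpec(n_macroions=4, template=template, n_solvent=0,
                          box_length=70.0, seed=seed)
        config = assemble_system(spec)
        sidecar = {"n_counterions": 24, "n_particles": config.n_particles,
                   "total_charge_e": config.total_charge()}
    else:
        raise UnknownFixtureError(name)
    xyz = outdir / f"{name}.xyz"
    write_xyz(_traj_of(config), xyz)
    side = outdir / f"{name}.json"
    with open(side, "w") as fh:
        json.dump({"name": name, "seed": seed, **sidecar}, fh, indent=2,
                  sort_keys=True)
    return {"xyz": str(xyz), "sidecar": str(side)}


def _free_config(pos: np.ndarray, charges: np.ndarray,
                 box: float) -> Configuration:
    n = len(pos)
    from .system import SP_COUNTERION, SP_SOLVENT
    species = np.where(charges != 0, SP_COUNTERION, SP_SOLVENT).astype(np.int8)
    return Configuration(box=box, positions=np.asarray(pos, float),
                         velocities=np.zeros((n, 3)), charges=charges,
                         species=species, mol=np.full(n, -1, np.int32),
                         masses=np.full(n, 72.0))
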