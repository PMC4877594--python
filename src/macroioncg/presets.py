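"""Reproducible experiment presets at desk scale.

Each preset builds a system, simulates it and analyses the result in one
call, returning a flat dict of numbers; :func:`run_preset` wraps them with
file output (results.json, thermo.tsv, manifest.json).  The presets mirror
the study designs the model was made for:

``solvent_diffusion``
    pure CG solvent at 0.97 g/cm^3 and 300 K; MSD -> self-diffusion
    coefficient with the factor-4 CG rescaling.
``npt_density``
    pure solvent NPT at 300 K / 1 bar; equilibrium density.
``two_macroion_forces``
    a contact dimer of two 20-charge macroions, 40 counterions, explicit
    solvent; decomposed net forces on each macroion projected onto the pair
    axis -> electrostatic vs van der Waals magnitude ratio.
``charge_sweep``
    implicit-solvent Langevin sweep over surface charge counts; mean
    first-neighbor count -> assembly transition charge, plus counterion and
    macroion diffusion versus charge.
``uncharged_control``
    uncharged macromolecules in the implicit good-solvent mode at sweep
    dilution; no aggregation beyond transient dimers/trimers.
``charge_switch_off``
    preformed charged aggregate whose charges are set to zero mid-run; the
    aggregate disassembles.

All sizes are deliberately desk-scale (hundreds of particles, nanoseconds);
``scale="tiny"`` shrinks durations further for smoke testing.
"""

from __future__ import annotations

import json
import time as _time
from pathlib import Path

import numpy as np

from . import units
from .analysis import (cluster_aggregates, compute_msd, compute_rdf,
                       diffusion_coefficient, macroion_force_series,
                       mean_first_neighbor_count)
from .builder import (MacroionTemplate, SystemSpec, assemble_system,
                      required_counterions)
from .ewald import EwaldSettings
from .forces import ForceCalculator
from .integrators import Protocol, Simulation, ThermoLog, minimize
from .trajectory import Trajectory, write_xyz

#: contact cutoff (A) defining macroion neighbors/clusters for 25 A macroions
CONTACT_CUTOFF = 32.0


def _box_for_density(n_beads: int, density: float, bead_mass: float = 72.0) -> float:
    volume = n_beads * bead_mass * units.DENSITY_GCM3 / density
    return float(volume ** (1.0 / 3.0))


def _steps(ps: float, timestep_fs: float = 10.0) -> int:
    return int(round(ps / (timestep_fs * 1e-3)))


# --- solvent self-diffusion ------------------------------------------------

def solvent_diffusion_experiment(seed: int = 0, n_solvent: int = 1000,
                                 density: float = 0.97,
                                 temperature: float = 300.0,
                                 equil_ps: float = 50.0,
                                 prod_ps: float = 2000.0,
                                 frame_ps: float = 1.0) -> dict:
    """Self-diffusion of the pure CG solvent from time-averaged MSD.

    Equilibrates with a tight Berendsen thermostat, then runs production
    with weak coupling (tau = 10 ps) so the thermostat barely perturbs the
    dynamics; D comes from a 10-50% lag-window fit and is divided by the
    standard CG factor of 4.
    """
    box = _box_for_density(n_solvent, density)
    spec = SystemSpec(n_macroions=0, n_solvent=n_solvent, box_length=box,
                      temperature=temperature, seed=seed)
    config = assemble_system(spec)
    calc = ForceCalculator()
    minimize(config, calc, n_steps=100)
    sim = Simulation(config, calc, Protocol(
        ensemble="NVT", temperature=temperature, tau_t_ps=0.5,
        n_steps=_steps(equil_ps), output_stride=0, log_stride=0, seed=seed))
    sim.run()
    thermo = ThermoLog()
    prot = Protocol(ensemble="NVT", temperature=temperature, tau_t_ps=10.0,
                    n_steps=_steps(prod_ps),
                    output_stride=_steps(frame_ps), log_stride=500, seed=seed)
    sim = Simulation(config, calc, prot)
    traj = sim.run(thermo=thermo)
    msd = compute_msd(traj, "solvent")
    msd = diffusion_coefficient(msd, fit_window=(0.1, 0.5), scale_factor=4.0)
    log = thermo.as_dict()
    return {
        "d_cm2_s": msd.d_reported,
        "d_raw_cm2_s": msd.d_raw,
        "mean_temperature_K": float(np.mean(log["temperature"])),
        "density_g_cm3": float(np.mean(log["density"])),
        "n_solvent": n_solvent,
        "prod_ps": prod_ps,
        "_msd": msd, "_thermo": log, "_trajectory": traj,
    }


# --- NPT density -----------------------------------------------------------

def npt_density_experiment(seed: int = 0, n_solvent: int = 512,
                           start_density: float = 0.90,
                           temperature: float = 300.0, pressure: float = 1.0,
                           equil_ps: float = 200.0,
                           prod_ps: float = 500.0) -> dict:
    """Equilibrium density of the pure solvent under NPT at 300 K / 1 bar.

    Starts deliberately off-density (0.90 g/cm^3) so the barostat has to
    find the equilibrium value; reports the production-phase mean.
    """
    box = _box_for_density(n_solvent, start_density)
    spec = SystemSpec(n_macroions=0, n_solvent=n_solvent, box_length=box,
                      temperature=temperature, pressure=pressure, seed=seed)
    config = assemble_system(spec)
    calc = ForceCalculator()
    minimize(config, calc, n_steps=100)
    sim = Simulation(config, calc, Protocol(
        ensemble="NPT", temperature=temperature, pressure=pressure,
        tau_t_ps=1.0, tau_p_ps=5.0, n_steps=_steps(equil_ps),
        output_stride=0, log_stride=500, seed=seed))
    sim.run()
    thermo = ThermoLog()
    sim = Simulation(config, calc, Protocol(
        ensemble="NPT", temperature=temperature, pressure=pressure,
        tau_t_ps=1.0, tau_p_ps=5.0, n_steps=_steps(prod_ps),
        output_stride=0, log_stride=100, seed=seed + 1))
    sim.run(thermo=thermo)
    log = thermo.as_dict()
    return {
        "density_g_cm3": float(np.mean(log["density"])),
        "density_std": float(np.std(log["density"])),
        "mean_temperature_K": float(np.mean(log["temperature"])),
        "mean_pressure_bar": float(np.mean(log["pressure"])),
        "n_solvent": n_solvent,
        "_thermo": log,
    }


# --- two-macroion force decomposition --------------------------------------

def dimer_force_experiment(seed: int = 0, n_charged: int = 20,
                           box: float = 60.0, density: float = 0.97,
                           separation: float = 30.0,
                           temperature: float = 300.0,
                           equil_ps: float = 30.0, prod_ps: float = 500.0,
                           frame_ps: float = 1.0) -> dict:
    """Electrostatic vs van der Waals force on a macroion contact dimer.

    Two 20-charge macroions prepared in contact with their 40 counterions
    and explicit solvent; the net vdW and Coulomb forces on each macroion
    are projected onto the pair axis every frame (negative = attractive).
    """
    template = MacroionTemplate(n_charged=n_charged, seed=seed)
    spec = SystemSpec(n_macroions=2, template=template,
                      target_density=density, box_length=box,
                      temperature=temperature, seed=seed)
    center = box / 2.0
    pins = np.array([[center - separation / 2.0, center, center],
                     [center + separation / 2.0, center, center]])
    config = assemble_system(spec, macroion_positions=pins)
    calc = ForceCalculator(coulomb="ewald",
                           ewald=EwaldSettings(accuracy=3e-4, r_cut=15.0))
    minimize(config, calc, n_steps=300)
    sim = Simulation(config, calc, Protocol(
        ensemble="LANGEVIN", temperature=temperature, gamma_ps=1.0,
        n_steps=_steps(equil_ps), output_stride=0, log_stride=0, seed=seed))
    sim.run()
    thermo = ThermoLog()
    prot = Protocol(ensemble="LANGEVIN", temperature=temperature,
                    gamma_ps=1.0, n_steps=_steps(prod_ps),
                    output_stride=_steps(frame_ps), log_stride=500,
                    store_forces=True, seed=seed + 1)
    sim = Simulation(config, calc, prot)
    traj = sim.run(thermo=thermo)
    trace = macroion_force_series(traj, pair=(0, 1))
    return {
        "force_ratio": trace.coul_vdw_ratio,
        "mean_signed_proj_coul_kjmol_A": float(trace.proj_coul.mean()),
        "mean_signed_proj_vdw_kjmol_A": float(trace.proj_vdw.mean()),
        "mean_abs_proj_coul_kjmol_A": trace.mean_abs_proj_coul,
        "mean_abs_proj_vdw_kjmol_A": trace.mean_abs_proj_vdw,
        "mean_pair_distance_A": float(trace.distance.mean()),
        "n_counterions": required_counterions(spec),
        "_trace": trace, "_trajectory": traj, "_thermo": thermo.as_dict(),
    }


# --- charge-density sweep (implicit solvent) -------------------------------

def charge_sweep_experiment(seed: int = 0,
                            charge_counts=(0, 2, 4, 5, 6, 8, 16, 20),
                            n_macroions: int = 8, box: float = 100.0,
                            temperature: float = 300.0,
                            gamma_ps: float = 0.1,
                            equil_ps: float = 30.0,
                            prod_ps: float = 1200.0,
                            frame_ps: float = 2.0) -> dict:
    """Assembly vs surface charge: the implicit-solvent surrogate sweep.

    Macroions + counterions only, WCA repulsion (the good-solvent limit)
    with damped-shifted-force electrostatics under weak-friction Langevin
    dynamics.  For each charge count the sustained mean first-neighbor
    count over the final 20% of frames is the assembly indicator; the
    transition charge is the smallest count with more than 2 neighbors.
    """
    per_charge = {}
    for qi, n_charged in enumerate(charge_counts):
        template = MacroionTemplate(n_charged=n_charged, seed=seed + qi)
        spec = SystemSpec(n_macroions=n_macroions, template=template,
                          n_solvent=0, box_length=box,
                          temperature=temperature, seed=seed + 100 + qi)
        config = assemble_system(spec)
        calc = ForceCalculator(coulomb="dsf" if n_charged else "none",
                               wca=True,
                               ewald=EwaldSettings(r_cut=20.0))
        minimize(config, calc, n_steps=100)
        sim = Simulation(config, calc, Protocol(
            ensemble="LANGEVIN", temperature=temperature, gamma_ps=1.0,
            n_steps=_steps(equil_ps), output_stride=0, log_stride=0,
            seed=seed + qi))
        sim.run()
        prot = Protocol(ensemble="LANGEVIN", temperature=temperature,
                        gamma_ps=gamma_ps, n_steps=_steps(prod_ps),
                        output_stride=_steps(frame_ps), log_stride=0,
                        seed=seed + 200 + qi)
        sim = Simulation(config, calc, prot)
        traj = sim.run()
        entry = {
            "neighbor_count": mean_first_neighbor_count(
                traj, cutoff=CONTACT_CUTOFF, frame_fraction=0.2),
            "largest_cluster": cluster_aggregates(
                traj.macroion_coms(traj.n_frames - 1), box,
                CONTACT_CUTOFF).largest,
        }
        msd_m = diffusion_coefficient(compute_msd(traj, "macroion"),
                                      fit_window=(0.1, 0.5))
        entry["d_macroion_cm2_s"] = msd_m.d_reported
        if n_charged > 0:
            msd_c = diffusion_coefficient(
                compute_msd(traj, "counterion", per_particle=True),
                fit_window=(0.1, 0.5))
            entry["d_counterion_cm2_s"] = msd_c.d_reported
            entry["d_counterion_sem"] = msd_c.d_sem
            rdf = compute_rdf(traj, "macroion", bin_width=0.5)
            entry["_rdf"] = rdf
        entry["_trajectory"] = traj
        per_charge[n_charged] = entry
    transition = None
    for q in sorted(per_charge):
        if per_charge[q]["neighbor_count"] > 2.0:
            transition = q
            break
    return {
        "transition_charge": transition,
        "neighbor_counts": {q: per_charge[q]["neighbor_count"]
                            for q in per_charge},
        "per_charge": per_charge,
    }


# --- uncharged control -----------------------------------------------------

def uncharged_control_experiment(seed: int = 0, n_macroions: int = 8,
                                 box: float = 100.0,
                                 temperature: float = 300.0,
                                 equil_ps: float = 30.0,
                                 prod_ps: float = 500.0,
                                 frame_ps: float = 2.0) -> dict:
    """Uncharged macromolecules in a good solvent: no aggregation.

    Runs the implicit good-solvent mode (WCA repulsion, Langevin) at the
    same dilution as the charge sweep, so the observable — no aggregation
    beyond transient dimers/trimers — is measurable at desk scale: the
    ideal-gas neighbor baseline at this density is ~1 and mobile shells
    with no electrostatic glue must not chain up.  The check is that the
    largest cluster never exceeds a trimer over the final 20% of frames.
    """
    template = MacroionTemplate(n_charged=0, seed=seed)
    spec = SystemSpec(n_macroions=n_macroions, template=template,
                      n_solvent=0, box_length=box,
                      temperature=temperature, seed=seed)
    config = assemble_system(spec)
    calc = ForceCalculator(coulomb="none", wca=True)
    minimize(config, calc, n_steps=100)
    sim = Simulation(config, calc, Protocol(
        ensemble="LANGEVIN", temperature=temperature, gamma_ps=1.0,
        n_steps=_steps(equil_ps), output_stride=0, log_stride=0, seed=seed))
    sim.run()
    prot = Protocol(ensemble="LANGEVIN", temperature=temperature,
                    gamma_ps=0.1, n_steps=_steps(prod_ps),
                    output_stride=_steps(frame_ps),
                    log_stride=0, seed=seed + 1)
    sim = Simulation(config, calc, prot)
    traj = sim.run()
    n_frames = traj.n_frames
    k0 = int(np.ceil(n_frames * 0.8))
    largest = [cluster_aggregates(traj.macroion_coms(k), traj.frames[k].box,
                                  CONTACT_CUTOFF).largest
               for k in range(k0, n_frames)]
    return {
        # max picks up single-frame contact chains; the median is the
        # persistence statistic that distinguishes a stable aggregate
        # from transient encounters
        "largest_cluster_final": int(max(largest)),
        "largest_cluster_median": float(np.median(largest)),
        "neighbor_count": mean_first_neighbor_count(
            traj, cutoff=CONTACT_CUTOFF, frame_fraction=0.2),
        "_trajectory": traj,
    }


# --- charge switch-off disassembly -----------------------------------------

def charge_switch_off_experiment(seed: int = 0, n_macroions: int = 4,
                                 n_charged: int = 16, box: float = 80.0,
                                 temperature: float = 300.0,
                                 pre_ps: float = 20.0,
                                 post_ps: float = 200.0) -> dict:
    """Disassembly of a preformed aggregate when all charges are zeroed.

    A compact macroion aggregate (tetrahedral contact arrangement) with its
    counterions is equilibrated with charges on, then every charge is set
    to zero and the run continues; the cluster count must increase as the
    aggregate falls apart, showing the binding was electrostatic.
    """
    template = MacroionTemplate(n_charged=n_charged, seed=seed)
    spec = SystemSpec(n_macroions=n_macroions, template=template,
                      n_solvent=0, box_length=box,
                      temperature=temperature, seed=seed)
    c = box / 2.0
    edge = 30.0
    verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float) * edge / (2 * np.sqrt(2.0))
    pins = c + verts[:n_macroions]
    config = assemble_system(spec, macroion_positions=pins)
    # an aggregated *charged* configuration needs its counterions bridging:
    # resample them into a shell around the aggregate instead of the bulk
    rng = np.random.default_rng(seed + 1000)
    from .system import SP_COUNTERION
    ci = np.flatnonzero(config.species == SP_COUNTERION)
    beads = config.positions[config.mol >= 0]
    for idx in ci:
        for _ in range(10_000):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            p = c + u * rng.uniform(5.0, 32.0)
            d2b = ((beads - p) ** 2).sum(axis=1).min()
            others = config.positions[ci[ci < idx]] if idx > ci[0] else None
            d2c = ((others - p) ** 2).sum(axis=1).min() \
                if others is not None and len(others) else np.inf
            if d2b > 16.0 and d2c > 16.0:
                config.positions[idx] = p
                break
    calc = ForceCalculator(coulomb="dsf", wca=True,
                           ewald=EwaldSettings(r_cut=20.0))
    minimize(config, calc, n_steps=100)
    sim = Simulation(config, calc, Protocol(
        ensemble="LANGEVIN", temperature=temperature, gamma_ps=1.0,
        n_steps=_steps(pre_ps), output_stride=0, log_stride=0, seed=seed))
    sim.run()
    before = cluster_aggregates(config.macroion_coms(), config.box,
                                CONTACT_CUTOFF)
    # switch every charge off: pure WCA repulsion remains
    config.charges[:] = 0.0
    calc_off = ForceCalculator(coulomb="none", wca=True)
    prot = Protocol(ensemble="LANGEVIN", temperature=temperature,
                    gamma_ps=0.1, n_steps=_steps(post_ps),
                    output_stride=_steps(1.0), log_stride=0, seed=seed + 1)
    sim = Simulation(config, calc_off, prot)
    traj = sim.run()
    after = cluster_aggregates(config.macroion_coms(), config.box,
                               CONTACT_CUTOFF)
    series = [cluster_aggregates(traj.macroion_coms(k), traj.frames[k].box,
                                 CONTACT_CUTOFF).n_clusters
              for k in range(traj.n_frames)]
    return {
        "clusters_before": before.n_clusters,
        "clusters_after": after.n_clusters,
        "cluster_series": series,
        "disassembled": after.n_clusters > before.n_clusters,
        "_trajectory": traj,
    }


# --- preset registry and runner --------------------------------------------

_TINY = {
    "solvent_diffusion": dict(n_solvent=250, equil_ps=20, prod_ps=100),
    "npt_density": dict(n_solvent=200, equil_ps=60, prod_ps=60),
    "two_macroion_forces": dict(equil_ps=10, prod_ps=40),
    "charge_sweep": dict(charge_counts=(0, 8), equil_ps=20, prod_ps=100),
    "uncharged_control": dict(n_macroions=4, equil_ps=10, prod_ps=40),
    "charge_switch_off": dict(pre_ps=10, post_ps=40),
}

PRESETS = {
    "solvent_diffusion": solvent_diffusion_experiment,
    "npt_density": npt_density_experiment,
    "two_macroion_forces": dimer_force_experiment,
    "charge_sweep": charge_sweep_experiment,
    "uncharged_control": uncharged_control_experiment,
    "charge_switch_off": charge_switch_off_experiment,
}


class UnknownPresetError(ValueError):
    def __init__(self, name: str):
        super().__init__(f"unknown preset {name!r}; available: "
                         + ", ".join(sorted(PRESETS)))


def _strip_private(obj):
    if isinstance(obj, dict):
        return {str(k): _strip_private(v) for k, v in obj.items()
                if not str(k).startswith("_")}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_preset(name: str, seed: int = 0, scale: str = "mini",
               outdir=".") -> dict:
    """Execute one preset and write results + manifest to ``outdir``.

    Fully determined by (name, seed, scale).  Returns the manifest dict.
    """
    if name not in PRESETS:
        raise UnknownPresetError(name)
    if scale not in ("mini", "tiny"):
        raise ValueError("scale must be 'mini' or 'tiny'")
    overrides = _TINY[name] if scale == "tiny" else {}
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    results = PRESETS[name](seed=seed, **overrides)
    wall = _time.time() - t0
    outputs = []

    res_path = outdir / f"{name}_results.json"
    with open(res_path, "w") as fh:
        json.dump(_strip_private(results), fh, indent=2, default=str)
    outputs.append(res_path.name)

    thermo = results.get("_thermo")
    if thermo is not None:
        tsv = outdir / f"{name}_thermo.tsv"
        _write_tsv(tsv, thermo, meta={"preset": name, "seed": seed,
                                      "scale": scale})
        outputs.append(tsv.name)
    traj = results.get("_trajectory")
    if isinstance(traj, Trajectory) and traj.n_frames:
        tpath = outdir / f"{name}_traj.xyz.gz"
        write_xyz(traj, tpath)
        outputs.append(tpath.name)

    from . import __version__
    manifest = {"preset": name, "seed": seed, "scale": scale,
                "version": __version__, "wall_time_s": round(wall, 2),
                "outputs": outputs,
                "results": _strip_private(results)}
    man_path = outdir / f"{name}_manifest.json"
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _write_tsv(path, columns: dict, meta: dict | None = None) -> None:
    """TSV with '#'-prefixed metadata header lines."""
    keys = list(columns)
    arrs = [np.atleast_1d(np.asarray(columns[k])) for k in keys]
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k} = {v}\n")
        fh.write("\t".join(keys) + "\n")
        for row in zip(*arrs):
            fh.write("\t".join(f"{v:.8g}" if isinstance(v, (float, np.floating))
                               else str(v) for v in row) + "\n")
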