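"""TOML configuration: load, validate, and print defaults.

A config file has up to four tables — ``[system]``, ``[forcefield]``,
``[protocol]``, ``[ewald]`` — whose keys map one-to-one onto
:class:`~macroioncg.builder.SystemSpec`, :class:`~macroioncg.builder.MacroionTemplate`,
:class:`~macroioncg.forcefield.ForceFieldParams`,
:class:`~macroioncg.integrators.Protocol` and
:class:`~macroioncg.ewald.EwaldSettings`.  Unknown keys are rejected by
name; every omitted key takes the documented default.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass

from .builder import MacroionTemplate, SystemSpec
from .ewald import EwaldSettings
from .forcefield import ForceFieldParams
from .integrators import Protocol


class ConfigError(ValueError):
    """Missing/unknown key or out-of-range value in a config file."""


_SYSTEM_KEYS = {
    "n_macroions", "diameter", "n_beads", "n_charged", "charge_selection",
    "placement", "template_seed", "n_solvent", "target_density",
    "box_length", "temperature", "pressure", "seed",
}
_FF_KEYS = {"epsilon", "sigma", "r_cut", "coulomb_constant", "bead_mass",
            "shift_lj"}
_PROTOCOL_KEYS = {"ensemble", "timestep_fs", "n_steps", "temperature",
                  "pressure", "tau_t_ps", "tau_p_ps", "gamma_ps",
                  "output_stride", "log_stride", "store_forces", "seed"}
_EWALD_KEYS = {"accuracy", "r_cut", "alpha", "nmax"}


@dataclass
class RunConfig:
    """Everything needed for one simulation run."""

    spec: SystemSpec
    params: ForceFieldParams
    protocol: Protocol
    ewald: EwaldSettings


def _check_keys(table: dict, allowed: set, section: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}")


def load_config(path) -> RunConfig:
    """Parse and validate a TOML run configuration."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    _check_keys(raw, {"system", "forcefield", "protocol", "ewald"}, "top level")
    sys_t = dict(raw.get("system", {}))
    ff_t = dict(raw.get("forcefield", {}))
    prot_t = dict(raw.get("protocol", {}))
    ew_t = dict(raw.get("ewald", {}))
    _check_keys(sys_t, _SYSTEM_KEYS, "system")
    _check_keys(ff_t, _FF_KEYS, "forcefield")
    _check_keys(prot_t, _PROTOCOL_KEYS, "protocol")
    _check_keys(ew_t, _EWALD_KEYS, "ewald")
    try:
        params = ForceFieldParams(**ff_t)
        template = MacroionTemplate(
            diameter=sys_t.pop("diameter", 25.0),
            n_beads=sys_t.pop("n_beads", 68),
            n_charged=sys_t.pop("n_charged", 20),
            placement_mode=sys_t.pop("placement", "fibonacci"),
            charge_selection_mode=sys_t.pop("charge_selection",
                                            "random_uniform"),
            seed=sys_t.pop("template_seed", 0))
        if "n_solvent" not in sys_t and "target_density" not in sys_t:
            sys_t["n_solvent"] = 0
        spec = SystemSpec(template=template, **sys_t)
        protocol = Protocol(**prot_t)
        ewald = EwaldSettings(accuracy=ew_t.get("accuracy", 1e-4),
                              r_cut=ew_t.get("r_cut", params.r_cut),
                              alpha=ew_t.get("alpha"),
                              nmax=ew_t.get("nmax"))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return RunConfig(spec=spec, params=params, protocol=protocol, ewald=ewald)


DEFAULT_CONFIG = """\
# macroion-cg run configuration (all values shown are the defaults)

[system]
n_macroions = 2          # rigid hollow-sphere macroions
diameter = 25.0          # A, bead-center shell diameter
n_beads = 68             # surface beads per macroion
n_charged = 20           # of which carry -1 e each
charge_selection = "random_uniform"   # or "max_spread"
placement = "fibonacci"
template_seed = 0
n_solvent = 0            # explicit CG solvent beads (or set target_density)
# target_density = 0.97  # g/cm^3; derives the solvent count from the box
box_length = 60.0        # A, cubic
temperature = 300.0      # K
pressure = 1.0           # bar
seed = 0

[forcefield]
epsilon = 4.5            # kJ/mol, all species pairs
sigma = 5.0              # A, all species pairs
r_cut = 15.0             # A, LJ truncation
bead_mass = 72.0         # g/mol (4:1 CG water mapping)
shift_lj = false         # energy-shift LJ to zero at r_cut

[protocol]
ensemble = "NVT"         # NVE | NVT | NPT | LANGEVIN
timestep_fs = 10.0
n_steps = 10000
temperature = 300.0
pressure = 1.0           # bar (NPT)
tau_t_ps = 1.0           # Berendsen thermostat coupling
tau_p_ps = 5.0           # Berendsen barostat coupling
gamma_ps = 1.0           # Langevin friction
output_stride = 100
log_stride = 100
store_forces = false     # keep decomposed per-particle forces in frames
seed = 0

[ewald]
accuracy = 1e-4          # target relative force accuracy
r_cut = 15.0             # real-space cutoff, A
# alpha = 0.2            # A^-1 (derived from accuracy when omitted)
# nmax = 8               # reciprocal extent (derived when omitted)
"""
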