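"""Internal unit system and physical constants.

The engine works in a self-consistent MD unit system:

==========  =======================  =========================
quantity    internal unit            notes
==========  =======================  =========================
length      angstrom (A)
time        picosecond (ps)
mass        g/mol
charge      elementary charge (e)
energy      (g/mol) A^2/ps^2         = 0.01 kJ/mol
velocity    A/ps
force       (g/mol) A/ps^2           = 0.01 kJ/mol/A
==========  =======================  =========================

With this choice Newton's equations need no conversion factors; user-facing
quantities (kJ/mol, bar, g/cm^3, cm^2/s) are converted at the API boundary.
"""

import numpy as np

#: 1 internal energy unit in kJ/mol
ENERGY_KJMOL = 0.01

#: kJ/mol -> internal energy
KJMOL = 1.0 / ENERGY_KJMOL

#: Boltzmann constant, kJ/mol/K
KB_KJMOL = 0.0083145

#: Boltzmann constant, internal energy per K
KB = KB_KJMOL * KJMOL  # 0.83145

#: Coulomb constant times e^2: k_q e^2 = 1389.35 kJ A / mol
KQ_KJMOL = 1389.35

#: Coulomb constant, internal units (energy*A per e^2)
KQ = KQ_KJMOL * KJMOL

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: 1 internal pressure unit (internal energy / A^3) in bar
PRESSURE_BAR = ENERGY_KJMOL * 1e3 / N_AVOGADRO / 1e-30 / 1e5  # ~166.054

#: mass density: (g/mol per A^3) -> g/cm^3
DENSITY_GCM3 = 1e24 / N_AVOGADRO  # ~1.66054

#: diffusion: A^2/ps -> cm^2/s
DIFFUSION_CM2S = 1e-4


def thermal_sigma_v(mass: float, temperature: float) -> float:
    """Std-dev of one velocity component (A/ps) at ``temperature`` (K)."""
    return np.sqrt(KB * temperature / mass)


def kinetic_temperature(kinetic_energy: float, n_dof: int) -> float:
    """Instantaneous temperature (K) from internal kinetic energy and DOF count."""
    if n_dof <= 0:
        return 0.0
    return 2.0 * kinetic_energy / (n_dof * KB)


def mass_density_gcm3(total_mass: float, volume_A3: float) -> float:
    """Mass density in g/cm^3 from total mass (g/mol) and volume (A^3)."""
    return total_mass / volume_A3 * DENSITY_GCM3
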