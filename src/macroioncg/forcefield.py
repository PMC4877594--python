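"""Pair interactions: 12-6 Lennard-Jones and Coulomb.

All beads — macroion surface beads, counterions and solvent — share a single
LJ parameter set (good-solvent conditions): by default epsilon = 4.5 kJ/mol
and sigma = 5 A for every species pair, truncated at r_c = 15 A.  Charged
species carry +-1 e and interact through the bare Coulomb potential
U = k_q q_a q_b / r (vacuum permittivity; the CG solvent is non-polar and
provides no dielectric screening).

The scalar functions here are the closed-form reference implementations used
for validation and for isolated (non-periodic) geometries; periodic systems
route through :mod:`macroioncg.forces`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .units import KQ_KJMOL


class SingularOverlapError(ValueError):
    """Two interaction sites at (numerically) zero separation."""


class PairEnergyForce(NamedTuple):
    """Energy (kJ/mol) and force magnitude (kJ/mol/A, positive = repulsive)."""

    energy: float
    force: float


@dataclass(frozen=True)
class ForceFieldParams:
    """Uniform CG force-field parameters.

    Parameters
    ----------
    epsilon : float
        LJ well depth, kJ/mol.
    sigma : float
        LJ size, A (also the contact diameter of every bead).
    r_cut : float
        LJ truncation radius, A.
    coulomb_constant : float
        k_q e^2 in kJ A/mol; charges are in units of e.
    bead_mass : float
        Mass of every CG bead, g/mol (4:1 water mapping convention).
    shift_lj : bool
        If True the LJ energy is shifted so U(r_cut) = 0 (strict-NVE mode);
        otherwise plain truncation.
    """

    epsilon: float = 4.5
    sigma: float = 5.0
    r_cut: float = 15.0
    coulomb_constant: float = KQ_KJMOL
    bead_mass: float = 72.0
    shift_lj: bool = False

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.r_cut <= self.sigma:
            raise ValueError("r_cut must exceed sigma")
        if self.coulomb_constant <= 0:
            raise ValueError("coulomb_constant must be > 0")
        if self.bead_mass <= 0:
            raise ValueError("bead_mass must be > 0")

    @property
    def lj_shift_energy(self) -> float:
        """Energy subtracted inside the cutoff when ``shift_lj`` is set."""
        if not self.shift_lj:
            return 0.0
        sr6 = (self.sigma / self.r_cut) ** 6
        return 4.0 * self.epsilon * (sr6 * sr6 - sr6)


def lj_pair(r: float, params: ForceFieldParams) -> PairEnergyForce:
    """LJ 12-6 energy/force of one pair at separation ``r`` (A)."""
    if r <= 0:
        raise SingularOverlapError("LJ pair at zero separation")
    if r >= params.r_cut:
        return PairEnergyForce(0.0, 0.0)
    sr6 = (params.sigma / r) ** 6
    energy = 4.0 * params.epsilon * (sr6 * sr6 - sr6) - params.lj_shift_energy
    force = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return PairEnergyForce(energy, force)


def coulomb_pair(
    r: float, q_a: float, q_b: float, coulomb_constant: float = KQ_KJMOL
) -> PairEnergyForce:
    """Bare (non-periodic) Coulomb energy/force of one charge pair."""
    if r <= 0:
        raise SingularOverlapError("Coulomb pair at zero separation")
    energy = coulomb_constant * q_a * q_b / r
    return PairEnergyForce(energy, energy / r)


def wca_cutoff(sigma: float) -> float:
    """Cutoff of the purely repulsive (WCA) form: the LJ minimum 2^(1/6) sigma."""
    return 2.0 ** (1.0 / 6.0) * sigma
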