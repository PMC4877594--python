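"""Force evaluation: LJ + electrostatics with energy decomposition.

:class:`ForceCalculator` owns the neighbor list and returns per-particle
force vectors split into a van der Waals and an electrostatic channel, the
matching energy decomposition, and the pairwise virial used for pressure.

Electrostatics modes
--------------------
``"ewald"``
    erfc-screened real-space pairs + reciprocal/self/exclusion terms
    (:mod:`macroioncg.ewald`); the default for charged periodic systems.
``"dsf"``
    damped-shifted-force truncation (Fennell/Gezelter), a pairwise O(N)
    scheme used for the implicit-solvent surrogate mode.
``"none"``
    chosen automatically when every charge is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import units
from ._kernels import (COUL_DSF, COUL_EWALD_REAL, COUL_NONE,
                       all_pairs_forces, build_neighbor_list, pair_forces)
from .ewald import EwaldSettings, ewald_long_range
from .forcefield import ForceFieldParams, SingularOverlapError, wca_cutoff
from .system import Configuration


@dataclass
class ForceResult:
    """Per-particle forces and energy decomposition (internal units)."""

    f_total: np.ndarray
    f_vdw: np.ndarray
    f_coul: np.ndarray
    e_vdw: float
    e_coul: float
    virial: float              # pairwise sum F.r (LJ + short-range coulomb)

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_coul

    @property
    def e_vdw_kjmol(self) -> float:
        return self.e_vdw * units.ENERGY_KJMOL

    @property
    def e_coul_kjmol(self) -> float:
        return self.e_coul * units.ENERGY_KJMOL


class NeighborList:
    """Verlet half list with a displacement-triggered rebuild."""

    def __init__(self, r_cut: float, skin: float = 2.0):
        self.r_cut = r_cut
        self.skin = skin
        self.neighbors: np.ndarray | None = None
        self.counts: np.ndarray | None = None
        self._ref_positions: np.ndarray | None = None
        self._max_neighbors = 64

    def needs_rebuild(self, positions: np.ndarray) -> bool:
        if self._ref_positions is None or \
                len(self._ref_positions) != len(positions):
            return True
        disp2 = np.max(np.sum((positions - self._ref_positions) ** 2, axis=1))
        return disp2 > (0.5 * self.skin) ** 2

    def build(self, config: Configuration) -> None:
        pos, _ = config.wrapped_positions()
        r_list = self.r_cut + self.skin
        while True:
            neighbors, counts, overflow = build_neighbor_list(
                pos, config.box, r_list, config.mol, self._max_neighbors)
            if not overflow:
                break
            self._max_neighbors *= 2
        self.neighbors, self.counts = neighbors, counts
        self._ref_positions = config.positions.copy()

    def update(self, config: Configuration) -> None:
        if self.needs_rebuild(config.positions):
            self.build(config)

    def pairs_of(self, i: int) -> np.ndarray:
        """All neighbors of particle i (both list directions), for inspection."""
        out = list(self.neighbors[i, :self.counts[i]])
        for j in range(len(self.counts)):
            if i in self.neighbors[j, :self.counts[j]]:
                out.append(j)
        return np.unique(np.array(out, dtype=np.int64))


class ForceCalculator:
    """Evaluate the CG force field on a configuration."""

    def __init__(self, params: ForceFieldParams | None = None,
                 coulomb: str = "auto",
                 ewald: EwaldSettings | None = None,
                 wca: bool = False,
                 skin: float = 2.0,
                 dsf_alpha: float = 0.1):
        self.params = params or ForceFieldParams()
        self.coulomb = coulomb
        self.ewald = ewald or EwaldSettings(r_cut=self.params.r_cut)
        # DSF damping is a physical smoothing choice, not an accuracy knob:
        # keep it gentle so contact ion pairs feel near-bare Coulomb forces
        self.dsf_alpha = dsf_alpha
        self.wca = wca
        p = self.params
        if wca:
            self.lj_rc = wca_cutoff(p.sigma)
            self.lj_shift = -p.epsilon * units.KJMOL  # U(rc) of plain LJ = -eps
        else:
            self.lj_rc = p.r_cut
            self.lj_shift = p.lj_shift_energy * units.KJMOL
        self.eps = p.epsilon * units.KJMOL
        self.kq = p.coulomb_constant * units.KJMOL
        self.nlist = NeighborList(max(self.lj_rc, self.ewald.r_cut), skin)

    def _mode(self, config: Configuration) -> int:
        mode = self.coulomb
        if mode == "auto":
            mode = "none" if not np.any(config.charges != 0.0) else "ewald"
        return {"none": COUL_NONE, "ewald": COUL_EWALD_REAL,
                "dsf": COUL_DSF}[mode]

    def compute(self, config: Configuration,
                all_pairs: bool = False) -> ForceResult:
        """Forces/energies; ``all_pairs=True`` bypasses the neighbor list
        (O(N^2) oracle path, identical physics)."""
        p = self.params
        mode = self._mode(config)
        alpha, _ = self.ewald.resolve(config.box)
        if mode == COUL_DSF:
            alpha = self.dsf_alpha
        n = config.n_particles
        f_vdw = np.zeros((n, 3))
        f_coul = np.zeros((n, 3))
        pos, _ = config.wrapped_positions()
        coul_rc = self.ewald.r_cut
        if all_pairs:
            e_vdw, e_coul, w_vdw, w_coul = all_pairs_forces(
                pos, config.box, config.charges, config.mol,
                self.eps, p.sigma, self.lj_rc, self.lj_shift,
                mode, alpha, self.kq, coul_rc, f_vdw, f_coul)
        else:
            self.nlist.update(config)
            e_vdw, e_coul, w_vdw, w_coul = pair_forces(
                pos, config.box, config.charges,
                self.nlist.neighbors, self.nlist.counts,
                self.eps, p.sigma, self.lj_rc, self.lj_shift,
                mode, alpha, self.kq, coul_rc, f_vdw, f_coul)
        if not np.isfinite(e_vdw) or not np.isfinite(e_coul):
            raise SingularOverlapError("overlapping particles (r < 1e-6 A)")
        if mode == COUL_EWALD_REAL:
            e_coul += ewald_long_range(config, self.ewald, f_coul)
        return ForceResult(f_total=f_vdw + f_coul, f_vdw=f_vdw, f_coul=f_coul,
                           e_vdw=e_vdw, e_coul=e_coul,
                           virial=w_vdw + w_coul)
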