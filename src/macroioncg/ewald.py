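"""Classical Ewald summation for periodic Coulomb interactions.

The conditionally convergent lattice sum is split into an erfc-screened
real-space part (evaluated in the pair kernel alongside LJ), a smooth
reciprocal-space part, the Gaussian self term, and corrections that remove
the smeared interaction between excluded (intra-rigid-body) charge pairs.
Tinfoil (conducting) boundary conditions; neutral systems only.

Parameters are tuned from a single target accuracy ``delta``:
``alpha = s / r_cut`` and ``k_max = 2 alpha s`` with ``s = sqrt(-ln delta)``,
the standard heuristic that balances real- and reciprocal-space truncation
errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erf

from . import units
from ._kernels import ewald_reciprocal
from .system import Configuration, NeutralityError


@dataclass
class EwaldSettings:
    """Accuracy/cutoff controls for the Ewald sum.

    ``alpha`` (A^-1) and ``nmax`` (reciprocal lattice extent) are derived
    from ``accuracy`` and the box unless given explicitly.
    """

    accuracy: float = 1e-4
    r_cut: float = 15.0
    alpha: float | None = None
    nmax: int | None = None

    def resolve(self, box: float) -> tuple[float, int]:
        s = np.sqrt(-np.log(self.accuracy))
        alpha = self.alpha if self.alpha is not None else s / self.r_cut
        if self.nmax is not None:
            nmax = self.nmax
        else:
            k_max = 2.0 * alpha * s
            nmax = max(1, int(np.ceil(k_max * box / (2.0 * np.pi))))
        return float(alpha), int(nmax)


def ewald_long_range(config: Configuration, settings: EwaldSettings,
                     forces_out: np.ndarray) -> float:
    """Reciprocal + self + exclusion terms; adds forces, returns energy.

    Energies/forces in internal units.  The companion real-space part must
    be evaluated with the same ``alpha`` (Coulomb mode ``COUL_EWALD_REAL``).
    """
    q = config.charges
    if abs(q.sum()) > 1e-9:
        raise NeutralityError(
            f"Ewald requires a neutral system (net charge {q.sum():g} e)")
    charged = np.flatnonzero(q != 0.0)
    if len(charged) == 0:
        return 0.0
    alpha, nmax = settings.resolve(config.box)
    pos, _ = config.wrapped_positions()
    sub_f = np.zeros((len(charged), 3))
    e_recip = ewald_reciprocal(
        np.ascontiguousarray(pos[charged]),
        np.ascontiguousarray(q[charged]),
        config.box, alpha, nmax, sub_f)
    e_recip *= units.KQ
    forces_out[charged] += units.KQ * sub_f

    e_self = -units.KQ * alpha / np.sqrt(np.pi) * np.sum(q[charged] ** 2)

    # remove the smeared interaction between excluded intra-body pairs
    e_excl = 0.0
    rb = config.rigid
    if rb is not None:
        for b in range(rb.n_bodies):
            idx = np.arange(rb.first[b], rb.first[b] + rb.n_beads)
            idx = idx[q[idx] != 0.0]
            if len(idx) < 2:
                continue
            ii, jj = np.triu_indices(len(idx), k=1)
            gi, gj = idx[ii], idx[jj]
            d = config.positions[gi] - config.positions[gj]  # intra-body: no pbc
            r = np.linalg.norm(d, axis=1)
            qq = q[gi] * q[gj]
            e_excl -= units.KQ * np.sum(qq * erf(alpha * r) / r)
            # smeared pair force on i: kq qq (erf/r^2 - 2a/sqrt(pi) e^{-a^2r^2}/r) rhat
            fmag = units.KQ * qq * (erf(alpha * r) / r ** 2
                                    - 2.0 * alpha / np.sqrt(np.pi)
                                    * np.exp(-(alpha * r) ** 2) / r) / r
            fv = fmag[:, None] * d
            np.add.at(forces_out, gi, -fv)
            np.add.at(forces_out, gj, fv)
    return float(e_recip + e_self + e_excl)
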