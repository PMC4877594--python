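"""Particle state: periodic configuration plus rigid-body bookkeeping.

A :class:`Configuration` holds every particle of the system — macroion
surface beads first (grouped by macroion), then counterions, then solvent —
in a cubic periodic box.  Rigid macroions are described by a
:class:`RigidBodies` block: body-frame bead coordinates in the principal-axis
frame, a unit quaternion, the center of mass, its velocity and the body-frame
angular momentum.  Bead positions are always derived from the body pose, so
rigidity is exact by construction.

Positions are stored *unwrapped*; :meth:`Configuration.wrapped_positions`
produces the minimum-image copy used by the force kernels and trajectory
writers, together with integer image counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# species codes
SP_BEAD_UNCHARGED = 0
SP_BEAD_CHARGED = 1
SP_COUNTERION = 2
SP_SOLVENT = 3

SPECIES_NAMES = {
    SP_BEAD_UNCHARGED: "macroion_bead_uncharged",
    SP_BEAD_CHARGED: "macroion_bead_charged",
    SP_COUNTERION: "counterion",
    SP_SOLVENT: "solvent",
}
SPECIES_CODES = {v: k for k, v in SPECIES_NAMES.items()}

#: short labels used in XYZ files
SPECIES_LABELS = {
    SP_BEAD_UNCHARGED: "MB",
    SP_BEAD_CHARGED: "MC",
    SP_COUNTERION: "CI",
    SP_SOLVENT: "SV",
}
LABEL_CODES = {v: k for k, v in SPECIES_LABELS.items()}


class NeutralityError(ValueError):
    """Total charge of a periodic system is not zero."""


@dataclass
class RigidBodies:
    """Pose and inertia of every rigid macroion.

    ``body_coords[b]`` are bead coordinates in the body principal-axis frame
    (COM at the origin, inertia tensor diagonal); beads of body ``b`` occupy
    configuration indices ``first[b] : first[b] + n_beads``.
    """

    body_coords: np.ndarray      # (n_bodies, n_beads, 3)
    first: np.ndarray            # (n_bodies,) int
    quat: np.ndarray             # (n_bodies, 4) unit, body->space
    com: np.ndarray              # (n_bodies, 3) unwrapped
    com_vel: np.ndarray          # (n_bodies, 3)
    ang_mom: np.ndarray          # (n_bodies, 3) body frame
    inertia: np.ndarray          # (n_bodies, 3) principal moments, g/mol A^2
    mass: np.ndarray             # (n_bodies,)

    @property
    def n_bodies(self) -> int:
        return len(self.first)

    @property
    def n_beads(self) -> int:
        return self.body_coords.shape[1]

    def copy(self) -> "RigidBodies":
        return RigidBodies(*(getattr(self, f).copy() for f in (
            "body_coords", "first", "quat", "com", "com_vel",
            "ang_mom", "inertia", "mass")))


def principal_frame(coords: np.ndarray, masses: np.ndarray):
    """Shift to COM and rotate into the principal-axis frame.

    Returns ``(body_coords, principal_moments, rotation)`` where ``rotation``
    maps original (COM-relative) coordinates to the principal frame.
    """
    com = np.average(coords, axis=0, weights=masses)
    rel = coords - com
    inertia = np.zeros((3, 3))
    for m, r in zip(masses, rel):
        inertia += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    moments, axes = np.linalg.eigh(inertia)
    if np.linalg.det(axes) < 0:  # keep a right-handed frame
        axes[:, 2] *= -1
    return rel @ axes, moments, axes.T


@dataclass
class Configuration:
    """Full particle state of one periodic system."""

    box: float
    positions: np.ndarray        # (N, 3) unwrapped
    velocities: np.ndarray       # (N, 3)
    charges: np.ndarray          # (N,) in e
    species: np.ndarray          # (N,) int8 codes
    mol: np.ndarray              # (N,) int32, -1 for free particles
    masses: np.ndarray           # (N,)
    rigid: RigidBodies | None = None
    time: float = 0.0            # ps

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def free_mask(self) -> np.ndarray:
        return self.mol < 0

    def wrapped_positions(self):
        """Minimum-image positions in [0, box) and integer image counts."""
        images = np.floor(self.positions / self.box).astype(np.int32)
        return self.positions - images * self.box, images

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def validate_neutral(self) -> None:
        if abs(self.total_charge()) > 1e-9:
            raise NeutralityError(
                f"system carries net charge {self.total_charge():g} e")

    def sync_rigid_beads(self) -> None:
        """Recompute bead positions/velocities from the rigid-body poses.

        Bodies are contiguous and uniform, so this is fully vectorised.
        """
        rb = self.rigid
        if rb is None:
            return
        from ._kernels import rigid_sync
        rigid_sync(rb.quat, rb.com, rb.com_vel, rb.ang_mom, rb.inertia,
                   rb.body_coords, self.positions, self.velocities)

    def kinetic_energy(self) -> float:
        """Total kinetic energy, internal units (translation + rotation)."""
        free = self.free_mask
        ke = 0.5 * np.sum(self.masses[free, None] * self.velocities[free] ** 2)
        rb = self.rigid
        if rb is not None:
            ke += 0.5 * np.sum(rb.mass[:, None] * rb.com_vel ** 2)
            with np.errstate(divide="ignore", invalid="ignore"):
                rot = np.where(rb.inertia > 1e-9,
                               rb.ang_mom ** 2 / np.maximum(rb.inertia, 1e-300), 0.0)
            ke += 0.5 * rot.sum()
        return float(ke)

    def n_dof(self, remove_com: bool = True) -> int:
        n = 3 * int(self.free_mask.sum())
        rb = self.rigid
        if rb is not None:
            n += 3 * rb.n_bodies
            n += int((rb.inertia > 1e-9).sum())
        if remove_com:
            n -= 3
        return n

    def total_momentum(self) -> np.ndarray:
        free = self.free_mask
        p = (self.masses[free, None] * self.velocities[free]).sum(axis=0)
        if self.rigid is not None:
            p = p + (self.rigid.mass[:, None] * self.rigid.com_vel).sum(axis=0)
        return p

    def total_mass(self) -> float:
        return float(self.masses.sum())

    def macroion_coms(self) -> np.ndarray:
        """Unwrapped macroion centers of mass, (n_bodies, 3)."""
        if self.rigid is None:
            return np.zeros((0, 3))
        return self.rigid.com.copy()

    def copy(self) -> "Configuration":
        return Configuration(
            box=self.box,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            charges=self.charges.copy(),
            species=self.species.copy(),
            mol=self.mol.copy(),
            masses=self.masses.copy(),
            rigid=self.rigid.copy() if self.rigid is not None else None,
            time=self.time,
        )

    # --- checkpointing -----------------------------------------------------

    def save_npz(self, path) -> None:
        data = dict(box=self.box, positions=self.positions,
                    velocities=self.velocities, charges=self.charges,
                    species=self.species, mol=self.mol, masses=self.masses,
                    time=self.time)
        if self.rigid is not None:
            for f in ("body_coords", "first", "quat", "com", "com_vel",
                      "ang_mom", "inertia", "mass"):
                data["rigid_" + f] = getattr(self.rigid, f)
        np.savez(path, **data)

    @classmethod
    def load_npz(cls, path) -> "Configuration":
        with np.load(path) as z:
            rigid = None
            if "rigid_first" in z:
                rigid = RigidBodies(
                    body_coords=z["rigid_body_coords"], first=z["rigid_first"],
                    quat=z["rigid_quat"], com=z["rigid_com"],
                    com_vel=z["rigid_com_vel"], ang_mom=z["rigid_ang_mom"],
                    inertia=z["rigid_inertia"], mass=z["rigid_mass"])
            return cls(box=float(z["box"]), positions=z["positions"],
                       velocities=z["velocities"], charges=z["charges"],
                       species=z["species"], mol=z["mol"], masses=z["masses"],
                       rigid=rigid, time=float(z["time"]))
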