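"""System assembly: macroion templates, charge placement, packing.

A macroion is a rigid hollow sphere of CG beads: ``n_beads`` bead centers on
a shell of radius ``diameter/2`` (25 A diameter by default, the size of a
typical Keplerate-type metal-oxide cluster), of which ``n_charged`` carry
-1 e each.  Electrical neutrality is enforced by construction: every
assembled system receives exactly one +1 e counterion per charged surface
bead.  Solvent is a neutral CG bead fluid (one bead ~ four waters,
72 g/mol).

Assembly inserts macroions, then counterions, then solvent by rejection
sampling against a minimum-separation rule, and draws Maxwell-Boltzmann
velocities with the net momentum removed.  Everything is reproducible from
``SystemSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import units
from .forcefield import ForceFieldParams
from .geometry import place_beads_on_sphere, random_quaternion
from .system import (SP_BEAD_CHARGED, SP_BEAD_UNCHARGED, SP_COUNTERION,
                     SP_SOLVENT, Configuration, RigidBodies, principal_frame)

__all__ = [
    "MacroionTemplate", "Macroion", "SystemSpec", "PackingError",
    "select_charged_beads", "required_counterions",
    "solvent_count_for_density", "assemble_system",
]


class PackingError(RuntimeError):
    """Rejection sampling failed to place a particle (density too high)."""


@dataclass(frozen=True)
class MacroionTemplate:
    """Geometry and charge pattern of one macroion species."""

    diameter: float = 25.0
    n_beads: int = 68
    n_charged: int = 20
    charge_per_bead: float = -1.0
    placement_mode: str = "fibonacci"
    charge_selection_mode: str = "random_uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if not 0 <= self.n_charged <= self.n_beads:
            raise ValueError("need 0 <= n_charged <= n_beads")
        if self.n_charged > 0 and abs(self.charge_per_bead) != 1.0:
            raise ValueError("charged surface beads carry exactly 1 e")
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def total_charge(self) -> float:
        return self.n_charged * self.charge_per_bead


@dataclass
class Macroion:
    """One rigid macroion instance (body-frame geometry plus pose)."""

    bead_offsets: np.ndarray          # (n_beads, 3), |offset| = diameter/2
    bead_charges: np.ndarray          # (n_beads,)
    center: np.ndarray
    orientation: np.ndarray           # unit quaternion
    com_velocity: np.ndarray
    angular_momentum: np.ndarray      # body frame


def select_charged_beads(template: MacroionTemplate) -> np.ndarray:
    """Indices of the charged beads on the template shell.

    ``random_uniform`` draws without replacement from the template seed;
    ``max_spread`` greedily maximises the minimal pairwise angular
    separation (deterministic: starts from bead 0).
    """
    n, k = template.n_beads, template.n_charged
    if k == 0:
        return np.empty(0, dtype=np.int64)
    if k == n:
        return np.arange(n, dtype=np.int64)
    if template.charge_selection_mode == "random_uniform":
        rng = np.random.default_rng(template.seed)
        return np.sort(rng.choice(n, size=k, replace=False)).astype(np.int64)
    if template.charge_selection_mode == "max_spread":
        pts = place_beads_on_sphere(n, 1.0, template.placement_mode)
        chosen = [0]
        cos_min = pts @ pts[0]            # running max-cos (min angle) to chosen set
        cos_min[0] = 2.0                  # chosen beads are unpickable
        for _ in range(k - 1):
            nxt = int(np.argmin(cos_min))
            chosen.append(nxt)
            cos_min = np.maximum(cos_min, pts @ pts[nxt])
            cos_min[chosen] = 2.0
        return np.sort(np.array(chosen, dtype=np.int64))
    raise ValueError(
        f"unknown charge_selection_mode {template.charge_selection_mode!r}")


def build_macroion(template: MacroionTemplate) -> Macroion:
    """Instantiate a template at the origin with identity orientation."""
    offsets = place_beads_on_sphere(
        template.n_beads, template.radius, template.placement_mode)
    charges = np.zeros(template.n_beads)
    charges[select_charged_beads(template)] = template.charge_per_bead
    return Macroion(
        bead_offsets=offsets, bead_charges=charges,
        center=np.zeros(3), orientation=np.array([1.0, 0, 0, 0]),
        com_velocity=np.zeros(3), angular_momentum=np.zeros(3))


@dataclass(frozen=True)
class SystemSpec:
    """Composition and thermodynamic state of one system to assemble."""

    n_macroions: int = 0
    template: MacroionTemplate = MacroionTemplate()
    n_solvent: int | None = None
    target_density: float | None = None   # g/cm^3, overrides n_solvent
    box_length: float = 50.0
    temperature: float = 300.0
    pressure: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_macroions < 0:
            raise ValueError("n_macroions must be >= 0")
        if self.box_length <= 0:
            raise ValueError("box_length must be positive")
        if self.n_solvent is None and self.target_density is None:
            raise ValueError("give n_solvent or target_density")


def required_counterions(spec: SystemSpec) -> int:
    """One +1 e counterion per charged surface bead (exact neutrality)."""
    return spec.n_macroions * spec.template.n_charged


def solvent_count_for_density(density: float, box_length: float,
                              bead_mass: float = 72.0,
                              occupied_mass: float = 0.0) -> int:
    """Bead count giving mass density ``density`` (g/cm^3) in a cubic box.

    ``occupied_mass`` (g/mol) already present in the box is subtracted.
    """
    total = density * box_length ** 3 / units.DENSITY_GCM3
    return max(0, int(round((total - occupied_mass) / bead_mass)))


def _min_image_dist2(delta: np.ndarray, box: float) -> np.ndarray:
    delta = delta - box * np.round(delta / box)
    return np.einsum("ij,ij->i", delta, delta)


def assemble_system(spec: SystemSpec,
                    params: ForceFieldParams | None = None,
                    max_attempts: int = 10_000,
                    min_separation_factor: float = 0.8,
                    macroion_positions: np.ndarray | None = None) -> Configuration:
    """Build a neutral, overlap-free periodic Configuration.

    Macroions are inserted first (random COM + uniform random orientation,
    rejected if any bead comes within ``min_separation_factor * sigma`` of an
    existing particle), then counterions, then solvent.  Velocities are
    Maxwell-Boltzmann at ``spec.temperature`` with net momentum removed.

    ``macroion_positions`` pins the macroion COMs (e.g. a contact dimer or a
    preformed aggregate); orientations are still sampled, with rejection
    against bead overlap only.
    """
    params = params or ForceFieldParams()
    if spec.box_length < 2.0 * params.r_cut and spec.n_macroions > 0:
        # analysis-only toy boxes may be smaller; warn via exception only for
        # real systems where the minimum-image force loop would be invalid
        raise ValueError("box_length must be at least 2 * r_cut")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    L = spec.box_length
    min_d2 = (min_separation_factor * params.sigma) ** 2
    tpl = spec.template
    proto = build_macroion(tpl) if spec.n_macroions > 0 else None

    placed: list[np.ndarray] = []       # flat list of accepted positions
    occupied = np.zeros((0, 3))

    def ok(points: np.ndarray) -> bool:
        if len(occupied) == 0:
            return True
        for p in np.atleast_2d(points):
            if (_min_image_dist2(occupied - p, L) < min_d2).any():
                return False
        return True

    def grow(points: np.ndarray) -> None:
        nonlocal occupied
        occupied = np.vstack([occupied, np.atleast_2d(points)])

    # rigid bodies
    n_b = tpl.n_beads
    quats = np.zeros((spec.n_macroions, 4))
    coms = np.zeros((spec.n_macroions, 3))
    bead_positions = []
    from .geometry import quat_to_matrix
    for b in range(spec.n_macroions):
        for attempt in range(max_attempts):
            if macroion_positions is not None:
                com = np.asarray(macroion_positions[b], dtype=float)
            else:
                com = rng.random(3) * L
            q = random_quaternion(rng)
            beads = com + proto.bead_offsets @ quat_to_matrix(q).T
            # internal bead spacing is fixed by the template; only check
            # against previously placed particles
            if ok(beads):
                quats[b], coms[b] = q, com
                bead_positions.append(beads)
                grow(beads)
                break
        else:
            raise PackingError(f"could not place macroion {b}")

    n_ci = required_counterions(spec)
    for i in range(n_ci):
        for attempt in range(max_attempts):
            p = rng.random(3) * L
            if ok(p):
                placed.append(p)
                grow(p)
                break
        else:
            raise PackingError(f"could not place counterion {i}")

    if spec.target_density is not None:
        occupied_mass = (spec.n_macroions * n_b + n_ci) * params.bead_mass
        n_sv = solvent_count_for_density(
            spec.target_density, L, params.bead_mass, occupied_mass)
    else:
        n_sv = spec.n_solvent or 0
    for i in range(n_sv):
        for attempt in range(max_attempts):
            p = rng.random(3) * L
            if ok(p):
                placed.append(p)
                grow(p)
                break
        else:
            raise PackingError(f"could not place solvent bead {i}")

    # --- flatten state -----------------------------------------------------
    n_bead_tot = spec.n_macroions * n_b
    n_total = n_bead_tot + n_ci + n_sv
    positions = np.zeros((n_total, 3))
    charges = np.zeros(n_total)
    species = np.zeros(n_total, dtype=np.int8)
    mol = np.full(n_total, -1, dtype=np.int32)
    masses = np.full(n_total, params.bead_mass)

    rigid = None
    if spec.n_macroions > 0:
        bead_masses = np.full(n_b, params.bead_mass)
        body_coords, moments, to_principal = principal_frame(
            proto.bead_offsets, bead_masses)
        # charge pattern follows the bead ordering, which principal_frame keeps
        for b in range(spec.n_macroions):
            sl = slice(b * n_b, (b + 1) * n_b)
            positions[sl] = bead_positions[b]
            charges[sl] = proto.bead_charges
            species[sl] = np.where(proto.bead_charges != 0.0,
                                   SP_BEAD_CHARGED, SP_BEAD_UNCHARGED)
            mol[sl] = b
        # orientation: body_coords are principal-frame; pose quaternion must
        # reproduce the placed beads:  beads = com + R(q_pose) P rel
        # where P = to_principal.  R(q_pose) P = R(q_place) =>
        # recompute body pose rotation matrix directly.
        quat_pose = np.zeros((spec.n_macroions, 4))
        for b in range(spec.n_macroions):
            rot = quat_to_matrix(quats[b]) @ to_principal.T
            quat_pose[b] = _matrix_to_quat(rot)
        rigid = RigidBodies(
            body_coords=np.repeat(body_coords[None], spec.n_macroions, axis=0),
            first=np.arange(spec.n_macroions, dtype=np.int64) * n_b,
            quat=quat_pose, com=coms,
            com_vel=np.zeros((spec.n_macroions, 3)),
            ang_mom=np.zeros((spec.n_macroions, 3)),
            inertia=np.repeat(moments[None], spec.n_macroions, axis=0),
            mass=np.full(spec.n_macroions, n_b * params.bead_mass))

    if n_ci:
        sl = slice(n_bead_tot, n_bead_tot + n_ci)
        positions[sl] = placed[:n_ci]
        charges[sl] = 1.0
        species[sl] = SP_COUNTERION
    if n_sv:
        sl = slice(n_bead_tot + n_ci, n_total)
        positions[sl] = placed[n_ci:]
        species[sl] = SP_SOLVENT

    config = Configuration(box=L, positions=positions,
                           velocities=np.zeros((n_total, 3)),
                           charges=charges, species=species, mol=mol,
                           masses=masses, rigid=rigid)
    _draw_velocities(config, spec.temperature, rng)
    config.sync_rigid_beads()
    config.validate_neutral()
    return config


def _matrix_to_quat(rot: np.ndarray) -> np.ndarray:
    """Rotation matrix -> unit quaternion (w, x, y, z)."""
    t = np.trace(rot)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        w = 0.25 * s
        x = (rot[2, 1] - rot[1, 2]) / s
        y = (rot[0, 2] - rot[2, 0]) / s
        z = (rot[1, 0] - rot[0, 1]) / s
    else:
        i = int(np.argmax(np.diag(rot)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(rot[i, i] - rot[j, j] - rot[k, k] + 1.0) * 2
        qv = np.zeros(3)
        qv[i] = 0.25 * s
        qv[j] = (rot[j, i] + rot[i, j]) / s
        qv[k] = (rot[k, i] + rot[i, k]) / s
        w = (rot[k, j] - rot[j, k]) / s
        x, y, z = qv
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)


def _draw_velocities(config: Configuration, temperature: float,
                     rng: np.random.Generator) -> None:
    """Maxwell-Boltzmann velocities; exact zero net momentum."""
    free = config.free_mask
    n_free = int(free.sum())
    if n_free:
        sigma = np.sqrt(units.KB * temperature / config.masses[free])
        config.velocities[free] = rng.standard_normal((n_free, 3)) * sigma[:, None]
    rb = config.rigid
    if rb is not None:
        sig_v = np.sqrt(units.KB * temperature / rb.mass)
        rb.com_vel[:] = rng.standard_normal((rb.n_bodies, 3)) * sig_v[:, None]
        sig_l = np.sqrt(units.KB * temperature * np.maximum(rb.inertia, 0.0))
        rb.ang_mom[:] = rng.standard_normal((rb.n_bodies, 3)) * sig_l
        rb.ang_mom[rb.inertia <= 1e-9] = 0.0
    # remove net momentum
    p = config.total_momentum()
    m_tot = config.total_mass()
    if m_tot > 0:
        dv = p / m_tot
        config.velocities[free] -= dv
        if rb is not None:
            rb.com_vel -= dv
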