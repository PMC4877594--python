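"""Trajectory container and text formats (extended XYZ, LAMMPS dump).

Extended XYZ is the native format: self-describing per-atom columns
(species label, position, charge, molecule id, image flags, optional
decomposed force channels) plus the box and per-frame energies in the
comment line.  A LAMMPS-dump writer/reader is provided for interoperability
with the wider ecosystem; the reader tolerates arbitrary column order.
Both support gzip transparently via a ``.gz`` suffix.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field

import numpy as np

from .system import LABEL_CODES, SPECIES_LABELS


class TrajectoryReadError(RuntimeError):
    """Malformed or truncated trajectory file.

    ``last_good_frame`` is the index of the last frame read completely
    (-1 if none).
    """

    def __init__(self, message: str, last_good_frame: int = -1):
        super().__init__(message)
        self.last_good_frame = last_good_frame


class UnwrapError(RuntimeError):
    """MSD-style analysis asked for unwrapped coordinates, none available."""


@dataclass
class Frame:
    """One snapshot: box, wrapped positions, image counts, optional forces."""

    box: float
    time: float
    positions: np.ndarray
    images: np.ndarray | None = None
    f_vdw: np.ndarray | None = None       # kJ/mol/A
    f_coul: np.ndarray | None = None
    e_vdw: float | None = None            # kJ/mol, whole system
    e_coul: float | None = None

    def unwrapped(self) -> np.ndarray:
        if self.images is None:
            raise UnwrapError("frame stores no image flags")
        return self.positions + self.images * self.box


@dataclass
class Trajectory:
    """Frame sequence with constant per-particle metadata."""

    species: np.ndarray
    mol: np.ndarray
    charges: np.ndarray
    frames: list[Frame] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_particles(self) -> int:
        return len(self.species)

    def append(self, frame: Frame) -> None:
        if len(frame.positions) != self.n_particles:
            raise ValueError("frame atom count mismatch")
        self.frames.append(frame)

    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def unwrapped(self, k: int) -> np.ndarray:
        return self.frames[k].unwrapped()

    # --- species selection -------------------------------------------------

    def select(self, species_name: str) -> np.ndarray:
        """Particle indices of one species name (see system.SPECIES_NAMES).

        The pseudo-species ``"macroion"`` is resolved by
        :meth:`macroion_coms`, not here.
        """
        from .system import SPECIES_CODES
        if species_name == "macroion_bead":
            return np.flatnonzero(self.species <= 1)
        return np.flatnonzero(self.species == SPECIES_CODES[species_name])

    def n_macroions(self) -> int:
        m = self.mol[self.mol >= 0]
        return 0 if len(m) == 0 else int(m.max()) + 1

    def macroion_coms(self, k: int, unwrapped: bool = True) -> np.ndarray:
        """Macroion centers of mass in frame ``k`` (equal bead masses).

        With image flags present the COM is exact and unwrapped; otherwise
        beads are unwrapped around the body's first bead by minimum image
        (valid while the body is much smaller than half the box).
        """
        frame = self.frames[k]
        n_mac = self.n_macroions()
        coms = np.zeros((n_mac, 3))
        if frame.images is not None:
            pos = frame.unwrapped()
            for b in range(n_mac):
                coms[b] = pos[self.mol == b].mean(axis=0)
        else:
            L = frame.box
            for b in range(n_mac):
                beads = frame.positions[self.mol == b]
                rel = beads - beads[0]
                rel -= L * np.round(rel / L)
                coms[b] = beads[0] + rel.mean(axis=0)
        if not unwrapped:
            coms -= np.floor(coms / frame.box) * frame.box
        return coms

    def positions_of(self, species_name: str, k: int,
                     unwrapped: bool = False) -> np.ndarray:
        """Coordinates of one species in frame ``k``; ``"macroion"`` means
        the rigid-body centers of mass."""
        if species_name == "macroion":
            return self.macroion_coms(k, unwrapped=unwrapped)
        idx = self.select(species_name)
        frame = self.frames[k]
        return (frame.unwrapped() if unwrapped else frame.positions)[idx]


def _opener(path, mode):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


# --- extended XYZ ----------------------------------------------------------

def write_xyz(traj: Trajectory, path) -> None:
    with _opener(path, "w") as fh:
        for frame in traj.frames:
            props = "species:S:1:pos:R:3:charge:R:1:mol:I:1"
            if frame.images is not None:
                props += ":image:I:3"
            if frame.f_vdw is not None:
                props += ":force_vdw:R:3:force_coul:R:3"
            fh.write(f"{traj.n_particles}\n")
            comment = (f'Lattice="{frame.box:.8f} 0.0 0.0 0.0 '
                       f'{frame.box:.8f} 0.0 0.0 0.0 {frame.box:.8f}" '
                       f'Properties={props} Time={frame.time:.6f}')
            if frame.e_vdw is not None:
                comment += f" E_vdw={frame.e_vdw:.8f}"
            if frame.e_coul is not None:
                comment += f" E_coul={frame.e_coul:.8f}"
            fh.write(comment + "\n")
            for i in range(traj.n_particles):
                row = [SPECIES_LABELS[int(traj.species[i])],
                       f"{frame.positions[i,0]:.8f}",
                       f"{frame.positions[i,1]:.8f}",
                       f"{frame.positions[i,2]:.8f}",
                       f"{traj.charges[i]:.4f}",
                       str(int(traj.mol[i]))]
                if frame.images is not None:
                    row += [str(int(v)) for v in frame.images[i]]
                if frame.f_vdw is not None:
                    row += [f"{v:.8e}" for v in frame.f_vdw[i]]
                    row += [f"{v:.8e}" for v in frame.f_coul[i]]
                fh.write(" ".join(row) + "\n")


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_PROPS_RE = re.compile(r'Properties=(\S+)')
_KV_RE = re.compile(r'(\w+)=([-\d.eE+]+)')


def read_xyz(path) -> Trajectory:
    frames: list[Frame] = []
    species = mol = charges = None
    with _opener(path, "r") as fh:
        lines = fh.read().splitlines()
    i = 0
    k = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryReadError(
                f"bad atom-count line at frame {k}", last_good_frame=k - 1)
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise TrajectoryReadError(
                f"truncated frame {k}", last_good_frame=k - 1)
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise TrajectoryReadError(
                f"frame {k}: missing Lattice", last_good_frame=k - 1)
        lat = [float(v) for v in m.group(1).split()]
        box = lat[0]
        pm = _PROPS_RE.search(comment)
        if not pm:
            raise TrajectoryReadError(
                f"frame {k}: missing Properties", last_good_frame=k - 1)
        fields = pm.group(1).split(":")
        layout = []  # (name, kind, ncol)
        for j in range(0, len(fields), 3):
            layout.append((fields[j], fields[j + 1], int(fields[j + 2])))
        kv = dict(_KV_RE.findall(comment.split('"')[-1]))
        time = float(kv.get("Time", 0.0))
        body = lines[i + 2:i + 2 + n]
        if len(body) < n:
            raise TrajectoryReadError(
                f"truncated frame {k}", last_good_frame=k - 1)
        sp = np.zeros(n, dtype=np.int8)
        mo = np.zeros(n, dtype=np.int32)
        ch = np.zeros(n)
        pos = np.zeros((n, 3))
        img = None
        fvdw = fcoul = None
        col_of = {}
        c = 0
        for name, kind, ncol in layout:
            col_of[name] = (c, ncol)
            c += ncol
        if "image" in col_of:
            img = np.zeros((n, 3), dtype=np.int32)
        if "force_vdw" in col_of:
            fvdw = np.zeros((n, 3))
            fcoul = np.zeros((n, 3))
        for a, line in enumerate(body):
            tok = line.split()
            if len(tok) < c:
                raise TrajectoryReadError(
                    f"frame {k}: short atom line {a}", last_good_frame=k - 1)
            s0, _ = col_of["species"]
            sp[a] = LABEL_CODES[tok[s0]]
            p0, _ = col_of["pos"]
            pos[a] = [float(tok[p0 + d]) for d in range(3)]
            if "charge" in col_of:
                ch[a] = float(tok[col_of["charge"][0]])
            if "mol" in col_of:
                mo[a] = int(tok[col_of["mol"][0]])
            if img is not None:
                i0 = col_of["image"][0]
                img[a] = [int(tok[i0 + d]) for d in range(3)]
            if fvdw is not None:
                v0 = col_of["force_vdw"][0]
                c0 = col_of["force_coul"][0]
                fvdw[a] = [float(tok[v0 + d]) for d in range(3)]
                fcoul[a] = [float(tok[c0 + d]) for d in range(3)]
        if species is None:
            species, mol, charges = sp, mo, ch
        elif n != len(species):
            raise TrajectoryReadError(
                f"frame {k}: atom count changed", last_good_frame=k - 1)
        frames.append(Frame(box=box, time=time, positions=pos, images=img,
                            f_vdw=fvdw, f_coul=fcoul,
                            e_vdw=float(kv["E_vdw"]) if "E_vdw" in kv else None,
                            e_coul=float(kv["E_coul"]) if "E_coul" in kv else None))
        i += 2 + n
        k += 1
    if species is None:
        raise TrajectoryReadError("empty trajectory file")
    return Trajectory(species=species, mol=mol, charges=charges, frames=frames)


# --- LAMMPS dump -----------------------------------------------------------

def write_lammps_dump(traj: Trajectory, path) -> None:
    with _opener(path, "w") as fh:
        for k, frame in enumerate(traj.frames):
            fh.write("ITEM: TIMESTEP\n%d\n" % k)
            fh.write("ITEM: NUMBER OF ATOMS\n%d\n" % traj.n_particles)
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for _ in range(3):
                fh.write(f"0.0 {frame.box:.8f}\n")
            cols = "id type mol q x y z"
            if frame.images is not None:
                cols += " ix iy iz"
            if frame.f_vdw is not None:
                cols += " fvx fvy fvz fcx fcy fcz"
            fh.write("ITEM: ATOMS " + cols + "\n")
            for i in range(traj.n_particles):
                row = [str(i + 1), str(int(traj.species[i]) + 1),
                       str(int(traj.mol[i])), f"{traj.charges[i]:.4f}",
                       f"{frame.positions[i,0]:.8f}",
                       f"{frame.positions[i,1]:.8f}",
                       f"{frame.positions[i,2]:.8f}"]
                if frame.images is not None:
                    row += [str(int(v)) for v in frame.images[i]]
                if frame.f_vdw is not None:
                    row += [f"{v:.8e}" for v in frame.f_vdw[i]]
                    row += [f"{v:.8e}" for v in frame.f_coul[i]]
                fh.write(" ".join(row) + "\n")


def read_lammps_dump(path) -> Trajectory:
    frames: list[Frame] = []
    species = mol = charges = None
    with _opener(path, "r") as fh:
        lines = fh.read().splitlines()
    i = 0
    k = 0
    try:
        while i < len(lines):
            if not lines[i].startswith("ITEM: TIMESTEP"):
                if not lines[i].strip():
                    i += 1
                    continue
                raise TrajectoryReadError(
                    f"frame {k}: expected TIMESTEP", last_good_frame=k - 1)
            step = int(lines[i + 1])
            assert lines[i + 2].startswith("ITEM: NUMBER OF ATOMS")
            n = int(lines[i + 3])
            assert lines[i + 4].startswith("ITEM: BOX BOUNDS")
            lo, hi = (float(v) for v in lines[i + 5].split()[:2])
            box = hi - lo
            header = lines[i + 8].split()
            assert header[:2] == ["ITEM:", "ATOMS"]
            names = header[2:]
            col = {nm: c for c, nm in enumerate(names)}
            body = lines[i + 9:i + 9 + n]
            if len(body) < n:
                raise TrajectoryReadError(
                    f"truncated frame {k}", last_good_frame=k - 1)
            sp = np.zeros(n, dtype=np.int8)
            mo = np.zeros(n, dtype=np.int32)
            ch = np.zeros(n)
            pos = np.zeros((n, 3))
            img = np.zeros((n, 3), dtype=np.int32) if "ix" in col else None
            fvdw = np.zeros((n, 3)) if "fvx" in col else None
            fcoul = np.zeros((n, 3)) if "fcx" in col else None
            for line in body:
                tok = line.split()
                a = int(tok[col["id"]]) - 1
                sp[a] = int(tok[col["type"]]) - 1
                mo[a] = int(tok[col["mol"]]) if "mol" in col else -1
                ch[a] = float(tok[col["q"]]) if "q" in col else 0.0
                pos[a] = [float(tok[col[c]]) for c in ("x", "y", "z")]
                if img is not None:
                    img[a] = [int(tok[col[c]]) for c in ("ix", "iy", "iz")]
                if fvdw is not None:
                    fvdw[a] = [float(tok[col[c]]) for c in ("fvx", "fvy", "fvz")]
                if fcoul is not None:
                    fcoul[a] = [float(tok[col[c]]) for c in ("fcx", "fcy", "fcz")]
            if species is None:
                species, mol, charges = sp, mo, ch
            elif n != len(species):
                raise TrajectoryReadError(
                    f"frame {k}: atom count changed", last_good_frame=k - 1)
            frames.append(Frame(box=box, time=float(step), positions=pos,
                                images=img, f_vdw=fvdw, f_coul=fcoul))
            i += 9 + n
            k += 1
    except (IndexError, ValueError, AssertionError) as exc:
        raise TrajectoryReadError(
            f"truncated or malformed frame {k}",
            last_good_frame=k - 1) from exc
    if species is None:
        raise TrajectoryReadError("empty trajectory file")
    return Trajectory(species=species, mol=mol, charges=charges, frames=frames)
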