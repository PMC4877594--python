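"""Trajectory measurements: g(r), coordination, MSD/diffusion, forces,
clustering, energy-distance profiles.

Macroion positions are rigid-body centers of mass throughout.  Distances use
the minimum-image convention; MSD uses unwrapped coordinates (image flags).

The first coordination shell of 25 A macroions shows up in g(r) as two
close-range peaks — direct contact, and contact bridged by one solvent bead
or counterion — so the first-shell limit for neighbor counting is the first
local minimum of the smoothed g(r) after those peaks (searched between 25
and 50 A), or an explicit radius.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .trajectory import Trajectory

__all__ = [
    "RDFResult", "MSDResult", "ForceTrace", "ClusterResult",
    "compute_rdf", "coordination_number", "compute_msd",
    "diffusion_coefficient", "radial_projection", "macroion_force_series",
    "cluster_aggregates", "energy_distance_profile",
    "mean_first_neighbor_count",
]


def _min_image(delta: np.ndarray, box: float) -> np.ndarray:
    return delta - box * np.round(delta / box)


def _pair_distances(a: np.ndarray, b: np.ndarray | None, box: float) -> np.ndarray:
    """Minimum-image distances: all a-b pairs, or all distinct a-a pairs."""
    if b is None:
        ii, jj = np.triu_indices(len(a), k=1)
        d = _min_image(a[ii] - a[jj], box)
    else:
        d = _min_image(a[:, None, :] - b[None, :, :], box).reshape(-1, 3)
    return np.sqrt((d ** 2).sum(axis=-1))


# --- radial distribution function -----------------------------------------

@dataclass
class RDFResult:
    """Ideal-gas-normalised pair correlation g(r)."""

    r: np.ndarray                 # bin centers, A
    g: np.ndarray
    species_pair: tuple
    density: float                # number density of species b, 1/A^3
    n_reference: int              # particles of species a per frame
    n_frames: int
    bin_width: float

    def first_peak(self) -> tuple:
        """(r, g) of the global maximum (the contact peak in practice)."""
        k = int(np.argmax(self.g))
        return float(self.r[k]), float(self.g[k])


class GeometryError(ValueError):
    """r_max beyond half the box (minimum image would alias)."""


def compute_rdf(traj: Trajectory, species_a: str, species_b: str | None = None,
                bin_width: float = 0.5, r_max: float | None = None) -> RDFResult:
    """Frame-averaged g(r) between two species (``"macroion"`` = COMs)."""
    species_b = species_b or species_a
    same = species_a == species_b
    box = traj.frames[0].box
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-9:
        raise GeometryError(f"r_max {r_max} exceeds half the box {box/2}")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    hist = np.zeros(len(edges) - 1)
    n_a = n_b = 0
    for k in range(traj.n_frames):
        a = traj.positions_of(species_a, k)
        b = None if same else traj.positions_of(species_b, k)
        n_a, n_b = len(a), len(a) if same else len(b)
        if n_a == 0 or n_b == 0:
            raise ValueError("empty species selection")
        r = _pair_distances(a, b, box)
        h, _ = np.histogram(r, bins=edges)
        hist += 2.0 * h if same else h
    volume = box ** 3
    rho_b = n_b / volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # conventional normalisation with rho = N_b/V: for a homogeneous system
    # rho * integral 4 pi r^2 g dr over all r equals N_b - 1 (same species)
    ideal = rho_b * shell * n_a * traj.n_frames
    g = np.where(ideal > 0, hist / np.maximum(ideal, 1e-300), 0.0)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=centers, g=g, species_pair=(species_a, species_b),
                     density=rho_b, n_reference=n_a, n_frames=traj.n_frames,
                     bin_width=bin_width)


class ShellLimitError(RuntimeError):
    """Automatic first-shell search found no local minimum."""


def coordination_number(rdf: RDFResult, r_limit: float | str = "auto",
                        search_window: tuple = (25.0, 50.0)) -> float:
    """Mean first-shell neighbor count  n = rho * int_0^R 4 pi r^2 g(r) dr.

    ``r_limit="auto"`` integrates to the first local minimum of the 5-point
    smoothed g(r) inside ``search_window`` (ties break to smaller r).
    """
    if r_limit == "auto":
        r_limit = first_shell_limit(rdf, search_window)
    r_limit = float(r_limit)
    if r_limit > rdf.r[-1] + rdf.bin_width:
        raise GeometryError("r_limit outside the computed g(r) range")
    mask = rdf.r < r_limit
    r = np.append(rdf.r[mask], r_limit)
    g = np.append(rdf.g[mask], np.interp(r_limit, rdf.r, rdf.g))
    integrand = 4.0 * np.pi * r ** 2 * g
    return float(rdf.density * np.trapezoid(integrand, r))


def first_shell_limit(rdf: RDFResult, search_window: tuple = (25.0, 50.0)) -> float:
    """First local minimum of smoothed g(r) in the window (the shell edge)."""
    kernel = np.ones(5) / 5.0
    g_s = np.convolve(rdf.g, kernel, mode="same")
    lo, hi = search_window
    idx = np.flatnonzero((rdf.r >= lo) & (rdf.r <= hi))
    for i in idx:
        if 0 < i < len(g_s) - 1 and g_s[i] <= g_s[i - 1] and g_s[i] < g_s[i + 1]:
            return float(rdf.r[i])
    raise ShellLimitError(
        f"no local minimum of g(r) in [{lo}, {hi}] A; pass r_limit explicitly")


# --- mean squared displacement --------------------------------------------

@dataclass
class MSDResult:
    """Time-origin-averaged mean-squared displacement."""

    lag: np.ndarray               # ps
    msd: np.ndarray               # A^2
    species: str
    n_particles: int
    fit_window: tuple | None = None
    d_raw: float | None = None       # cm^2/s
    d_reported: float | None = None  # cm^2/s (rescaled)
    msd_per_particle: np.ndarray | None = None   # (n_lag+1, N)
    d_sem: float | None = None       # SEM of d_reported over particles


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-origin-averaged MSD of one walker, all lags (FFT algorithm)."""
    n = len(x)
    nfft = 1 << (2 * n - 1).bit_length()
    sq = (x ** 2).sum(axis=1)
    # autocorrelation per component via FFT
    s2 = np.zeros(n)
    for c in range(x.shape[1]):
        f = np.fft.rfft(x[:, c], nfft)
        ac = np.fft.irfft(f * np.conj(f), nfft)[:n]
        s2 += ac.real
    sumsq = np.concatenate([[0.0], np.cumsum(sq)])
    total = sumsq[-1]
    msd = np.empty(n)
    for m in range(n):
        # sum over t of |x(t+m)-x(t)|^2 = S1(m) - 2*S2(m)
        s1 = sumsq[n - m] + (total - sumsq[m])
        msd[m] = s1 / (n - m) - 2.0 * s2[m] / (n - m)
    return msd


def compute_msd(traj: Trajectory, species: str,
                max_lag_fraction: float = 0.5,
                per_particle: bool = False) -> MSDResult:
    """Time- and particle-averaged MSD from unwrapped coordinates.

    ``per_particle=True`` also keeps each particle's own time-averaged MSD
    (used to put an uncertainty on fitted diffusion coefficients).
    """
    n_frames = traj.n_frames
    if n_frames < 2:
        raise ValueError("need at least two frames")
    coords = np.stack([traj.positions_of(species, k, unwrapped=True)
                       for k in range(n_frames)])  # (T, N, 3)
    times = traj.times()
    dt = float(times[1] - times[0])
    n_lag = max(1, int(n_frames * max_lag_fraction))
    msd = np.zeros(n_frames)
    per = np.zeros((n_lag + 1, coords.shape[1])) if per_particle else None
    for p in range(coords.shape[1]):
        m = _msd_fft(coords[:, p, :])
        msd += m
        if per is not None:
            per[:, p] = m[:n_lag + 1]
    msd /= coords.shape[1]
    return MSDResult(lag=np.arange(n_lag + 1) * dt, msd=msd[:n_lag + 1],
                     species=species, n_particles=coords.shape[1],
                     msd_per_particle=per)


class FitWindowError(ValueError):
    """Diffusion fit window empty or slope negative."""


def diffusion_coefficient(msd: MSDResult,
                          fit_window: tuple = (0.1, 0.5),
                          scale_factor: float = 4.0) -> MSDResult:
    """D from a linear fit of MSD: D_raw = slope/6, then CG rescaling.

    ``fit_window`` is a fraction range of the maximum lag (default 10-50%,
    excluding the ballistic onset and the poorly averaged tail).  The
    reported value divides by ``scale_factor`` (4, the CG dynamics
    convention compensating the smoothed interactions).  Units: cm^2/s.
    """
    t_max = msd.lag[-1]
    lo, hi = fit_window[0] * t_max, fit_window[1] * t_max
    mask = (msd.lag >= lo) & (msd.lag <= hi)
    if mask.sum() < 2:
        raise FitWindowError("fit window contains fewer than two points")
    slope, _ = np.polyfit(msd.lag[mask], msd.msd[mask], 1)
    if slope < 0:
        raise FitWindowError(
            f"negative MSD slope {slope:.3g} A^2/ps in the fit window")
    d_raw = slope / 6.0 * 1e-4                # A^2/ps -> cm^2/s
    msd.fit_window = fit_window
    msd.d_raw = float(d_raw)
    msd.d_reported = float(d_raw / scale_factor)
    if msd.msd_per_particle is not None and msd.n_particles > 1:
        slopes = np.polyfit(msd.lag[mask],
                            msd.msd_per_particle[mask, :], 1)[0]
        d_each = slopes / 6.0 * 1e-4 / scale_factor
        msd.d_sem = float(np.std(d_each, ddof=1)
                          / np.sqrt(msd.n_particles))
    return msd


# --- force projection ------------------------------------------------------

class UndefinedAxisError(ValueError):
    """Coincident macroion centers: the projection axis is undefined."""


def radial_projection(force_on_a: np.ndarray, com_a: np.ndarray,
                      com_b: np.ndarray, box: float | None = None) -> float:
    """Project a force on macroion A onto the pair axis; negative = attractive.

    The axis is the unit vector from the pair midpoint to A's center, so a
    force pointing toward B projects negative (attraction) and away from B
    positive (repulsion).
    """
    d = np.asarray(com_a, float) - np.asarray(com_b, float)
    if box is not None:
        d = _min_image(d, box)
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise UndefinedAxisError("macroion centers coincide")
    return float(np.dot(force_on_a, d / norm))


@dataclass
class ForceTrace:
    """Per-frame decomposed net forces on a macroion pair (kJ/mol/A)."""

    time: np.ndarray
    distance: np.ndarray                 # COM-COM, A
    proj_coul: np.ndarray                # (T, 2) signed projections
    proj_vdw: np.ndarray
    net_coul: np.ndarray                 # (T, 2, 3)
    net_vdw: np.ndarray

    @property
    def mean_abs_proj_coul(self) -> float:
        return float(np.abs(self.proj_coul).mean())

    @property
    def mean_abs_proj_vdw(self) -> float:
        return float(np.abs(self.proj_vdw).mean())

    @property
    def coul_vdw_ratio(self) -> float:
        return self.mean_abs_proj_coul / self.mean_abs_proj_vdw


class MissingChannelError(RuntimeError):
    """Trajectory frames carry no decomposed force channels."""


def macroion_force_series(traj: Trajectory, pair: tuple = (0, 1)) -> ForceTrace:
    """Net electrostatic/vdW force on each macroion of a pair, per frame.

    The net force on a macroion is the sum over its beads of the stored
    per-particle force channels; projections follow the midpoint sign
    convention of :func:`radial_projection`.
    """
    i, j = pair
    t = traj.times()
    nt = traj.n_frames
    proj_c = np.zeros((nt, 2))
    proj_v = np.zeros((nt, 2))
    net_c = np.zeros((nt, 2, 3))
    net_v = np.zeros((nt, 2, 3))
    dist = np.zeros(nt)
    sel = [traj.mol == i, traj.mol == j]
    for k in range(nt):
        frame = traj.frames[k]
        if frame.f_vdw is None or frame.f_coul is None:
            raise MissingChannelError(
                "trajectory lacks decomposed force channels "
                "(run with store_forces=True)")
        coms = traj.macroion_coms(k)
        box = frame.box
        dvec = _min_image(coms[i] - coms[j], box)
        dist[k] = np.linalg.norm(dvec)
        for s, m in enumerate((i, j)):
            net_c[k, s] = frame.f_coul[sel[s]].sum(axis=0)
            net_v[k, s] = frame.f_vdw[sel[s]].sum(axis=0)
            other = coms[j] if m == i else coms[i]
            proj_c[k, s] = radial_projection(net_c[k, s], coms[m], other, box)
            proj_v[k, s] = radial_projection(net_v[k, s], coms[m], other, box)
    return ForceTrace(time=t, distance=dist, proj_coul=proj_c,
                      proj_vdw=proj_v, net_coul=net_c, net_vdw=net_v)


# --- clustering ------------------------------------------------------------

@dataclass
class ClusterResult:
    """Single-linkage aggregates of macroions under a contact cutoff."""

    labels: np.ndarray           # per-macroion cluster id (lowest member idx)
    sizes: np.ndarray            # size per cluster, ordered by label
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    @property
    def largest(self) -> int:
        return int(self.sizes.max()) if len(self.sizes) else 0


def cluster_aggregates(coms: np.ndarray, box: float,
                       contact_cutoff: float = 32.0) -> ClusterResult:
    """Union of macroions whose COM distance is within the contact cutoff.

    32 A for 25 A macroions spans direct contact plus one bridging bead.
    Deterministic labels: each cluster is named by its lowest member index.
    """
    n = len(coms)
    if n == 0:
        return ClusterResult(labels=np.zeros(0, int), sizes=np.zeros(0, int),
                             cutoff=contact_cutoff)
    ii, jj = np.triu_indices(n, k=1)
    d = _min_image(coms[ii] - coms[jj], box)
    touch = (d ** 2).sum(axis=1) <= contact_cutoff ** 2
    adj = coo_matrix((np.ones(touch.sum()), (ii[touch], jj[touch])),
                     shape=(n, n))
    _, comp = connected_components(adj, directed=False)
    # relabel components by their lowest member
    labels = np.empty(n, dtype=np.int64)
    for c in np.unique(comp):
        members = np.flatnonzero(comp == c)
        labels[members] = members.min()
    uniq, sizes = np.unique(labels, return_counts=True)
    return ClusterResult(labels=labels, sizes=sizes, cutoff=contact_cutoff)


def mean_first_neighbor_count(traj: Trajectory, cutoff: float = 32.0,
                              frame_fraction: float = 0.2) -> float:
    """Mean neighbors-within-cutoff per macroion over the final frames.

    The self-assembly indicator: sustained values above 2 mean aggregates
    beyond dimers/trimers.
    """
    n_frames = traj.n_frames
    k0 = int(np.ceil(n_frames * (1.0 - frame_fraction)))
    counts = []
    for k in range(k0, n_frames):
        coms = traj.macroion_coms(k)
        box = traj.frames[k].box
        r = _pair_distances(coms, None, box)
        n = len(coms)
        ii, jj = np.triu_indices(n, k=1)
        neigh = np.zeros(n)
        within = r <= cutoff
        np.add.at(neigh, ii[within], 1)
        np.add.at(neigh, jj[within], 1)
        counts.append(neigh.mean())
    return float(np.mean(counts))


# --- energy vs distance ----------------------------------------------------

def energy_distance_profile(traj: Trajectory, pair: tuple = (0, 1),
                            bin_width: float = 1.0):
    """Mean total electrostatic energy binned by macroion pair distance.

    Returns a dict of arrays: ``r`` (bin centers), ``mean`` (kJ/mol, NaN for
    empty bins), ``stderr``, ``count``.  Empty bins are reported, never
    interpolated.
    """
    i, j = pair
    dist = []
    energy = []
    for k in range(traj.n_frames):
        frame = traj.frames[k]
        if frame.e_coul is None:
            raise MissingChannelError("frames carry no electrostatic energy")
        coms = traj.macroion_coms(k)
        d = _min_image(coms[i] - coms[j], frame.box)
        dist.append(np.linalg.norm(d))
        energy.append(frame.e_coul)
    dist = np.asarray(dist)
    energy = np.asarray(energy)
    edges = np.arange(dist.min() - bin_width, dist.max() + 2 * bin_width,
                      bin_width)
    idx = np.digitize(dist, edges) - 1
    nb = len(edges) - 1
    mean = np.full(nb, np.nan)
    stderr = np.full(nb, np.nan)
    count = np.zeros(nb, dtype=int)
    for b in range(nb):
        vals = energy[idx == b]
        count[b] = len(vals)
        if len(vals):
            mean[b] = vals.mean()
            if len(vals) > 1:
                stderr[b] = vals.std(ddof=1) / np.sqrt(len(vals))
    return {"r": 0.5 * (edges[1:] + edges[:-1]), "mean": mean,
            "stderr": stderr, "count": count}
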