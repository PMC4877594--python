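"""Numba-compiled inner loops: neighbor lists and pair forces.

All quantities here are in internal units (A, ps, g/mol, e); energies in
(g/mol) A^2/ps^2.  Pair lists are half lists (j > i) with intra-rigid-group
pairs excluded at build time.  Coulomb modes: 0 = none, 1 = Ewald real-space
(erfc-screened, reciprocal part handled elsewhere), 2 = damped-shifted-force
(DSF) truncation.
"""

import math

import numpy as np
from numba import njit

COUL_NONE = 0
COUL_EWALD_REAL = 1
COUL_DSF = 2


@njit(cache=True, fastmath=True)
def build_neighbor_list(pos, box, r_list, mol, max_neighbors):
    """Half Verlet list via a linked-cell grid (falls back to all pairs).

    Returns (neighbors (N, max_neighbors) int32, counts (N,) int32, overflow
    flag).  Caller retries with a larger ``max_neighbors`` on overflow.
    """
    n = pos.shape[0]
    neighbors = np.full((n, max_neighbors), -1, dtype=np.int32)
    counts = np.zeros(n, dtype=np.int32)
    r2 = r_list * r_list
    half = 0.5 * box
    # half-cutoff cells scanned over a +-2 range: finer grained than
    # cutoff-sized cells, which matters when the box is only ~3 cutoffs
    ncell = int(box // (0.5 * r_list))
    scan = 2
    overflow = False
    if ncell < 2 * scan + 1:
        for i in range(n - 1):
            for j in range(i + 1, n):
                if mol[i] >= 0 and mol[i] == mol[j]:
                    continue
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if dx > half:
                    dx -= box
                elif dx < -half:
                    dx += box
                if dy > half:
                    dy -= box
                elif dy < -half:
                    dy += box
                if dz > half:
                    dz -= box
                elif dz < -half:
                    dz += box
                if dx * dx + dy * dy + dz * dz < r2:
                    if counts[i] >= max_neighbors:
                        overflow = True
                    else:
                        neighbors[i, counts[i]] = j
                        counts[i] += 1
        return neighbors, counts, overflow

    cell_len = box / ncell
    if cell_len * scan < r_list:
        scan = int(r_list / cell_len) + 1
        if 2 * scan + 1 > ncell:
            scan = (ncell - 1) // 2
    head = np.full(ncell * ncell * ncell, -1, dtype=np.int32)
    nxt = np.full(n, -1, dtype=np.int32)
    for i in range(n):
        cx = min(int(pos[i, 0] / cell_len), ncell - 1)
        cy = min(int(pos[i, 1] / cell_len), ncell - 1)
        cz = min(int(pos[i, 2] / cell_len), ncell - 1)
        c = (cx * ncell + cy) * ncell + cz
        nxt[i] = head[c]
        head[c] = i
    for i in range(n):
        cx = min(int(pos[i, 0] / cell_len), ncell - 1)
        cy = min(int(pos[i, 1] / cell_len), ncell - 1)
        cz = min(int(pos[i, 2] / cell_len), ncell - 1)
        for ox in range(-scan, scan + 1):
            for oy in range(-scan, scan + 1):
                for oz in range(-scan, scan + 1):
                    c = (((cx + ox) % ncell) * ncell + ((cy + oy) % ncell)) \
                        * ncell + ((cz + oz) % ncell)
                    j = head[c]
                    while j >= 0:
                        if j > i and not (mol[i] >= 0 and mol[i] == mol[j]):
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            if dx > half:
                                dx -= box
                            elif dx < -half:
                                dx += box
                            if dy > half:
                                dy -= box
                            elif dy < -half:
                                dy += box
                            if dz > half:
                                dz -= box
                            elif dz < -half:
                                dz += box
                            if dx * dx + dy * dy + dz * dz < r2:
                                if counts[i] >= max_neighbors:
                                    overflow = True
                                else:
                                    neighbors[i, counts[i]] = j
                                    counts[i] += 1
                        j = nxt[j]
    return neighbors, counts, overflow


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, charges, neighbors, counts,
                eps, sigma, lj_rc, lj_shift,
                coul_mode, alpha, kq, coul_rc,
                f_vdw, f_coul):
    """LJ + short-range Coulomb over the half neighbor list.

    Fills ``f_vdw``/``f_coul`` (zeroed here) and returns
    (e_vdw, e_coul, w_vdw, w_coul) with w the pair virial sum(F.r).
    Raises nothing: a singular overlap returns inf energies (caller checks).
    """
    n = pos.shape[0]
    f_vdw[:] = 0.0
    f_coul[:] = 0.0
    e_vdw = 0.0
    e_coul = 0.0
    w_vdw = 0.0
    w_coul = 0.0
    lj_rc2 = lj_rc * lj_rc
    coul_rc2 = coul_rc * coul_rc
    sig2 = sigma * sigma
    half = 0.5 * box
    # DSF shifts
    if coul_mode == COUL_DSF:
        erfc_rc = math.erfc(alpha * coul_rc)
        dsf_e = erfc_rc / coul_rc
        dsf_f = erfc_rc / coul_rc2 \
            + 2.0 * alpha / math.sqrt(math.pi) \
            * math.exp(-alpha * alpha * coul_rc2) / coul_rc
    else:
        dsf_e = 0.0
        dsf_f = 0.0
    for i in range(n):
        qi = charges[i]
        for kk in range(counts[i]):
            j = neighbors[i, kk]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            if dx > half:
                dx -= box
            elif dx < -half:
                dx += box
            if dy > half:
                dy -= box
            elif dy < -half:
                dy += box
            if dz > half:
                dz -= box
            elif dz < -half:
                dz += box
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                return (math.inf, math.inf, 0.0, 0.0)
            if r2 < lj_rc2:
                inv_r2 = 1.0 / r2
                sr2 = sig2 * inv_r2
                sr6 = sr2 * sr2 * sr2
                e_vdw += 4.0 * eps * (sr6 * sr6 - sr6) - lj_shift
                fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r2
                fx = fr * dx
                fy = fr * dy
                fz = fr * dz
                f_vdw[i, 0] += fx
                f_vdw[i, 1] += fy
                f_vdw[i, 2] += fz
                f_vdw[j, 0] -= fx
                f_vdw[j, 1] -= fy
                f_vdw[j, 2] -= fz
                w_vdw += fr * r2
            if coul_mode != COUL_NONE and r2 < coul_rc2:
                qq = qi * charges[j]
                if qq != 0.0:
                    r = math.sqrt(r2)
                    if coul_mode == COUL_EWALD_REAL:
                        er = math.erfc(alpha * r)
                        e_coul += kq * qq * er / r
                        fr = kq * qq * (er / r
                                        + 2.0 * alpha / math.sqrt(math.pi)
                                        * math.exp(-alpha * alpha * r2)) / r2
                    else:  # DSF
                        er = math.erfc(alpha * r)
                        e_coul += kq * qq * (er / r - dsf_e
                                             + dsf_f * (r - coul_rc))
                        fr = kq * qq * (er / r2
                                        + 2.0 * alpha / math.sqrt(math.pi)
                                        * math.exp(-alpha * alpha * r2) / r
                                        - dsf_f) / r
                    fx = fr * dx
                    fy = fr * dy
                    fz = fr * dz
                    f_coul[i, 0] += fx
                    f_coul[i, 1] += fy
                    f_coul[i, 2] += fz
                    f_coul[j, 0] -= fx
                    f_coul[j, 1] -= fy
                    f_coul[j, 2] -= fz
                    w_coul += fr * r2
    return e_vdw, e_coul, w_vdw, w_coul


@njit(cache=True)
def ewald_reciprocal(pos, charges, box, alpha, nmax, f_coul):
    """Reciprocal-space Ewald energy; adds forces into ``f_coul``.

    Half-space sum over integer lattice vectors with |n|^2 <= nmax^2, using
    per-axis phase recursion.  kq is applied by the caller.
    """
    n = pos.shape[0]
    volume = box * box * box
    two_pi = 2.0 * math.pi
    # phase tables e^{i 2 pi m x / L}, m = 0..nmax
    eik = np.empty((3, n, nmax + 1), dtype=np.complex128)
    for ax in range(3):
        for i in range(n):
            eik[ax, i, 0] = 1.0 + 0.0j
            base = math.cos(two_pi * pos[i, ax] / box) \
                + 1j * math.sin(two_pi * pos[i, ax] / box)
            for m in range(1, nmax + 1):
                eik[ax, i, m] = eik[ax, i, m - 1] * base
    energy = 0.0
    nmax2 = nmax * nmax
    phase = np.empty(n, dtype=np.complex128)
    for nx in range(0, nmax + 1):
        for ny in range(-nmax, nmax + 1):
            if nx == 0 and ny < 0:
                continue
            for nz in range(-nmax, nmax + 1):
                if nx == 0 and ny == 0 and nz <= 0:
                    continue
                m2 = nx * nx + ny * ny + nz * nz
                if m2 > nmax2:
                    continue
                kx = two_pi * nx / box
                ky = two_pi * ny / box
                kz = two_pi * nz / box
                k2 = kx * kx + ky * ky + kz * kz
                a = math.exp(-k2 / (4.0 * alpha * alpha)) / k2
                # structure factor
                s_re = 0.0
                s_im = 0.0
                for i in range(n):
                    if charges[i] == 0.0:
                        p = 0.0 + 0.0j
                    else:
                        p = eik[0, i, nx]
                        p = p * (eik[1, i, ny] if ny >= 0
                                 else np.conj(eik[1, i, -ny]))
                        p = p * (eik[2, i, nz] if nz >= 0
                                 else np.conj(eik[2, i, -nz]))
                        p = charges[i] * p
                    phase[i] = p
                    s_re += p.real
                    s_im += p.imag
                energy += 2.0 * (two_pi / volume) * a * (s_re * s_re + s_im * s_im)
                fpref = 4.0 * (two_pi / volume) * a
                for i in range(n):
                    if charges[i] == 0.0:
                        continue
                    # Im[S(k)* e^{i k r_i} q_i] = s_re*p_im - s_im*p_re
                    im = s_re * phase[i].imag - s_im * phase[i].real
                    f_coul[i, 0] += fpref * kx * im
                    f_coul[i, 1] += fpref * ky * im
                    f_coul[i, 2] += fpref * kz * im
    return energy


@njit(cache=True)
def all_pairs_forces(pos, box, charges, mol,
                     eps, sigma, lj_rc, lj_shift,
                     coul_mode, alpha, kq, coul_rc,
                     f_vdw, f_coul):
    """O(N^2) reference path (oracle for the neighbor-list path)."""
    n = pos.shape[0]
    neighbors = np.empty((n, n), dtype=np.int32)
    counts = np.zeros(n, dtype=np.int32)
    for i in range(n - 1):
        c = 0
        for j in range(i + 1, n):
            if mol[i] >= 0 and mol[i] == mol[j]:
                continue
            neighbors[i, c] = j
            c += 1
        counts[i] = c
    return pair_forces(pos, box, charges, neighbors, counts,
                       eps, sigma, lj_rc, lj_shift,
                       coul_mode, alpha, kq, coul_rc, f_vdw, f_coul)


@njit(cache=True)
def _quat_to_mat(q, rot):
    w, x, y, z = q[0], q[1], q[2], q[3]
    rot[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    rot[0, 1] = 2.0 * (x * y - w * z)
    rot[0, 2] = 2.0 * (x * z + w * y)
    rot[1, 0] = 2.0 * (x * y + w * z)
    rot[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    rot[1, 2] = 2.0 * (y * z - w * x)
    rot[2, 0] = 2.0 * (x * z - w * y)
    rot[2, 1] = 2.0 * (y * z + w * x)
    rot[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True)
def rigid_dlm_rotate(quat, ang_mom, inertia, h):
    """In-place DLM free rotation (axes 3-2-1-2-3 splitting) for all bodies."""
    axes = (2, 1, 0, 1, 2)
    fracs = (0.5, 0.5, 1.0, 0.5, 0.5)
    for b in range(quat.shape[0]):
        for s in range(5):
            ax = axes[s]
            inert = inertia[b, ax]
            if inert <= 1e-9:
                continue
            phi = ang_mom[b, ax] / inert * h * fracs[s]
            hw = math.cos(0.5 * phi)
            hv = math.sin(0.5 * phi)
            w, x, y, z = quat[b, 0], quat[b, 1], quat[b, 2], quat[b, 3]
            if ax == 0:
                quat[b, 0] = w * hw - x * hv
                quat[b, 1] = w * hv + x * hw
                quat[b, 2] = y * hw + z * hv
                quat[b, 3] = z * hw - y * hv
                i, j = 1, 2
            elif ax == 1:
                quat[b, 0] = w * hw - y * hv
                quat[b, 1] = x * hw - z * hv
                quat[b, 2] = w * hv + y * hw
                quat[b, 3] = z * hw + x * hv
                i, j = 2, 0
            else:
                quat[b, 0] = w * hw - z * hv
                quat[b, 1] = x * hw + y * hv
                quat[b, 2] = y * hw - x * hv
                quat[b, 3] = w * hv + z * hw
                i, j = 0, 1
            c = math.cos(phi)
            sn = math.sin(phi)
            li = ang_mom[b, i]
            lj = ang_mom[b, j]
            ang_mom[b, i] = c * li + sn * lj
            ang_mom[b, j] = -sn * li + c * lj
        norm = math.sqrt(quat[b, 0] ** 2 + quat[b, 1] ** 2
                         + quat[b, 2] ** 2 + quat[b, 3] ** 2)
        for k in range(4):
            quat[b, k] /= norm


@njit(cache=True)
def rigid_sync(quat, com, com_vel, ang_mom, inertia, body_coords,
               positions, velocities):
    """Bead positions/velocities from body poses (bodies contiguous first)."""
    n_bodies, n_beads = body_coords.shape[0], body_coords.shape[1]
    rot = np.empty((3, 3))
    for b in range(n_bodies):
        _quat_to_mat(quat[b], rot)
        wx = wy = wz = 0.0
        if inertia[b, 0] > 1e-9:
            wx = ang_mom[b, 0] / inertia[b, 0]
        if inertia[b, 1] > 1e-9:
            wy = ang_mom[b, 1] / inertia[b, 1]
        if inertia[b, 2] > 1e-9:
            wz = ang_mom[b, 2] / inertia[b, 2]
        ox = rot[0, 0] * wx + rot[0, 1] * wy + rot[0, 2] * wz
        oy = rot[1, 0] * wx + rot[1, 1] * wy + rot[1, 2] * wz
        oz = rot[2, 0] * wx + rot[2, 1] * wy + rot[2, 2] * wz
        for a in range(n_beads):
            bx, by, bz = body_coords[b, a, 0], body_coords[b, a, 1], \
                body_coords[b, a, 2]
            sx = rot[0, 0] * bx + rot[0, 1] * by + rot[0, 2] * bz
            sy = rot[1, 0] * bx + rot[1, 1] * by + rot[1, 2] * bz
            sz = rot[2, 0] * bx + rot[2, 1] * by + rot[2, 2] * bz
            k = b * n_beads + a
            positions[k, 0] = com[b, 0] + sx
            positions[k, 1] = com[b, 1] + sy
            positions[k, 2] = com[b, 2] + sz
            velocities[k, 0] = com_vel[b, 0] + oy * sz - oz * sy
            velocities[k, 1] = com_vel[b, 1] + oz * sx - ox * sz
            velocities[k, 2] = com_vel[b, 2] + ox * sy - oy * sx


@njit(cache=True)
def rigid_reduce_forces(f_total, quat, body_coords, force, torque_body):
    """Net force and body-frame torque about the COM for every body."""
    n_bodies, n_beads = body_coords.shape[0], body_coords.shape[1]
    rot = np.empty((3, 3))
    for b in range(n_bodies):
        _quat_to_mat(quat[b], rot)
        fx = fy = fz = 0.0
        tx = ty = tz = 0.0
        for a in range(n_beads):
            k = b * n_beads + a
            gx, gy, gz = f_total[k, 0], f_total[k, 1], f_total[k, 2]
            bx, by, bz = body_coords[b, a, 0], body_coords[b, a, 1], \
                body_coords[b, a, 2]
            sx = rot[0, 0] * bx + rot[0, 1] * by + rot[0, 2] * bz
            sy = rot[1, 0] * bx + rot[1, 1] * by + rot[1, 2] * bz
            sz = rot[2, 0] * bx + rot[2, 1] * by + rot[2, 2] * bz
            fx += gx
            fy += gy
            fz += gz
            tx += sy * gz - sz * gy
            ty += sz * gx - sx * gz
            tz += sx * gy - sy * gx
        force[b, 0] = fx
        force[b, 1] = fy
        force[b, 2] = fz
        # body frame: R^T tau
        torque_body[b, 0] = rot[0, 0] * tx + rot[1, 0] * ty + rot[2, 0] * tz
        torque_body[b, 1] = rot[0, 1] * tx + rot[1, 1] * ty + rot[2, 1] * tz
        torque_body[b, 2] = rot[0, 2] * tx + rot[1, 2] * ty + rot[2, 2] * tz
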