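"""Numba kernels: pair noise, nonbonded/bonded forces, neighbor search.

The random-force noise zeta_ij is counter-based: a splitmix64-style hash of
(min(i,j), max(i,j), step seed) feeds a Box-Muller transform.  This makes
zeta symmetric per pair, independent of pair-enumeration order (cell list
and brute force produce identical forces up to summation rounding) and
exactly reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_MIX1 = U64(0x9E3779B97F4A7C15)
_MIX2 = U64(0xC2B2AE3D27D4EB4F)
_MIX3 = U64(0xD6E8FEB86659FD93)
_FIN1 = U64(0xBF58476D1CE4E5B9)
_FIN2 = U64(0x94D049BB133111EB)
_TWO_PI = 6.283185307179586


@njit(cache=True)
def pair_noise(i, j, seed):
    """Standard-normal deviate, symmetric in (i, j), deterministic in seed."""
    if i > j:
        i, j = j, i
    x = U64(i) * _MIX1
    x ^= (U64(j) + _MIX2) * _MIX2
    x ^= U64(seed) * _MIX3
    x = (x ^ (x >> U64(30))) * _FIN1
    x = (x ^ (x >> U64(27))) * _FIN2
    x ^= x >> U64(31)
    hi = np.float64(x >> U64(32))
    lo = np.float64(x & U64(0xFFFFFFFF))
    u1 = (hi + 0.5) / 4294967296.0
    u2 = (lo + 0.5) / 4294967296.0
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(_TWO_PI * u2)


@njit(cache=True, inline="always")
def _min_image(d, L):
    # raw differences of wrapped coordinates lie in (-L, L)
    if d > 0.5 * L:
        return d - L
    if d < -0.5 * L:
        return d + L
    return d


@njit(cache=True, inline="always")
def _nb_pair(i, j, pos, vel, species, box, a, gamma, sigma, rc,
             inv_sqrt_dt, seed, forces):
    """One nonbonded pair; returns (energy, overlap_flag)."""
    dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
    dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
    dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc:
        return 0.0, 0
    r = np.sqrt(r2)
    ov = 0
    if r < 1e-10:
        # exact overlap: direction undefined, substitute a deterministic
        # pseudo-random unit vector (probability ~0 with soft cores)
        ov = 1
        ex = pair_noise(i, j, seed + 101)
        ey = pair_noise(i, j, seed + 202)
        ez = pair_noise(i, j, seed + 303)
        nn = np.sqrt(ex * ex + ey * ey + ez * ez)
        ex /= nn
        ey /= nn
        ez /= nn
        w = 1.0
    else:
        ex = dx / r
        ey = dy / r
        ez = dz / r
        w = 1.0 - r / rc
    aij = a[species[i], species[j]]
    e = 0.5 * aij * rc * w * w
    f = aij * w
    if gamma != 0.0:
        vdotr = (ex * (vel[i, 0] - vel[j, 0]) + ey * (vel[i, 1] - vel[j, 1])
                 + ez * (vel[i, 2] - vel[j, 2]))
        f -= gamma * w * w * vdotr
    if sigma != 0.0:
        f += sigma * w * pair_noise(i, j, seed) * inv_sqrt_dt
    forces[i, 0] += f * ex
    forces[i, 1] += f * ey
    forces[i, 2] += f * ez
    forces[j, 0] -= f * ex
    forces[j, 1] -= f * ey
    forces[j, 2] -= f * ez
    return e, ov


_OFFSETS = np.array(
    [[1, 0, 0], [0, 1, 0], [0, 0, 1],
     [1, 1, 0], [1, -1, 0], [1, 0, 1], [1, 0, -1], [0, 1, 1], [0, 1, -1],
     [1, 1, 1], [1, 1, -1], [1, -1, 1], [1, -1, -1]], dtype=np.int64)


@njit(cache=True)
def _bin_beads(pos, box, ncx, ncy, ncz):
    n = pos.shape[0]
    head = np.full(ncx * ncy * ncz, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    csx = box[0] / ncx
    csy = box[1] / ncy
    csz = box[2] / ncz
    for i in range(n):
        cx = int(pos[i, 0] / csx)
        cy = int(pos[i, 1] / csy)
        cz = int(pos[i, 2] / csz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cx * ncy + cy) * ncz + cz
        nxt[i] = head[c]
        head[c] = i
    return head, nxt


@njit(cache=True)
def nonbonded_forces(pos, vel, species, box, a, gamma, sigma, rc,
                     inv_sqrt_dt, seed, forces):
    """Accumulate all three DPD pair channels; returns (energy, n_overlap).

    Uses a cell-sorted neighbor search when the box admits >= 3 cells per
    axis, otherwise an O(N^2) double loop.  The counter-based noise makes
    both paths produce identical forces up to summation rounding.
    """
    n = pos.shape[0]
    e = 0.0
    nov = 0
    ncx = int(box[0] // rc)
    ncy = int(box[1] // rc)
    ncz = int(box[2] // rc)
    if ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                de, ov = _nb_pair(i, j, pos, vel, species, box, a, gamma,
                                  sigma, rc, inv_sqrt_dt, seed, forces)
                e += de
                nov += ov
        return e, nov
    # counting sort by cell: contiguous per-cell memory access keeps the
    # traversal cache-friendly (the dominant cost at rho = 3)
    ncell = ncx * ncy * ncz
    csx = box[0] / ncx
    csy = box[1] / ncy
    csz = box[2] / ncz
    cell_of = np.empty(n, dtype=np.int64)
    start = np.zeros(ncell + 1, dtype=np.int64)
    for i in range(n):
        cx = min(max(int(pos[i, 0] / csx), 0), ncx - 1)
        cy = min(max(int(pos[i, 1] / csy), 0), ncy - 1)
        cz = min(max(int(pos[i, 2] / csz), 0), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        cell_of[i] = c
        start[c + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int64)
    fill = start[:-1].copy()
    for i in range(n):
        c = cell_of[i]
        order[fill[c]] = i
        fill[c] += 1
    spos = np.empty((n, 3))
    svel = np.empty((n, 3))
    sspec = np.empty(n, dtype=species.dtype)
    for k in range(n):
        i = order[k]
        spos[k, 0] = pos[i, 0]
        spos[k, 1] = pos[i, 1]
        spos[k, 2] = pos[i, 2]
        svel[k, 0] = vel[i, 0]
        svel[k, 1] = vel[i, 1]
        svel[k, 2] = vel[i, 2]
        sspec[k] = species[i]
    sforce = np.zeros((n, 3))
    rc2 = rc * rc
    hx = 0.5 * box[0]
    hy = 0.5 * box[1]
    hz = 0.5 * box[2]
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                s0 = start[c]
                e0 = start[c + 1]
                for k in range(14):          # 13 half-neighbors + own cell
                    if k == 13:
                        s1 = s0
                        e1 = e0
                    else:
                        bx = (cx + _OFFSETS[k, 0]) % ncx
                        by = (cy + _OFFSETS[k, 1]) % ncy
                        bz = (cz + _OFFSETS[k, 2]) % ncz
                        b = (bx * ncy + by) * ncz + bz
                        s1 = start[b]
                        e1 = start[b + 1]
                    for p in range(s0, e0):
                        q0 = p + 1 if k == 13 else s1
                        for q in range(q0, e1):
                            dx = spos[p, 0] - spos[q, 0]
                            dy = spos[p, 1] - spos[q, 1]
                            dz = spos[p, 2] - spos[q, 2]
                            if dx > hx:
                                dx -= box[0]
                            elif dx < -hx:
                                dx += box[0]
                            if dy > hy:
                                dy -= box[1]
                            elif dy < -hy:
                                dy += box[1]
                            if dz > hz:
                                dz -= box[2]
                            elif dz < -hz:
                                dz += box[2]
                            r2 = dx * dx + dy * dy + dz * dz
                            if r2 >= rc2:
                                continue
                            r = np.sqrt(r2)
                            if r < 1e-10:
                                nov += 1
                                ex = pair_noise(order[p], order[q], seed + 101)
                                ey = pair_noise(order[p], order[q], seed + 202)
                                ez = pair_noise(order[p], order[q], seed + 303)
                                nn = np.sqrt(ex * ex + ey * ey + ez * ez)
                                ex /= nn
                                ey /= nn
                                ez /= nn
                                w = 1.0
                            else:
                                inv = 1.0 / r
                                ex = dx * inv
                                ey = dy * inv
                                ez = dz * inv
                                w = 1.0 - r / rc
                            aij = a[sspec[p], sspec[q]]
                            e += 0.5 * aij * rc * w * w
                            f = aij * w
                            if gamma != 0.0:
                                vdotr = (ex * (svel[p, 0] - svel[q, 0])
                                         + ey * (svel[p, 1] - svel[q, 1])
                                         + ez * (svel[p, 2] - svel[q, 2]))
                                f -= gamma * w * w * vdotr
                            if sigma != 0.0:
                                f += (sigma * w * inv_sqrt_dt
                                      * pair_noise(order[p], order[q], seed))
                            sforce[p, 0] += f * ex
                            sforce[p, 1] += f * ey
                            sforce[p, 2] += f * ez
                            sforce[q, 0] -= f * ex
                            sforce[q, 1] -= f * ey
                            sforce[q, 2] -= f * ez
    for k in range(n):
        i = order[k]
        forces[i, 0] += sforce[k, 0]
        forces[i, 1] += sforce[k, 1]
        forces[i, 2] += sforce[k, 2]
    return e, nov


@njit(cache=True)
def neighbor_pairs_kernel(pos, box, rc, out_i, out_j, force_brute):
    """Every unordered pair with minimum-image distance < rc, exactly once.

    Fills out_i/out_j and returns the count, or -1 on capacity overflow.
    """
    n = pos.shape[0]
    cap = out_i.shape[0]
    cnt = 0
    ncx = int(box[0] // rc)
    ncy = int(box[1] // rc)
    ncz = int(box[2] // rc)
    if force_brute or ncx < 3 or ncy < 3 or ncz < 3:
        for i in range(n - 1):
            for j in range(i + 1, n):
                dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                if dx * dx + dy * dy + dz * dz < rc * rc:
                    if cnt >= cap:
                        return -1
                    out_i[cnt] = i
                    out_j[cnt] = j
                    cnt += 1
        return cnt
    head, nxt = _bin_beads(pos, box, ncx, ncy, ncz)
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                i = head[c]
                while i >= 0:
                    j = nxt[i]
                    while j >= 0:
                        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                        if dx * dx + dy * dy + dz * dz < rc * rc:
                            if cnt >= cap:
                                return -1
                            out_i[cnt] = i
                            out_j[cnt] = j
                            cnt += 1
                        j = nxt[j]
                    i = nxt[i]
                for k in range(13):
                    bx = (cx + _OFFSETS[k, 0]) % ncx
                    by = (cy + _OFFSETS[k, 1]) % ncy
                    bz = (cz + _OFFSETS[k, 2]) % ncz
                    b = (bx * ncy + by) * ncz + bz
                    i = head[c]
                    while i >= 0:
                        j = head[b]
                        while j >= 0:
                            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
                            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
                            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
                            if dx * dx + dy * dy + dz * dz < rc * rc:
                                if cnt >= cap:
                                    return -1
                                out_i[cnt] = i
                                out_j[cnt] = j
                                cnt += 1
                            j = nxt[j]
                        i = nxt[i]
    return cnt


@njit(cache=True)
def bond_forces_kernel(pos, box, bonds, k_bond, r_bond, forces):
    """Harmonic bonds F = k (1 - r/r_s) r_hat; returns (energy, n_overlap)."""
    e = 0.0
    nov = 0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-10:
            nov += 1
            ex = pair_noise(i, j, 404)
            ey = pair_noise(i, j, 505)
            ez = pair_noise(i, j, 606)
            nn = np.sqrt(ex * ex + ey * ey + ez * ez)
            ex /= nn
            ey /= nn
            ez /= nn
            w = 1.0
        else:
            ex = dx / r
            ey = dy / r
            ez = dz / r
            w = 1.0 - r / r_bond
        e += 0.5 * k_bond * r_bond * w * w
        f = k_bond * w
        forces[i, 0] += f * ex
        forces[i, 1] += f * ey
        forces[i, 2] += f * ez
        forces[j, 0] -= f * ex
        forces[j, 1] -= f * ey
        forces[j, 2] -= f * ez
    return e, nov


@njit(cache=True)
def angle_forces_kernel(pos, box, angles, theta0, k_angle, forces):
    """Harmonic angles U = k (theta - theta0)^2; returns (energy, n_degenerate).

    Triples with a zero-length arm contribute nothing and are counted.
    """
    e = 0.0
    ndeg = 0
    for t in range(angles.shape[0]):
        ia = angles[t, 0]
        ij = angles[t, 1]
        ik = angles[t, 2]
        ux = _min_image(pos[ia, 0] - pos[ij, 0], box[0])
        uy = _min_image(pos[ia, 1] - pos[ij, 1], box[1])
        uz = _min_image(pos[ia, 2] - pos[ij, 2], box[2])
        vx = _min_image(pos[ik, 0] - pos[ij, 0], box[0])
        vy = _min_image(pos[ik, 1] - pos[ij, 1], box[1])
        vz = _min_image(pos[ik, 2] - pos[ij, 2], box[2])
        ru = np.sqrt(ux * ux + uy * uy + uz * uz)
        rv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if ru < 1e-12 or rv < 1e-12:
            ndeg += 1
            continue
        c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        diff = th - theta0[t]
        e += k_angle * diff * diff
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            s = 1e-8
        fac = 2.0 * k_angle * diff / s
        # F_a = fac (v_hat - c u_hat)/ru ; F_c = fac (u_hat - c v_hat)/rv
        fax = fac * (vx / rv - c * ux / ru) / ru
        fay = fac * (vy / rv - c * uy / ru) / ru
        faz = fac * (vz / rv - c * uz / ru) / ru
        fcx = fac * (ux / ru - c * vx / rv) / rv
        fcy = fac * (uy / ru - c * vy / rv) / rv
        fcz = fac * (uz / ru - c * vz / rv) / rv
        forces[ia, 0] += fax
        forces[ia, 1] += fay
        forces[ia, 2] += faz
        forces[ik, 0] += fcx
        forces[ik, 1] += fcy
        forces[ik, 2] += fcz
        forces[ij, 0] -= fax + fcx
        forces[ij, 1] -= fay + fcy
        forces[ij, 2] -= faz + fcz
    return e, ndeg
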