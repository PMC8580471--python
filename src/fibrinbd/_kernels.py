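"""Compiled kernels: potentials, neighbour search and the Langevin integrator.

All kernels operate on flat ``(N, 3)`` coordinate arrays in SI units.  Chain
topology is implicit: node ``n`` belongs to fibre ``n // nodes_per_fibre`` and
is bonded to ``n - 1`` / ``n + 1`` within the same fibre only.  Coordinates are
stored unwrapped (contour bookkeeping stays exact); the integrator maintains a
wrapped copy for the inter-fibre terms, whose distances always go through the
minimum-image convention.

Randomness: a seedable xorshift128+ uniform generator (seeded via splitmix64)
feeds the Box-Muller transform.  The generator state is an explicit
``uint64[2]`` array owned by the caller, so streams are reproducible and
independent per run.
"""

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi
_U64_11 = np.uint64(11)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True)
def seed_state(seed, state):
    """Initialize an xorshift128+ state from an integer seed (splitmix64)."""
    z = np.uint64(seed)
    for i in range(2):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        state[i] = t ^ (t >> np.uint64(31))
    if state[0] == np.uint64(0) and state[1] == np.uint64(0):
        state[0] = np.uint64(0x9E3779B97F4A7C15)


@njit(inline="always")
def _next_uniform(state):
    """Uniform double in [0, 1) from xorshift128+ (53 mantissa bits)."""
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= s1 << np.uint64(23)
    s1 ^= (s1 >> np.uint64(17)) ^ s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return float((s0 + s1) >> _U64_11) * _INV_2_53


@njit(cache=True, fastmath=True)
def fill_standard_normal(out, state):
    """Fill ``out`` with i.i.d. standard normals via Box-Muller."""
    n = out.size
    i = 0
    while i < n:
        u1 = _next_uniform(state)
        while u1 <= 0.0:
            u1 = _next_uniform(state)
        u2 = _next_uniform(state)
        r = math.sqrt(-2.0 * math.log(u1))
        out[i] = r * math.cos(TWO_PI * u2)
        if i + 1 < n:
            out[i + 1] = r * math.sin(TWO_PI * u2)
        i += 2


@njit(cache=True, fastmath=True)
def stretch_forces_write(pos, npf, kS, r0S, F):
    """stretch_forces variant that overwrites F instead of accumulating."""
    N = pos.shape[0]
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    return stretch_forces(pos, npf, kS, r0S, F)


@njit(cache=True, fastmath=True)
def stretch_forces(pos, npf, kS, r0S, F):
    """Harmonic bond term between chain neighbours.  Returns W^S, adds to F."""
    N = pos.shape[0]
    W = 0.0
    for base in range(0, N, npf):
        for j in range(npf - 1):
            i0 = base + j
            i1 = i0 + 1
            dx = pos[i1, 0] - pos[i0, 0]
            dy = pos[i1, 1] - pos[i0, 1]
            dz = pos[i1, 2] - pos[i0, 2]
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            d = r - r0S
            W += 0.5 * kS * d * d
            fac = kS * d / r
            F[i0, 0] += fac * dx
            F[i0, 1] += fac * dy
            F[i0, 2] += fac * dz
            F[i1, 0] -= fac * dx
            F[i1, 1] -= fac * dy
            F[i1, 2] -= fac * dz
    return W


@njit(cache=True, fastmath=True)
def bend_forces(pos, npf, kB, theta0, F):
    """Angular term at each interior node; straight chain (theta0 = pi) is the
    minimum.  The angular gradient is singular at theta = pi; there the force
    limit is zero and the kernel returns it smoothly through the h-gradient."""
    N = pos.shape[0]
    W = 0.0
    for base in range(0, N, npf):
        for j in range(1, npf - 1):
            i = base + j
            ux = pos[i - 1, 0] - pos[i, 0]
            uy = pos[i - 1, 1] - pos[i, 1]
            uz = pos[i - 1, 2] - pos[i, 2]
            vx = pos[i + 1, 0] - pos[i, 0]
            vy = pos[i + 1, 1] - pos[i, 1]
            vz = pos[i + 1, 2] - pos[i, 2]
            nu2 = ux * ux + uy * uy + uz * uz
            nv2 = vx * vx + vy * vy + vz * vz
            nu = math.sqrt(nu2)
            nv = math.sqrt(nv2)
            inv = 1.0 / (nu * nv)
            h = (ux * vx + uy * vy + uz * vz) * inv
            if h > 1.0:
                h = 1.0
            elif h < -1.0:
                h = -1.0
            th = math.acos(h)
            d = th - theta0
            W += 0.5 * kB * d * d
            s = math.sqrt(1.0 - h * h)
            if s < 1e-8:
                if abs(d) < 1e-6:
                    g = -kB  # limit of kB*(theta-pi)/sin(theta) at theta->pi
                else:
                    continue  # folded-back cusp (theta ~ 0): zero force
            else:
                g = kB * d / s
            px = vx * inv - h * ux / nu2
            py = vy * inv - h * uy / nu2
            pz = vz * inv - h * uz / nu2
            qx = ux * inv - h * vx / nv2
            qy = uy * inv - h * vy / nv2
            qz = uz * inv - h * vz / nv2
            F[i - 1, 0] += g * px
            F[i - 1, 1] += g * py
            F[i - 1, 2] += g * pz
            F[i + 1, 0] += g * qx
            F[i + 1, 1] += g * qy
            F[i + 1, 2] += g * qz
            F[i, 0] -= g * (px + qx)
            F[i, 1] -= g * (py + qy)
            F[i, 2] -= g * (pz + qz)
    return W


@njit(cache=True, fastmath=True)
def torsion_forces(pos, npf, kT, F):
    """Dihedral term over consecutive quadruples (j, i, k, l).

    m = r_ij x r_ik normal to the (j,i,k) plane, n = r_ki x r_kl normal to the
    (i,k,l) plane; W = 1/2 kT phi^2 with phi0 = 0 depends only on |phi| =
    arccos(m.n/|m||n|), so no sign factor enters the force.  Collinear
    (degenerate-normal) quadruples contribute zero force.
    """
    N = pos.shape[0]
    W = 0.0
    if npf < 4:
        return W
    for base in range(0, N, npf):
        for t in range(npf - 3):
            n0 = base + t
            n1 = n0 + 1
            n2 = n0 + 2
            n3 = n0 + 3
            ax = pos[n0, 0] - pos[n1, 0]
            ay = pos[n0, 1] - pos[n1, 1]
            az = pos[n0, 2] - pos[n1, 2]
            bx = pos[n2, 0] - pos[n1, 0]
            by = pos[n2, 1] - pos[n1, 1]
            bz = pos[n2, 2] - pos[n1, 2]
            px = -bx
            py = -by
            pz = -bz
            qx = pos[n3, 0] - pos[n2, 0]
            qy = pos[n3, 1] - pos[n2, 1]
            qz = pos[n3, 2] - pos[n2, 2]
            mx = ay * bz - az * by
            my = az * bx - ax * bz
            mz = ax * by - ay * bx
            nx = py * qz - pz * qy
            ny = pz * qx - px * qz
            nz = px * qy - py * qx
            nm2 = mx * mx + my * my + mz * mz
            nn2 = nx * nx + ny * ny + nz * nz
            a2 = ax * ax + ay * ay + az * az
            b2 = bx * bx + by * by + bz * bz
            q2 = qx * qx + qy * qy + qz * qz
            if nm2 < 1e-12 * a2 * b2 or nn2 < 1e-12 * b2 * q2:
                continue  # collinear triple: dihedral undefined, zero force
            nm = math.sqrt(nm2)
            nn = math.sqrt(nn2)
            inv = 1.0 / (nm * nn)
            h = (mx * nx + my * ny + mz * nz) * inv
            if h > 1.0:
                h = 1.0
            elif h < -1.0:
                h = -1.0
            phi = math.acos(h)
            W += 0.5 * kT * phi * phi
            s = math.sqrt(1.0 - h * h)
            if h > 1.0 - 1e-12:
                g = kT  # limit of kT*acos(h)/sqrt(1-h^2) at h->1
            elif s < 1e-8:
                continue  # phi ~ pi cusp of the harmonic dihedral
            else:
                g = kT * phi / s
            Ax = nx * inv - h * mx / nm2
            Ay = ny * inv - h * my / nm2
            Az = nz * inv - h * mz / nm2
            Bx = mx * inv - h * nx / nn2
            By = my * inv - h * ny / nn2
            Bz = mz * inv - h * nz / nn2
            # dh/dr0 = b x A ; dh/dr3 = B x p
            bAx = by * Az - bz * Ay
            bAy = bz * Ax - bx * Az
            bAz = bx * Ay - by * Ax
            Aax = Ay * az - Az * ay
            Aay = Az * ax - Ax * az
            Aaz = Ax * ay - Ay * ax
            qBx = qy * Bz - qz * By
            qBy = qz * Bx - qx * Bz
            qBz = qx * By - qy * Bx
            Bpx = By * pz - Bz * py
            Bpy = Bz * px - Bx * pz
            Bpz = Bx * py - By * px
            F[n0, 0] += g * bAx
            F[n0, 1] += g * bAy
            F[n0, 2] += g * bAz
            F[n1, 0] += g * (-bAx - Aax + qBx)
            F[n1, 1] += g * (-bAy - Aay + qBy)
            F[n1, 2] += g * (-bAz - Aaz + qBz)
            F[n2, 0] += g * (Aax - qBx - Bpx)
            F[n2, 1] += g * (Aay - qBy - Bpy)
            F[n2, 2] += g * (Aaz - qBz - Bpz)
            F[n3, 0] += g * Bpx
            F[n3, 1] += g * Bpy
            F[n3, 2] += g * Bpz
    return W


@njit(cache=True, fastmath=True)
def pair_forces(pos, pi, pj, box, kA, r0A, a_th, kR, r0R, F):
    """Aggregation (< a_th) and linear repulsion (< r0R) over candidate pairs.

    Accepts arbitrary (unwrapped) coordinates; full minimum image per pair.
    The candidate list may carry a skin margin; the physical cutoffs are
    re-evaluated on minimum-image distances every call.
    """
    WA = 0.0
    WR = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    c2 = a_th * a_th
    for t in range(pi.size):
        i = pi[t]
        j = pj[t]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= Lx * math.floor(dx / Lx + 0.5)
        dy -= Ly * math.floor(dy / Ly + 0.5)
        dz -= Lz * math.floor(dz / Lz + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        r = math.sqrt(r2)
        d = r - r0A
        WA += 0.5 * kA * d * d
        fac = kA * d / r
        F[i, 0] += fac * dx
        F[i, 1] += fac * dy
        F[i, 2] += fac * dz
        F[j, 0] -= fac * dx
        F[j, 1] -= fac * dy
        F[j, 2] -= fac * dz
        if r < r0R:
            dr = r - r0R
            WR += 0.5 * kR * dr * dr
            fac = kR * dr / r
            F[i, 0] += fac * dx
            F[i, 1] += fac * dy
            F[i, 2] += fac * dz
            F[j, 0] -= fac * dx
            F[j, 1] -= fac * dy
            F[j, 2] -= fac * dz
    return WA, WR


@njit(cache=True, fastmath=True)
def pair_forces_wrapped(wpos, pi, pj, box, kA, r0A, a_th, kR, r0R, F):
    """pair_forces fast path for coordinates already wrapped into [0, L):
    the minimum image then needs at most one box shift per component."""
    WA = 0.0
    WR = 0.0
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    c2 = a_th * a_th
    for t in range(pi.size):
        i = pi[t]
        j = pj[t]
        dx = wpos[j, 0] - wpos[i, 0]
        dy = wpos[j, 1] - wpos[i, 1]
        dz = wpos[j, 2] - wpos[i, 2]
        if dx >= hx:
            dx -= Lx
        elif dx < -hx:
            dx += Lx
        if dy >= hy:
            dy -= Ly
        elif dy < -hy:
            dy += Ly
        if dz >= hz:
            dz -= Lz
        elif dz < -hz:
            dz += Lz
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        r = math.sqrt(r2)
        d = r - r0A
        WA += 0.5 * kA * d * d
        fac = kA * d / r
        F[i, 0] += fac * dx
        F[i, 1] += fac * dy
        F[i, 2] += fac * dz
        F[j, 0] -= fac * dx
        F[j, 1] -= fac * dy
        F[j, 2] -= fac * dz
        if r < r0R:
            dr = r - r0R
            WR += 0.5 * kR * dr * dr
            fac = kR * dr / r
            F[i, 0] += fac * dx
            F[i, 1] += fac * dy
            F[i, 2] += fac * dz
            F[j, 0] -= fac * dx
            F[j, 1] -= fac * dy
            F[j, 2] -= fac * dz
    return WA, WR


@njit(inline="always")
def _mic_wrapped(du, L, half):
    if du >= half:
        return du - L
    elif du < -half:
        return du + L
    return du


@njit(inline="always")
def _has_free_slot(partner, i):
    for s in range(partner.shape[1]):
        if partner[i, s] < 0:
            return True
    return False


@njit(inline="always")
def _bonded_to(partner, i, j):
    for s in range(partner.shape[1]):
        if partner[i, s] == j:
            return True
    return False


@njit(inline="always")
def _attach(partner, i, j):
    for s in range(partner.shape[1]):
        if partner[i, s] < 0:
            partner[i, s] = j
            return


@njit(inline="always")
def _detach(partner, i, j):
    for s in range(partner.shape[1]):
        if partner[i, s] == j:
            partner[i, s] = -1
            return


@njit(cache=True, fastmath=True)
def pair_forces_sticky(wpos, pi, pj, box, kA, r0A, a_th, kR, r0R, F,
                       partner, best_j, best_d2):
    """Persistent aggregation bonds plus all-pairs repulsion (wrapped coords).

    ``partner`` has shape (N, K): each node carries up to K aggregation bonds
    (modelling its limited aC binding arms), stored symmetrically (-1 = free
    slot).  A bond persists while its minimum-image distance stays below a_th
    (dissociation = the pair leaving the a_th shell); nodes with a free slot
    bind their mutual nearest eligible foreign neighbour, one new bond per
    node per step.  Repulsion acts on every candidate pair inside r0R.
    Returns (WA, WR).
    """
    N = wpos.shape[0]
    K = partner.shape[1]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    c2 = a_th * a_th
    r2R = r0R * r0R
    # dissociate bonds whose pair left the a_th shell
    for i in range(N):
        for s in range(K):
            j = partner[i, s]
            if j > i:
                dx = _mic_wrapped(wpos[j, 0] - wpos[i, 0], Lx, hx)
                dy = _mic_wrapped(wpos[j, 1] - wpos[i, 1], Ly, hy)
                dz = _mic_wrapped(wpos[j, 2] - wpos[i, 2], Lz, hz)
                if dx * dx + dy * dy + dz * dz >= c2:
                    partner[i, s] = -1
                    _detach(partner, j, i)
    for i in range(N):
        best_j[i] = -1
        best_d2[i] = c2
    WR = 0.0
    for t in range(pi.size):
        i = pi[t]
        j = pj[t]
        dx = _mic_wrapped(wpos[j, 0] - wpos[i, 0], Lx, hx)
        dy = _mic_wrapped(wpos[j, 1] - wpos[i, 1], Ly, hy)
        dz = _mic_wrapped(wpos[j, 2] - wpos[i, 2], Lz, hz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < r2R:
            r = math.sqrt(r2)
            dr = r - r0R
            WR += 0.5 * kR * dr * dr
            fac = kR * dr / r
            F[i, 0] += fac * dx
            F[i, 1] += fac * dy
            F[i, 2] += fac * dz
            F[j, 0] -= fac * dx
            F[j, 1] -= fac * dy
            F[j, 2] -= fac * dz
        if r2 < best_d2[i] or r2 < best_d2[j]:
            if (_has_free_slot(partner, i) and _has_free_slot(partner, j)
                    and not _bonded_to(partner, i, j)):
                if r2 < best_d2[i]:
                    best_d2[i] = r2
                    best_j[i] = j
                if r2 < best_d2[j]:
                    best_d2[j] = r2
                    best_j[j] = i
    # mutual nearest eligible pairs bind (at most one new bond per node/step)
    for i in range(N):
        j = best_j[i]
        if (j > i and best_j[j] == i and _has_free_slot(partner, i)
                and _has_free_slot(partner, j)
                and not _bonded_to(partner, i, j)):
            _attach(partner, i, j)
            _attach(partner, j, i)
    WA = 0.0
    for i in range(N):
        for s in range(K):
            j = partner[i, s]
            if j <= i:
                continue
            dx = _mic_wrapped(wpos[j, 0] - wpos[i, 0], Lx, hx)
            dy = _mic_wrapped(wpos[j, 1] - wpos[i, 1], Ly, hy)
            dz = _mic_wrapped(wpos[j, 2] - wpos[i, 2], Lz, hz)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            d = r - r0A
            WA += 0.5 * kA * d * d
            fac = kA * d / r
            F[i, 0] += fac * dx
            F[i, 1] += fac * dy
            F[i, 2] += fac * dz
            F[j, 0] -= fac * dx
            F[j, 1] -= fac * dy
            F[j, 2] -= fac * dz
    return WA, WR


@njit(cache=True, fastmath=True)
def nearest_partner_select(pos, pi, pj, box, a_th):
    """Per-node nearest foreign neighbour within a_th over a candidate list.

    Returns (best_j, best_d) with best_j = -1 where no partner is in range.
    Accepts unwrapped coordinates (full minimum image).
    """
    N = pos.shape[0]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    c2 = a_th * a_th
    best_j = np.full(N, -1, np.int64)
    best_d2 = np.full(N, c2)
    for t in range(pi.size):
        i = pi[t]
        j = pj[t]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= Lx * math.floor(dx / Lx + 0.5)
        dy -= Ly * math.floor(dy / Ly + 0.5)
        dz -= Lz * math.floor(dz / Lz + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < best_d2[i]:
            best_d2[i] = r2
            best_j[i] = j
        if r2 < best_d2[j]:
            best_d2[j] = r2
            best_j[j] = i
    return best_j, np.sqrt(best_d2)


@njit(cache=True, fastmath=True)
def brute_force_pairs(pos, npf, box, cutoff):
    """O(N^2) inter-fibre pair enumeration under minimum image (reference)."""
    N = pos.shape[0]
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    c2 = cutoff * cutoff
    cnt = 0
    for i in range(N - 1):
        fi = i // npf
        for j in range(i + 1, N):
            if j // npf == fi:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= Lx * math.floor(dx / Lx + 0.5)
            dy -= Ly * math.floor(dy / Ly + 0.5)
            dz -= Lz * math.floor(dz / Lz + 0.5)
            if dx * dx + dy * dy + dz * dz < c2:
                cnt += 1
    pi = np.empty(cnt, np.int64)
    pj = np.empty(cnt, np.int64)
    k = 0
    for i in range(N - 1):
        fi = i // npf
        for j in range(i + 1, N):
            if j // npf == fi:
                continue
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= Lx * math.floor(dx / Lx + 0.5)
            dy -= Ly * math.floor(dy / Ly + 0.5)
            dz -= Lz * math.floor(dz / Lz + 0.5)
            if dx * dx + dy * dy + dz * dz < c2:
                pi[k] = i
                pj[k] = j
                k += 1
    return pi, pj


@njit(cache=True, fastmath=True)
def cell_list_pairs(pos, npf, box, cutoff):
    """Cell-list inter-fibre pair search; equals brute force by construction.

    Falls back to the O(N^2) path when the box holds fewer than 3 cells per
    dimension (cell aliasing would double-count periodic neighbours) or the
    system is tiny.
    """
    N = pos.shape[0]
    ncx = int(box[0] / cutoff)
    ncy = int(box[1] / cutoff)
    ncz = int(box[2] / cutoff)
    # more cells than ~N is wasted memory/scan time (huge dilute boxes);
    # larger cells remain correct as long as the cell edge >= cutoff
    limit = int(round((4.0 * N) ** (1.0 / 3.0))) + 1
    if ncx > limit:
        ncx = limit
    if ncy > limit:
        ncy = limit
    if ncz > limit:
        ncz = limit
    if ncx < 3 or ncy < 3 or ncz < 3 or N < 64:
        return brute_force_pairs(pos, npf, box, cutoff)
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    hx = 0.5 * Lx
    hy = 0.5 * Ly
    hz = 0.5 * Lz
    wx = np.empty(N)
    wy = np.empty(N)
    wz = np.empty(N)
    cell = np.empty(N, np.int64)
    for i in range(N):
        x = pos[i, 0] - Lx * math.floor(pos[i, 0] / Lx)
        y = pos[i, 1] - Ly * math.floor(pos[i, 1] / Ly)
        z = pos[i, 2] - Lz * math.floor(pos[i, 2] / Lz)
        wx[i] = x
        wy[i] = y
        wz[i] = z
        cx = int(x / Lx * ncx)
        cy = int(y / Ly * ncy)
        cz = int(z / Lz * ncz)
        if cx >= ncx:
            cx = ncx - 1
        if cy >= ncy:
            cy = ncy - 1
        if cz >= ncz:
            cz = ncz - 1
        cell[i] = (cz * ncy + cy) * ncx + cx
    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, np.int64)
    nxt = np.empty(N, np.int64)
    for i in range(N):
        nxt[i] = head[cell[i]]
        head[cell[i]] = i
    c2 = cutoff * cutoff
    cap = 64 * N
    pi = np.empty(cap, np.int64)
    pj = np.empty(cap, np.int64)
    cnt = 0
    for i in range(N):
        fi = i // npf
        ci = cell[i]
        ccx = ci % ncx
        ccy = (ci // ncx) % ncy
        ccz = ci // (ncx * ncy)
        for ox in range(-1, 2):
            gx = ccx + ox
            if gx < 0:
                gx += ncx
            elif gx >= ncx:
                gx -= ncx
            for oy in range(-1, 2):
                gy = ccy + oy
                if gy < 0:
                    gy += ncy
                elif gy >= ncy:
                    gy -= ncy
                for oz in range(-1, 2):
                    gz = ccz + oz
                    if gz < 0:
                        gz += ncz
                    elif gz >= ncz:
                        gz -= ncz
                    j = head[(gz * ncy + gy) * ncx + gx]
                    while j != -1:
                        if j > i and j // npf != fi:
                            dx = wx[j] - wx[i]
                            dy = wy[j] - wy[i]
                            dz = wz[j] - wz[i]
                            if dx >= hx:
                                dx -= Lx
                            elif dx < -hx:
                                dx += Lx
                            if dy >= hy:
                                dy -= Ly
                            elif dy < -hy:
                                dy += Ly
                            if dz >= hz:
                                dz -= Lz
                            elif dz < -hz:
                                dz += Lz
                            if dx * dx + dy * dy + dz * dz < c2:
                                if cnt < cap:
                                    pi[cnt] = i
                                    pj[cnt] = j
                                cnt += 1
                        j = nxt[j]
    if cnt > cap:  # extremely dense edge case: fall back to exact two-pass
        return brute_force_pairs(pos, npf, box, cutoff)
    return pi[:cnt].copy(), pj[:cnt].copy()


@njit(cache=True, fastmath=True)
def integrate(pos, npf, box, nsteps, dt, c, kS, r0S, use_rk4,
              kB, theta0, kT, kA, r0A, a_th, kR, r0R,
              noise_std, skin, energy_every, E_out, rng_state, agg_nearest,
              partner):
    """Advance ``nsteps`` of the operator-split overdamped update.

    Per step: (1) Euler displacement from bend + torsion + aggregation +
    repulsion forces, (2) Box-Muller thermal displacement of per-axis std
    ``noise_std``, (3) the stretch term advanced by one classical RK4 step with
    the other contributions frozen.  The candidate pair list (Verlet list with
    ``skin``) is rebuilt whenever any node has moved more than skin/2 since
    the last build.  Energies of the pre-step configuration are written to
    ``E_out`` (columns W^S, W^B, W^T, W^A, W^R) every ``energy_every`` steps.
    Returns ``(status, n_samples)``; status 1 flags a non-finite energy.
    """
    N = pos.shape[0]
    F = np.empty((N, 3))
    Fs = np.empty((N, 3))
    k123 = np.empty((N, 3))
    tmp = np.empty((N, 3))
    wpos = np.empty((N, 3))
    noise = np.empty(3 * N)
    best_j = np.empty(N, np.int64)
    best_d2 = np.empty(N)
    refpos = pos.copy()
    list_cut = a_th + skin
    pi, pj = cell_list_pairs(pos, npf, box, list_cut)
    dtc = dt / c
    half_skin2 = 0.25 * skin * skin
    Lx = box[0]
    Ly = box[1]
    Lz = box[2]
    nsamp = 0
    for istep in range(nsteps):
        rebuild = False
        for i in range(N):
            ddx = pos[i, 0] - refpos[i, 0]
            ddy = pos[i, 1] - refpos[i, 1]
            ddz = pos[i, 2] - refpos[i, 2]
            if ddx * ddx + ddy * ddy + ddz * ddz > half_skin2:
                rebuild = True
                break
        if rebuild:
            pi, pj = cell_list_pairs(pos, npf, box, list_cut)
            for i in range(N):
                refpos[i, 0] = pos[i, 0]
                refpos[i, 1] = pos[i, 1]
                refpos[i, 2] = pos[i, 2]
        for i in range(N):
            wpos[i, 0] = pos[i, 0] - Lx * math.floor(pos[i, 0] / Lx)
            wpos[i, 1] = pos[i, 1] - Ly * math.floor(pos[i, 1] / Ly)
            wpos[i, 2] = pos[i, 2] - Lz * math.floor(pos[i, 2] / Lz)
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        WB = bend_forces(pos, npf, kB, theta0, F)
        WT = torsion_forces(pos, npf, kT, F)
        if agg_nearest:
            WA, WR = pair_forces_sticky(wpos, pi, pj, box, kA, r0A, a_th,
                                        kR, r0R, F, partner, best_j, best_d2)
        else:
            WA, WR = pair_forces_wrapped(wpos, pi, pj, box, kA, r0A, a_th,
                                         kR, r0R, F)
        if energy_every > 0 and istep % energy_every == 0:
            WS = stretch_forces_write(pos, npf, kS, r0S, Fs)
            if not math.isfinite(WS + WB + WT + WA + WR):
                return 1, nsamp
            E_out[nsamp, 0] = WS
            E_out[nsamp, 1] = WB
            E_out[nsamp, 2] = WT
            E_out[nsamp, 3] = WA
            E_out[nsamp, 4] = WR
            nsamp += 1
        if noise_std > 0.0:
            fill_standard_normal(noise, rng_state)
            for i in range(N):
                pos[i, 0] += dtc * F[i, 0] + noise_std * noise[3 * i]
                pos[i, 1] += dtc * F[i, 1] + noise_std * noise[3 * i + 1]
                pos[i, 2] += dtc * F[i, 2] + noise_std * noise[3 * i + 2]
        else:
            for i in range(N):
                pos[i, 0] += dtc * F[i, 0]
                pos[i, 1] += dtc * F[i, 1]
                pos[i, 2] += dtc * F[i, 2]
        if use_rk4:
            # classical RK4 on dr/dt = f^S(r)/c, other contributions frozen
            invc = 1.0 / c
            stretch_forces_write(pos, npf, kS, r0S, Fs)
            half = 0.5 * dt
            for i in range(N):
                kx = Fs[i, 0] * invc
                ky = Fs[i, 1] * invc
                kz = Fs[i, 2] * invc
                k123[i, 0] = kx
                k123[i, 1] = ky
                k123[i, 2] = kz
                tmp[i, 0] = pos[i, 0] + half * kx
                tmp[i, 1] = pos[i, 1] + half * ky
                tmp[i, 2] = pos[i, 2] + half * kz
            stretch_forces_write(tmp, npf, kS, r0S, Fs)
            for i in range(N):
                kx = Fs[i, 0] * invc
                ky = Fs[i, 1] * invc
                kz = Fs[i, 2] * invc
                k123[i, 0] += 2.0 * kx
                k123[i, 1] += 2.0 * ky
                k123[i, 2] += 2.0 * kz
                tmp[i, 0] = pos[i, 0] + half * kx
                tmp[i, 1] = pos[i, 1] + half * ky
                tmp[i, 2] = pos[i, 2] + half * kz
            stretch_forces_write(tmp, npf, kS, r0S, Fs)
            for i in range(N):
                kx = Fs[i, 0] * invc
                ky = Fs[i, 1] * invc
                kz = Fs[i, 2] * invc
                k123[i, 0] += 2.0 * kx
                k123[i, 1] += 2.0 * ky
                k123[i, 2] += 2.0 * kz
                tmp[i, 0] = pos[i, 0] + dt * kx
                tmp[i, 1] = pos[i, 1] + dt * ky
                tmp[i, 2] = pos[i, 2] + dt * kz
            stretch_forces_write(tmp, npf, kS, r0S, Fs)
            sixth = dt / 6.0
            for i in range(N):
                pos[i, 0] += sixth * (k123[i, 0] + Fs[i, 0] * invc)
                pos[i, 1] += sixth * (k123[i, 1] + Fs[i, 1] * invc)
                pos[i, 2] += sixth * (k123[i, 2] + Fs[i, 2] * invc)
        else:
            stretch_forces_write(pos, npf, kS, r0S, Fs)
            for i in range(N):
                pos[i, 0] += dtc * Fs[i, 0]
                pos[i, 1] += dtc * Fs[i, 1]
                pos[i, 2] += dtc * Fs[i, 2]
    return 0, nsamp
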