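"""Numba kernels: exact polygon writhe and the Brownian-dynamics inner loop.

The integrator advances bead positions and per-segment frame angles by
overdamped Euler-Maruyama steps.  Reference directors are carried along by
time-parallel transport each step (quasi-static frame), so material junction
twists pick up the geometric (writhe) contribution automatically and
Lk = Tw + Wr is conserved up to integration error.

Everything here is also implemented, more readably, in numpy in
:mod:`twistloop.chain` / :mod:`twistloop.state`; the test suite pins the two
routes against each other on small systems.
"""
from __future__ import annotations

import numpy as np
from numba import njit

WCA_CUT = 2.0 ** (1.0 / 6.0)
SKIN = 0.45

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_OVERFLOW = 2


# ---------------------------------------------------------------------------
# writhe: exact solid-angle sum over non-adjacent segment pairs
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def writhe_xyz(pos):
    """Exact writhe of a closed polygon via the pairwise solid-angle formula."""
    n = pos.shape[0]
    wr = 0.0
    for i in range(n - 1):
        p1 = pos[i]
        p2 = pos[(i + 1) % n]
        jmax = n if i > 0 else n - 1
        for j in range(i + 2, jmax):
            p3 = pos[j]
            p4 = pos[(j + 1) % n]
            # Gauss solid angle of segment pair (p1p2, p3p4)
            r13 = p3 - p1
            r14 = p4 - p1
            r23 = p3 - p2
            r24 = p4 - p2
            n1x = r13[1] * r14[2] - r13[2] * r14[1]
            n1y = r13[2] * r14[0] - r13[0] * r14[2]
            n1z = r13[0] * r14[1] - r13[1] * r14[0]
            n2x = r14[1] * r24[2] - r14[2] * r24[1]
            n2y = r14[2] * r24[0] - r14[0] * r24[2]
            n2z = r14[0] * r24[1] - r14[1] * r24[0]
            n3x = r24[1] * r23[2] - r24[2] * r23[1]
            n3y = r24[2] * r23[0] - r24[0] * r23[2]
            n3z = r24[0] * r23[1] - r24[1] * r23[0]
            n4x = r23[1] * r13[2] - r23[2] * r13[1]
            n4y = r23[2] * r13[0] - r23[0] * r13[2]
            n4z = r23[0] * r13[1] - r23[1] * r13[0]
            m1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
            m2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
            m3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
            m4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
            if m1 < 1e-14 or m2 < 1e-14 or m3 < 1e-14 or m4 < 1e-14:
                continue  # coplanar pair: zero solid angle
            a1 = (n1x * n2x + n1y * n2y + n1z * n2z) / (m1 * m2)
            a2 = (n2x * n3x + n2y * n3y + n2z * n3z) / (m2 * m3)
            a3 = (n3x * n4x + n3y * n4y + n3z * n4z) / (m3 * m4)
            a4 = (n4x * n1x + n4y * n1y + n4z * n1z) / (m4 * m1)
            a1 = min(1.0, max(-1.0, a1))
            a2 = min(1.0, max(-1.0, a2))
            a3 = min(1.0, max(-1.0, a3))
            a4 = min(1.0, max(-1.0, a4))
            omega = np.arcsin(a1) + np.arcsin(a2) + np.arcsin(a3) + np.arcsin(a4)
            # sign from (r34 x r12) . r13
            r12 = p2 - p1
            r34 = p4 - p3
            cx = r34[1] * r12[2] - r34[2] * r12[1]
            cy = r34[2] * r12[0] - r34[0] * r12[2]
            cz = r34[0] * r12[1] - r34[1] * r12[0]
            s = cx * r13[0] + cy * r13[1] + cz * r13[2]
            if s > 0.0:
                wr += omega
            elif s < 0.0:
                wr -= omega
    return wr / (2.0 * np.pi)


@njit(cache=True)
def writhe_series(frames):
    out = np.empty(frames.shape[0])
    for f in range(frames.shape[0]):
        out[f] = writhe_xyz(frames[f])
    return out


# ---------------------------------------------------------------------------
# small vector helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _transport(vx, vy, vz, ax, ay, az, bx, by, bz):
    """Parallel transport of v by the minimal rotation a -> b (unit tangents)."""
    kx = ay * bz - az * by
    ky = az * bx - ax * bz
    kz = ax * by - ay * bx
    s2 = kx * kx + ky * ky + kz * kz
    c = ax * bx + ay * by + az * bz
    if s2 < 1e-14:
        return vx, vy, vz
    kv = kx * vx + ky * vy + kz * vz
    f = kv * (1.0 - c) / s2
    rx = vx * c + (ky * vz - kz * vy) + kx * f
    ry = vy * c + (kz * vx - kx * vz) + ky * f
    rz = vz * c + (kx * vy - ky * vx) + kz * f
    return rx, ry, rz


# ---------------------------------------------------------------------------
# neighbour list
# ---------------------------------------------------------------------------

@njit(cache=True)
def _excluded(i, j, ring_of, loc, ring_n, ring_closed):
    if ring_of[i] == ring_of[j]:
        n = ring_n[ring_of[i]]
        d = loc[j] - loc[i]
        if d < 0:
            d = -d
        if d == 1:
            return True
        if ring_closed[ring_of[i]] == 1 and d == n - 1:
            return True
    return False


@njit(cache=True, fastmath=True)
def _build_pairs(pos, box_edge, cut, ring_of, loc, ring_n, ring_closed,
                 aff_flag, ia, ja):
    """Fill (ia, ja) with candidate WCA pairs within ``cut``; return count."""
    m = pos.shape[0]
    cut2 = cut * cut
    cap = ia.shape[0]
    cnt = 0
    use_cells = m > 220
    cwx = cut
    cwy = cut
    cwz = cut
    if use_cells:
        # cell grid over (wrapped) bounding region; grid capped at ~8 cells
        # per bead (cells may be wider than the cutoff, never narrower)
        if box_edge > 0.0:
            ncx = int(box_edge / cut)
            if ncx < 3:
                use_cells = False
            ncy = ncx
            ncz = ncx
            ox = 0.0
            oy = 0.0
            oz = 0.0
            cwx = box_edge / max(ncx, 1)
            cwy = cwx
            cwz = cwx
        else:
            xmin = pos[:, 0].min()
            ymin = pos[:, 1].min()
            zmin = pos[:, 2].min()
            ex = pos[:, 0].max() - xmin
            ey = pos[:, 1].max() - ymin
            ez = pos[:, 2].max() - zmin
            ncx = int(ex / cut) + 1
            ncy = int(ey / cut) + 1
            ncz = int(ez / cut) + 1
            cap_cells = 8 * m
            while ncx * ncy * ncz > cap_cells:
                if ncx >= ncy and ncx >= ncz:
                    ncx = (ncx + 1) // 2
                elif ncy >= ncz:
                    ncy = (ncy + 1) // 2
                else:
                    ncz = (ncz + 1) // 2
            if ncx * ncy * ncz < 27:
                use_cells = False
            ox, oy, oz = xmin, ymin, zmin
            cwx = ex / ncx + 1e-9
            cwy = ey / ncy + 1e-9
            cwz = ez / ncz + 1e-9
            if cwx < cut:
                cwx = cut
            if cwy < cut:
                cwy = cut
            if cwz < cut:
                cwz = cut
    if not use_cells:
        for i in range(m):
            for j in range(i + 1, m):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                if box_edge > 0.0:
                    dx -= box_edge * np.rint(dx / box_edge)
                    dy -= box_edge * np.rint(dy / box_edge)
                    dz -= box_edge * np.rint(dz / box_edge)
                if dx * dx + dy * dy + dz * dz < cut2:
                    if not _excluded(i, j, ring_of, loc, ring_n, ring_closed) and not (
                        aff_flag[i] == 1 and aff_flag[j] == 2
                    ) and not (aff_flag[i] == 2 and aff_flag[j] == 1):
                        if cnt >= cap:
                            return -1
                        ia[cnt] = i
                        ja[cnt] = j
                        cnt += 1
        return cnt

    ncell = ncx * ncy * ncz
    head = np.full(ncell, -1, dtype=np.int64)
    nxt = np.empty(m, dtype=np.int64)
    cix = np.empty(m, dtype=np.int64)
    for i in range(m):
        x = pos[i, 0] - ox
        y = pos[i, 1] - oy
        z = pos[i, 2] - oz
        if box_edge > 0.0:
            x -= box_edge * np.floor(x / box_edge)
            y -= box_edge * np.floor(y / box_edge)
            z -= box_edge * np.floor(z / box_edge)
        cx = min(int(x / cwx), ncx - 1)
        cy = min(int(y / cwy), ncy - 1)
        cz = min(int(z / cwz), ncz - 1)
        c = (cx * ncy + cy) * ncz + cz
        cix[i] = c
        nxt[i] = head[c]
        head[c] = i
    for i in range(m):
        c = cix[i]
        cz0 = c % ncz
        cy0 = (c // ncz) % ncy
        cx0 = c // (ncy * ncz)
        for dxc in range(-1, 2):
            cx1 = cx0 + dxc
            if box_edge > 0.0:
                cx1 = cx1 % ncx
            elif cx1 < 0 or cx1 >= ncx:
                continue
            for dyc in range(-1, 2):
                cy1 = cy0 + dyc
                if box_edge > 0.0:
                    cy1 = cy1 % ncy
                elif cy1 < 0 or cy1 >= ncy:
                    continue
                for dzc in range(-1, 2):
                    cz1 = cz0 + dzc
                    if box_edge > 0.0:
                        cz1 = cz1 % ncz
                    elif cz1 < 0 or cz1 >= ncz:
                        continue
                    j = head[(cx1 * ncy + cy1) * ncz + cz1]
                    while j >= 0:
                        if j > i:
                            dx = pos[j, 0] - pos[i, 0]
                            dy = pos[j, 1] - pos[i, 1]
                            dz = pos[j, 2] - pos[i, 2]
                            if box_edge > 0.0:
                                dx -= box_edge * np.rint(dx / box_edge)
                                dy -= box_edge * np.rint(dy / box_edge)
                                dz -= box_edge * np.rint(dz / box_edge)
                            if dx * dx + dy * dy + dz * dz < cut2:
                                if not _excluded(i, j, ring_of, loc, ring_n, ring_closed) and not (
                                    aff_flag[i] == 1 and aff_flag[j] == 2
                                ) and not (aff_flag[i] == 2 and aff_flag[j] == 1):
                                    if cnt >= cap:
                                        return -1
                                    ia[cnt] = i
                                    ja[cnt] = j
                                    cnt += 1
                        j = nxt[j]
    return cnt


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _forces(pos, theta, dirA, dirT, ring_start, ring_closed,
            k_bond, r0, k_bend, k_tor, cos_phi0, sin_phi0,
            eps_wca, sigma, eps_aff, rcut_aff,
            extra_bonds, aff_pairs, box_edge,
            ia, ja, npairs, F, tq, phi,
            tarr, barr, marr, want_phi, fcap):
    """Fill forces F and frame torques tq; update directors in place.

    Two passes per ring: (1) edges: bonds, tangents, time-parallel director
    transport, material directors; (2) junctions: bending, torsion (through
    the curvature binormal) and frame torques.  The junction twist angle
    itself (atan2) is only evaluated into ``phi`` when ``want_phi`` is set;
    the torque needs just its sine/cosine.
    """
    m = pos.shape[0]
    nrings = ring_start.shape[0] - 1
    for i in range(m):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
        tq[i] = 0.0

    for r in range(nrings):
        lo = ring_start[r]
        hi = ring_start[r + 1]
        n = hi - lo
        closed = ring_closed[r] == 1
        nedge = n if closed else n - 1
        if n < 2:
            continue
        # --- pass 1: edges ---------------------------------------------
        for e in range(nedge):
            i = lo + e
            j = lo + ((e + 1) % n)
            ex = pos[j, 0] - pos[i, 0]
            ey = pos[j, 1] - pos[i, 1]
            ez = pos[j, 2] - pos[i, 2]
            b = np.sqrt(ex * ex + ey * ey + ez * ez)
            if b < 1e-12:
                return STATUS_NONFINITE
            fb = k_bond * (b - r0) / b
            F[i, 0] += fb * ex
            F[i, 1] += fb * ey
            F[i, 2] += fb * ez
            F[j, 0] -= fb * ex
            F[j, 1] -= fb * ey
            F[j, 2] -= fb * ez
            barr[i] = b
            tx, ty, tz = ex / b, ey / b, ez / b
            tarr[i, 0] = tx
            tarr[i, 1] = ty
            tarr[i, 2] = tz
            if n >= 3:
                ax, ay, az = _transport(
                    dirA[i, 0], dirA[i, 1], dirA[i, 2],
                    dirT[i, 0], dirT[i, 1], dirT[i, 2], tx, ty, tz,
                )
                d = ax * tx + ay * ty + az * tz
                ax -= d * tx
                ay -= d * ty
                az -= d * tz
                na = np.sqrt(ax * ax + ay * ay + az * az)
                ax /= na
                ay /= na
                az /= na
                dirA[i, 0] = ax
                dirA[i, 1] = ay
                dirA[i, 2] = az
                dirT[i, 0] = tx
                dirT[i, 1] = ty
                dirT[i, 2] = tz
                ct = np.cos(theta[i])
                st = np.sin(theta[i])
                marr[i, 0] = ax * ct + (ty * az - tz * ay) * st
                marr[i, 1] = ay * ct + (tz * ax - tx * az) * st
                marr[i, 2] = az * ct + (tx * ay - ty * ax) * st
        if n < 3:
            continue
        # --- pass 2: junctions -----------------------------------------
        njunc = n if closed else n - 2
        for jn in range(njunc):
            e1 = lo + jn
            e2 = lo + ((jn + 1) % n)
            i0 = e1
            i1 = lo + ((jn + 1) % n)
            i2 = lo + ((jn + 2) % n)
            b1 = barr[e1]
            b2 = barr[e2]
            t1x, t1y, t1z = tarr[e1, 0], tarr[e1, 1], tarr[e1, 2]
            t2x, t2y, t2z = tarr[e2, 0], tarr[e2, 1], tarr[e2, 2]
            c = t1x * t2x + t1y * t2y + t1z * t2z
            # bending E = k_bend (1 - c)
            g1x = (t2x - c * t1x) / b1
            g1y = (t2y - c * t1y) / b1
            g1z = (t2z - c * t1z) / b1
            g2x = (t1x - c * t2x) / b2
            g2y = (t1y - c * t2y) / b2
            g2z = (t1z - c * t2z) / b2
            F[i0, 0] += -k_bend * g1x
            F[i0, 1] += -k_bend * g1y
            F[i0, 2] += -k_bend * g1z
            F[i1, 0] += k_bend * (g1x - g2x)
            F[i1, 1] += k_bend * (g1y - g2y)
            F[i1, 2] += k_bend * (g1z - g2z)
            F[i2, 0] += k_bend * g2x
            F[i2, 1] += k_bend * g2y
            F[i2, 2] += k_bend * g2z
            # junction twist via transported material director
            m1x, m1y, m1z = _transport(
                marr[e1, 0], marr[e1, 1], marr[e1, 2],
                t1x, t1y, t1z, t2x, t2y, t2z,
            )
            m2x, m2y, m2z = marr[e2, 0], marr[e2, 1], marr[e2, 2]
            crx = m1y * m2z - m1z * m2y
            cry = m1z * m2x - m1x * m2z
            crz = m1x * m2y - m1y * m2x
            sphi = crx * t2x + cry * t2y + crz * t2z
            cphi = m1x * m2x + m1y * m2y + m1z * m2z
            inv = 1.0 / np.sqrt(sphi * sphi + cphi * cphi)
            sphi *= inv
            cphi *= inv
            if want_phi == 1:
                phi[e1] = np.arctan2(sphi, cphi)
            # dV/dphi = 0.5 k sin(phi - phi0)
            g = 0.5 * k_tor * (sphi * cos_phi0[e1] - cphi * sin_phi0[e1])
            tq[e1] += g
            tq[e2] -= g
            denom = b1 * b2 * (1.0 + c)
            kbx = 2.0 * b1 * b2 * (t1y * t2z - t1z * t2y) / denom
            kby = 2.0 * b1 * b2 * (t1z * t2x - t1x * t2z) / denom
            kbz = 2.0 * b1 * b2 * (t1x * t2y - t1y * t2x) / denom
            d1 = 1.0 / (2.0 * b1)
            d2 = 1.0 / (2.0 * b2)
            F[i0, 0] += g * kbx * d1
            F[i0, 1] += g * kby * d1
            F[i0, 2] += g * kbz * d1
            F[i1, 0] -= g * (kbx * d1 - kbx * d2)
            F[i1, 1] -= g * (kby * d1 - kby * d2)
            F[i1, 2] -= g * (kbz * d1 - kbz * d2)
            F[i2, 0] -= g * kbx * d2
            F[i2, 1] -= g * kby * d2
            F[i2, 2] -= g * kbz * d2

    # --- extra harmonic bonds (tethers) --------------------------------
    for bnd in range(extra_bonds.shape[0]):
        i = extra_bonds[bnd, 0]
        j = extra_bonds[bnd, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if box_edge > 0.0:
            dx -= box_edge * np.rint(dx / box_edge)
            dy -= box_edge * np.rint(dy / box_edge)
            dz -= box_edge * np.rint(dz / box_edge)
        b = np.sqrt(dx * dx + dy * dy + dz * dz)
        fb = k_bond * (b - r0) / b
        F[i, 0] += fb * dx
        F[i, 1] += fb * dy
        F[i, 2] += fb * dz
        F[j, 0] -= fb * dx
        F[j, 1] -= fb * dy
        F[j, 2] -= fb * dz

    # --- excluded volume over the neighbour list -----------------------
    wcut2 = (WCA_CUT * sigma) ** 2
    for p in range(npairs):
        i = ia[p]
        j = ja[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if box_edge > 0.0:
            dx -= box_edge * np.rint(dx / box_edge)
            dy -= box_edge * np.rint(dy / box_edge)
            dz -= box_edge * np.rint(dz / box_edge)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= wcut2 or r2 < 1e-12:
            continue
        sr2 = sigma * sigma / r2
        sr6 = sr2 * sr2 * sr2
        fr = 24.0 * eps_wca * (2.0 * sr6 * sr6 - sr6) / r2  # -dV/dr / r
        if fr * fr * r2 > fcap * fcap:  # cap the pair force magnitude
            fr = fcap / np.sqrt(r2)
        F[i, 0] -= fr * dx
        F[i, 1] -= fr * dy
        F[i, 2] -= fr * dz
        F[j, 0] += fr * dx
        F[j, 1] += fr * dy
        F[j, 2] += fr * dz

    # --- affinity pairs -------------------------------------------------
    acut2 = rcut_aff * rcut_aff
    for p in range(aff_pairs.shape[0]):
        i = aff_pairs[p, 0]
        j = aff_pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        if box_edge > 0.0:
            dx -= box_edge * np.rint(dx / box_edge)
            dy -= box_edge * np.rint(dy / box_edge)
            dz -= box_edge * np.rint(dz / box_edge)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            continue
        if eps_aff > 0.0:
            if r2 >= acut2:
                continue
            sr2 = sigma * sigma / r2
            sr6 = sr2 * sr2 * sr2
            fr = 24.0 * eps_aff * (2.0 * sr6 * sr6 - sr6) / r2
        else:
            if r2 >= wcut2:
                continue
            sr2 = sigma * sigma / r2
            sr6 = sr2 * sr2 * sr2
            fr = 24.0 * eps_wca * (2.0 * sr6 * sr6 - sr6) / r2
        if fr * fr * r2 > fcap * fcap:
            fr = (fcap if fr > 0.0 else -fcap) / np.sqrt(r2)
        F[i, 0] -= fr * dx
        F[i, 1] -= fr * dy
        F[i, 2] -= fr * dz
        F[j, 0] += fr * dx
        F[j, 1] += fr * dy
        F[j, 2] += fr * dz
    return STATUS_OK


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def bd_init(pos, aff_pairs, ring_start):
    """Static index arrays for a run: (ring_of, loc, ring_n, aff_flag)."""
    m = pos.shape[0]
    nrings = ring_start.shape[0] - 1
    ring_of = np.empty(m, dtype=np.int64)
    loc = np.empty(m, dtype=np.int64)
    ring_n = np.empty(nrings, dtype=np.int64)
    aff_flag = np.zeros(m, dtype=np.int64)
    for p in range(aff_pairs.shape[0]):
        aff_flag[aff_pairs[p, 0]] = 1
        aff_flag[aff_pairs[p, 1]] = 2
    for r in range(nrings):
        ring_n[r] = ring_start[r + 1] - ring_start[r]
        for i in range(ring_start[r], ring_start[r + 1]):
            ring_of[i] = r
            loc[i] = i - ring_start[r]
    return ring_of, loc, ring_n, aff_flag


@njit(cache=True)
def bd_chunk(pos, theta, dirA, dirT, ring_start, ring_closed,
             extra_bonds, aff_pairs, phi0,
             k_bond, r0, k_bend, k_tor, eps_wca, sigma, eps_aff, rcut_aff,
             box_edge, dt, gamma, gamma_r, kT, noise, step0, sample_every,
             fcap, ring_of, loc, ring_n, aff_flag, ia, ja, npairs_in,
             pos_ref, out_pos, out_phi, out_t, ns_in):
    """Advance ``noise.shape[0]`` BD steps using pre-drawn standard normals.

    ``noise`` has shape (steps, 4*m): 3m position components then m frame
    components per step.  Neighbour-list state (ia, ja, npairs, pos_ref)
    persists across chunks.  Samples are written whenever the global step
    index hits a multiple of ``sample_every``.  Returns
    (status, npairs, n_samples, n_steps_done).
    """
    m = pos.shape[0]
    F = np.empty((m, 3))
    tq = np.empty(m)
    phi = np.zeros(m)
    tarr = np.empty((m, 3))
    barr = np.empty(m)
    marr = np.empty((m, 3))
    cos_phi0 = np.cos(phi0)
    sin_phi0 = np.sin(phi0)
    list_cut = WCA_CUT * sigma + SKIN
    half_skin2 = (SKIN / 2.0) ** 2
    sq = np.sqrt(2.0 * kT * dt / gamma)
    sq_r = np.sqrt(2.0 * kT * dt / gamma_r)
    inv_g = dt / gamma
    inv_gr = dt / gamma_r
    npairs = npairs_in
    ns = ns_in

    if step0 == 0:
        npairs = _build_pairs(pos, box_edge, list_cut, ring_of, loc, ring_n,
                              ring_closed, aff_flag, ia, ja)
        if npairs < 0:
            return STATUS_OVERFLOW, npairs, ns, 0
        pos_ref[:, :] = pos
        status = _forces(pos, theta, dirA, dirT, ring_start, ring_closed,
                         k_bond, r0, k_bend, k_tor, cos_phi0, sin_phi0,
                         eps_wca, sigma, eps_aff, rcut_aff, extra_bonds,
                         aff_pairs, box_edge, ia, ja, npairs, F, tq, phi,
                         tarr, barr, marr, 1, fcap)
        if status != STATUS_OK:
            return status, npairs, ns, 0
        out_t[ns] = 0.0
        for i in range(m):
            out_pos[ns, i, 0] = pos[i, 0]
            out_pos[ns, i, 1] = pos[i, 1]
            out_pos[ns, i, 2] = pos[i, 2]
            out_phi[ns, i] = phi[i]
        ns += 1
    else:
        status = _forces(pos, theta, dirA, dirT, ring_start, ring_closed,
                         k_bond, r0, k_bend, k_tor, cos_phi0, sin_phi0,
                         eps_wca, sigma, eps_aff, rcut_aff, extra_bonds,
                         aff_pairs, box_edge, ia, ja, npairs, F, tq, phi,
                         tarr, barr, marr, 0, fcap)
        if status != STATUS_OK:
            return status, npairs, ns, 0

    nsteps = noise.shape[0]
    for s in range(nsteps):
        step = step0 + s + 1
        want_phi = 1 if step % sample_every == 0 else 0
        for i in range(m):
            pos[i, 0] += F[i, 0] * inv_g + sq * noise[s, 3 * i]
            pos[i, 1] += F[i, 1] * inv_g + sq * noise[s, 3 * i + 1]
            pos[i, 2] += F[i, 2] * inv_g + sq * noise[s, 3 * i + 2]
            theta[i] += tq[i] * inv_gr + sq_r * noise[s, 3 * m + i]
        maxd2 = 0.0
        for i in range(m):
            ddx = pos[i, 0] - pos_ref[i, 0]
            ddy = pos[i, 1] - pos_ref[i, 1]
            ddz = pos[i, 2] - pos_ref[i, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > maxd2:
                maxd2 = d2
        if maxd2 > half_skin2:
            npairs = _build_pairs(pos, box_edge, list_cut, ring_of, loc,
                                  ring_n, ring_closed, aff_flag, ia, ja)
            if npairs < 0:
                return STATUS_OVERFLOW, npairs, ns, s
            pos_ref[:, :] = pos
        status = _forces(pos, theta, dirA, dirT, ring_start, ring_closed,
                         k_bond, r0, k_bend, k_tor, cos_phi0, sin_phi0,
                         eps_wca, sigma, eps_aff, rcut_aff, extra_bonds,
                         aff_pairs, box_edge, ia, ja, npairs, F, tq, phi,
                         tarr, barr, marr, want_phi, fcap)
        if status != STATUS_OK:
            return status, npairs, ns, s
        if want_phi == 1:
            ok = True
            for i in range(m):
                if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                        and np.isfinite(pos[i, 2]) and np.isfinite(theta[i])):
                    ok = False
            if not ok:
                return STATUS_NONFINITE, npairs, ns, s
            out_t[ns] = step * dt
            for i in range(m):
                out_pos[ns, i, 0] = pos[i, 0]
                out_pos[ns, i, 1] = pos[i, 1]
                out_pos[ns, i, 2] = pos[i, 2]
                out_phi[ns, i] = phi[i]
            ns += 1
    return STATUS_OK, npairs, ns, nsteps
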