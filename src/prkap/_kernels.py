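"""Numba-compiled inner loops: neighbour list, pair/bonded forces, BAOAB chunks.

All kernels use minimum-image distances in a cubic periodic box and the
package unit system (nm, ps, Da, kJ/mol).  Scalar force-field parameters
are packed into a flat float64 vector ``p`` (see ``forcefield.pack_params``):

    p[0]  coulomb prefactor (already divided by eps_r in constant mode)
    p[1]  debye length (nm)
    p[2]  nonbonded cutoff (nm)
    p[3]  cation-pi prefactor  depth/(1+g(rc))
    p[4]  cation-pi sigma (well-minimum distance, nm)
    p[5]  cation-pi g(rc) shift
    p[6]  excluded-volume strength (kJ/mol)
    p[7]  excluded-volume diameter (nm)
    p[8]  hydrophobic sigma (nm)
    p[9]  hydrophobic g(rc) shift
    p[10] hydrophobic max depth (kJ/mol)
    p[11] electrostatic shift per unit q_i q_j at cutoff
    p[12] dielectric mode (0 constant, 1 distance-dependent)
    p[13] eps_s (bulk relative permittivity)
    p[14] eps_min (contact permittivity, distance mode)
    p[15] eps_xi (saturation length, distance mode, nm)

Pair types: 0 receptor intra-chain (excluded volume only), 1 chain-receptor
(electrostatic + cation-pi + excluded volume), 2 chain-chain (electrostatic +
hydrophobic + excluded volume), 3 receptor-receptor inter-chain
(electrostatic + excluded volume).
"""

import numpy as np
from numba import njit

NP = 16  # length of packed parameter vector


@njit(cache=True)
def _build_pairs(pos, box, chain_index, role, rc_short, rc_long):
    """O(N^2) candidate pair scan.  Excludes same-chain |i-j| < 2."""
    n = pos.shape[0]
    rc2s = rc_short * rc_short
    rc2l = rc_long * rc_long
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_index[i] == chain_index[j] and j - i < 2:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if role[i] == 0 and role[j] == 0 and chain_index[i] == chain_index[j]:
                if r2 <= rc2s:
                    count += 1
            elif r2 <= rc2l:
                count += 1
    pi = np.empty(count, dtype=np.int64)
    pj = np.empty(count, dtype=np.int64)
    pt = np.empty(count, dtype=np.int8)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            if chain_index[i] == chain_index[j] and j - i < 2:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box * np.rint(dx / box)
            dy -= box * np.rint(dy / box)
            dz -= box * np.rint(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            same = chain_index[i] == chain_index[j]
            if role[i] == 0 and role[j] == 0:
                if same:
                    if r2 <= rc2s:
                        pi[k] = i
                        pj[k] = j
                        pt[k] = 0
                        k += 1
                else:
                    if r2 <= rc2l:
                        pi[k] = i
                        pj[k] = j
                        pt[k] = 3
                        k += 1
            elif role[i] == 1 and role[j] == 1:
                if r2 <= rc2l:
                    pi[k] = i
                    pj[k] = j
                    pt[k] = 2
                    k += 1
            else:
                if r2 <= rc2l:
                    pi[k] = i
                    pj[k] = j
                    pt[k] = 1
                    k += 1
    return pi, pj, pt


@njit(cache=True)
def _pair_forces(pos, box, charge, cationic, aromatic, hydro, pi, pj, pt, p, f):
    """Accumulate nonbonded forces; returns per-term energies.

    Returns (elec, cation_pi, excluded_volume, hydrophobic, r_min).
    """
    e_el = 0.0
    e_cp = 0.0
    e_ev = 0.0
    e_hp = 0.0
    r_min = 1.0e30
    rc = p[2]
    lam = p[1]
    ck = p[0]
    ev_k = p[6]
    ev_s = p[7]
    for m in range(pi.shape[0]):
        i = pi[m]
        j = pj[m]
        t = pt[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < r_min:
            r_min = r
        if r <= 1.0e-6:
            continue  # flagged by caller via r_min
        fmag = 0.0  # dU/dr accumulated; force = -fmag * rhat

        # excluded volume (all pair types)
        if r < ev_s:
            s2 = (ev_s * ev_s) / r2
            s6 = s2 * s2 * s2
            s12 = s6 * s6
            e_ev += ev_k * (s12 - 2.0 * s6 + 1.0)
            fmag += ev_k * (-12.0) * (s12 - s6) / r

        if t != 0 and r < rc:
            qq = charge[i] * charge[j]
            if qq != 0.0:
                if p[12] == 0.0:
                    u0 = ck * qq * np.exp(-r / lam) / r
                    e_el += u0 - qq * p[11]
                    fmag += -u0 * (1.0 / lam + 1.0 / r)
                else:
                    eps = p[14] + (p[13] - p[14]) * (1.0 - np.exp(-r / p[15]))
                    deps = (p[13] - p[14]) / p[15] * np.exp(-r / p[15])
                    u0 = ck * qq * np.exp(-r / lam) / (eps * r)
                    e_el += u0 - qq * p[11]
                    fmag += -u0 * (1.0 / lam + 1.0 / r + deps / eps)

            if t == 1:
                if (cationic[i] and aromatic[j]) or (aromatic[i] and cationic[j]):
                    s = p[4] / r
                    s6 = s * s * s * s * s * s
                    s12 = s6 * s6
                    g = s12 - 2.0 * s6
                    e_cp += p[3] * (g - p[5])
                    fmag += p[3] * (-12.0) * (s12 - s6) / r
            elif t == 2:
                hh = hydro[i] * hydro[j]
                if hh > 0.0:
                    eps_hp = p[10] * np.sqrt(hh) / (1.0 + p[9]) if p[9] > -1.0 else 0.0
                    s = p[8] / r
                    s6 = s * s * s * s * s * s
                    s12 = s6 * s6
                    g = s12 - 2.0 * s6
                    e_hp += eps_hp * (g - p[9])
                    fmag += eps_hp * (-12.0) * (s12 - s6) / r

        if fmag != 0.0:
            fx = -fmag * dx / r
            fy = -fmag * dy / r
            fz = -fmag * dz / r
            f[i, 0] += fx
            f[i, 1] += fy
            f[i, 2] += fz
            f[j, 0] -= fx
            f[j, 1] -= fy
            f[j, 2] -= fz
    return e_el, e_cp, e_ev, e_hp, r_min


@njit(cache=True)
def _bonded_forces(pos, box,
                   bond_i, bond_j, bond_r0, bond_k,
                   el_i, el_j, el_r0, el_k,
                   ang_i, ang_j, ang_k, ang_kf, ang_t0,
                   tor_i, tor_j, tor_k, tor_l, tor_kf, tor_p0,
                   tet_idx, tet_k, tet_c,
                   f):
    """Accumulate bonded forces; returns (bonded_energy, elastic_energy)."""
    e_bond = 0.0
    e_el = 0.0

    for m in range(bond_i.shape[0]):
        i = bond_i[m]
        j = bond_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_r0[m]
        e_bond += 0.5 * bond_k * dr * dr
        fmag = -bond_k * dr / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz

    for m in range(el_i.shape[0]):
        i = el_i[m]
        j = el_j[m]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box * np.rint(dx / box)
        dy -= box * np.rint(dy / box)
        dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - el_r0[m]
        e_el += 0.5 * el_k * dr * dr
        fmag = -el_k * dr / r
        f[i, 0] += fmag * dx
        f[i, 1] += fmag * dy
        f[i, 2] += fmag * dz
        f[j, 0] -= fmag * dx
        f[j, 1] -= fmag * dy
        f[j, 2] -= fmag * dz

    for m in range(ang_i.shape[0]):
        i = ang_i[m]
        j = ang_j[m]
        k = ang_k[m]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        ux -= box * np.rint(ux / box)
        uy -= box * np.rint(uy / box)
        uz -= box * np.rint(uz / box)
        vx -= box * np.rint(vx / box)
        vy -= box * np.rint(vy / box)
        vz -= box * np.rint(vz / box)
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        if ct > 1.0:
            ct = 1.0
        if ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1.0e-8:
            st = 1.0e-8
        dth = theta - ang_t0[m]
        e_bond += 0.5 * ang_kf[m] * dth * dth
        coef = -ang_kf[m] * dth / st
        # dtheta/dri = (ct*uhat - vhat)/lu ; force = -dU/dtheta * dtheta/dr
        fix = coef * (ct * ux / lu - vx / lv) / lu
        fiy = coef * (ct * uy / lu - vy / lv) / lu
        fiz = coef * (ct * uz / lu - vz / lv) / lu
        fkx = coef * (ct * vx / lv - ux / lu) / lv
        fky = coef * (ct * vy / lv - uy / lu) / lv
        fkz = coef * (ct * vz / lv - uz / lu) / lv
        f[i, 0] += fix
        f[i, 1] += fiy
        f[i, 2] += fiz
        f[k, 0] += fkx
        f[k, 1] += fky
        f[k, 2] += fkz
        f[j, 0] -= fix + fkx
        f[j, 1] -= fiy + fky
        f[j, 2] -= fiz + fkz

    for m in range(tor_i.shape[0]):
        i = tor_i[m]
        j = tor_j[m]
        k = tor_k[m]
        l = tor_l[m]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        b1x -= box * np.rint(b1x / box)
        b1y -= box * np.rint(b1y / box)
        b1z -= box * np.rint(b1z / box)
        b2x -= box * np.rint(b2x / box)
        b2y -= box * np.rint(b2y / box)
        b2z -= box * np.rint(b2z / box)
        b3x -= box * np.rint(b3x / box)
        b3y -= box * np.rint(b3y / box)
        b3z -= box * np.rint(b3z / box)
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        b1sq = b1x * b1x + b1y * b1y + b1z * b1z
        b2sq = b2x * b2x + b2y * b2y + b2z * b2z
        b3sq = b3x * b3x + b3y * b3y + b3z * b3z
        lb2 = np.sqrt(b2sq)
        # The bare dihedral gradient diverges (~1/sin theta) as either
        # flanking pseudo-bond angle approaches collinearity.  The torsion
        # is therefore smoothly switched off with s(x) = x/(x + xc) on each
        # x = sin^2(theta), which keeps energy and force continuous (and
        # the integrator stable at dt = 0.02 ps).
        if n1sq < 1.0e-9 or n2sq < 1.0e-9 or lb2 < 1.0e-8:
            continue  # fully inside the switched-off region
        xc = 0.02
        x1 = n1sq / (b1sq * b2sq)
        x2 = n2sq / (b2sq * b3sq)
        sw1 = x1 / (x1 + xc)
        sw2 = x2 / (x2 + xc)
        dsw1 = xc / ((x1 + xc) * (x1 + xc))
        dsw2 = xc / ((x2 + xc) * (x2 + xc))
        mx = n1y * b2z - n1z * b2y
        my = n1z * b2x - n1x * b2z
        mz = n1x * b2y - n1y * b2x
        x = n1x * n2x + n1y * n2y + n1z * n2z
        y = (mx * n2x + my * n2y + mz * n2z) / lb2
        phi = np.arctan2(y, x)
        tors = tor_kf[m] * (1.0 + np.cos(phi - tor_p0[m]))
        e_bond += sw1 * sw2 * tors
        dudphi = -sw1 * sw2 * tor_kf[m] * np.sin(phi - tor_p0[m])
        # dphi/dri = (lb2/n1sq) n1 ; dphi/drl = -(lb2/n2sq) n2
        gix = (lb2 / n1sq) * n1x
        giy = (lb2 / n1sq) * n1y
        giz = (lb2 / n1sq) * n1z
        glx = -(lb2 / n2sq) * n2x
        gly = -(lb2 / n2sq) * n2y
        glz = -(lb2 / n2sq) * n2z
        s1 = (b1x * b2x + b1y * b2y + b1z * b2z) / b2sq
        s2 = (b3x * b2x + b3y * b2y + b3z * b2z) / b2sq
        gjx = -(1.0 + s1) * gix + s2 * glx
        gjy = -(1.0 + s1) * giy + s2 * gly
        gjz = -(1.0 + s1) * giz + s2 * glz
        gkx = -gix - gjx - glx
        gky = -giy - gjy - gly
        gkz = -giz - gjz - glz
        f[i, 0] -= dudphi * gix
        f[i, 1] -= dudphi * giy
        f[i, 2] -= dudphi * giz
        f[j, 0] -= dudphi * gjx
        f[j, 1] -= dudphi * gjy
        f[j, 2] -= dudphi * gjz
        f[k, 0] -= dudphi * gkx
        f[k, 1] -= dudphi * gky
        f[k, 2] -= dudphi * gkz
        f[l, 0] -= dudphi * glx
        f[l, 1] -= dudphi * gly
        f[l, 2] -= dudphi * glz
        # switch-gradient contribution: grad(s1*s2) * torsion energy
        c1 = b1x * b2x + b1y * b2y + b1z * b2z
        c2 = b2x * b3x + b2y * b3y + b2z * b3z
        # d x1 / d b1 and d b2 ; x1 = 1 - (b1.b2)^2/(b1^2 b2^2)
        a1 = 2.0 * c1 / (b1sq * b2sq)
        w1b1x = a1 * (c1 / b1sq * b1x - b2x)
        w1b1y = a1 * (c1 / b1sq * b1y - b2y)
        w1b1z = a1 * (c1 / b1sq * b1z - b2z)
        w1b2x = a1 * (c1 / b2sq * b2x - b1x)
        w1b2y = a1 * (c1 / b2sq * b2y - b1y)
        w1b2z = a1 * (c1 / b2sq * b2z - b1z)
        a2 = 2.0 * c2 / (b2sq * b3sq)
        w2b2x = a2 * (c2 / b2sq * b2x - b3x)
        w2b2y = a2 * (c2 / b2sq * b2y - b3y)
        w2b2z = a2 * (c2 / b2sq * b2z - b3z)
        w2b3x = a2 * (c2 / b3sq * b3x - b2x)
        w2b3y = a2 * (c2 / b3sq * b3y - b2y)
        w2b3z = a2 * (c2 / b3sq * b3z - b2z)
        p1 = sw2 * dsw1 * tors  # coefficient on grad x1
        p2 = sw1 * dsw2 * tors  # coefficient on grad x2
        # b1 = rj - ri, b2 = rk - rj, b3 = rl - rk
        f[i, 0] += p1 * w1b1x
        f[i, 1] += p1 * w1b1y
        f[i, 2] += p1 * w1b1z
        f[j, 0] -= p1 * (w1b1x - w1b2x) - p2 * w2b2x
        f[j, 1] -= p1 * (w1b1y - w1b2y) - p2 * w2b2y
        f[j, 2] -= p1 * (w1b1z - w1b2z) - p2 * w2b2z
        f[k, 0] -= p1 * w1b2x + p2 * (w2b2x - w2b3x)
        f[k, 1] -= p1 * w1b2y + p2 * (w2b2y - w2b3y)
        f[k, 2] -= p1 * w1b2z + p2 * (w2b2z - w2b3z)
        f[l, 0] -= p2 * w2b3x
        f[l, 1] -= p2 * w2b3y
        f[l, 2] -= p2 * w2b3z

    for m in range(tet_idx.shape[0]):
        i = tet_idx[m]
        dx = pos[i, 0] - tet_c[m, 0]
        dy = pos[i, 1] - tet_c[m, 1]
        dz = pos[i, 2] - tet_c[m, 2]
        e_bond += 0.5 * tet_k[m] * (dx * dx + dy * dy + dz * dz)
        f[i, 0] -= tet_k[m] * dx
        f[i, 1] -= tet_k[m] * dy
        f[i, 2] -= tet_k[m] * dz

    return e_bond, e_el


@njit(cache=True)
def _max_displacement(pos, ref):
    best = 0.0
    for i in range(pos.shape[0]):
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > best:
            best = d
    return best


@njit(cache=True)
def _integrate_chunk(pos, vel, inv_mass, noise, dt, gamma, kT, box,
                     charge, cationic, aromatic, hydro, chain_index, role,
                     bond_i, bond_j, bond_r0, bond_k,
                     el_i, el_j, el_r0, el_k,
                     ang_i, ang_j, ang_k, ang_kf, ang_t0,
                     tor_i, tor_j, tor_k, tor_l, tor_kf, tor_p0,
                     tet_idx, tet_k, tet_c,
                     p, skin, forces):
    """Run ``noise.shape[0]`` BAOAB steps in place.

    ``forces`` holds current forces on entry and updated forces on exit.
    Returns (energies[6], min_pair_distance) where energies are
    (bonded, elastic, elec, cation_pi, excluded_volume, hydrophobic) of
    the final configuration.
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    c1 = np.exp(-gamma * dt)
    rc_short = p[7] + skin
    rc_long = p[2] + skin

    ref = pos.copy()
    pi, pj, pt = _build_pairs(pos, box, chain_index, role, rc_short, rc_long)

    e0 = 0.0
    e1 = 0.0
    e2 = 0.0
    e3 = 0.0
    e4 = 0.0
    e5 = 0.0
    r_min = 1.0e30

    for s in range(nsteps):
        half = 0.5 * dt
        for i in range(n):
            vel[i, 0] += half * forces[i, 0] * inv_mass[i]
            vel[i, 1] += half * forces[i, 1] * inv_mass[i]
            vel[i, 2] += half * forces[i, 2] * inv_mass[i]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        for i in range(n):
            sd = np.sqrt(kT * (1.0 - c1 * c1) * inv_mass[i])
            vel[i, 0] = c1 * vel[i, 0] + sd * noise[s, i, 0]
            vel[i, 1] = c1 * vel[i, 1] + sd * noise[s, i, 1]
            vel[i, 2] = c1 * vel[i, 2] + sd * noise[s, i, 2]
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]

        if _max_displacement(pos, ref) > 0.5 * skin:
            pi, pj, pt = _build_pairs(pos, box, chain_index, role, rc_short, rc_long)
            ref[:, :] = pos

        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        e0, e1 = _bonded_forces(pos, box, bond_i, bond_j, bond_r0, bond_k,
                                el_i, el_j, el_r0, el_k,
                                ang_i, ang_j, ang_k, ang_kf, ang_t0,
                                tor_i, tor_j, tor_k, tor_l, tor_kf, tor_p0,
                                tet_idx, tet_k, tet_c, forces)
        e2, e3, e4, e5, r_min = _pair_forces(pos, box, charge, cationic, aromatic,
                                             hydro, pi, pj, pt, p, forces)
        for i in range(n):
            vel[i, 0] += half * forces[i, 0] * inv_mass[i]
            vel[i, 1] += half * forces[i, 1] * inv_mass[i]
            vel[i, 2] += half * forces[i, 2] * inv_mass[i]

    energies = np.empty(6)
    energies[0] = e0
    energies[1] = e1
    energies[2] = e2
    energies[3] = e3
    energies[4] = e4
    energies[5] = e5
    return energies, r_min
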