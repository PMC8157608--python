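"""Numba inner loops: pair sums, Metropolis sweeps, insertion batches, grids.

All kernels operate on flat float64 arrays produced by
``Configuration.site_arrays``.  Pair styles are encoded as integers
(0 = Lennard-Jones + optional Coulomb, 1 = hard sphere, 2 = hard cube);
``excl`` is a molecule index whose sites are skipped (intramolecular
exclusion), or -1 for a ghost probe.

The Lennard-Jones term is truncated at ``rcut`` on the site-site distance.
The Coulomb term (``coul == 1``) uses a molecule-centroid-based group
cutoff: every site pair of a molecule pair is included iff the two
molecular centroids are within ``rcut`` (minimum image), each pair
contributing ``q_i q_j (1/r - 1/rcut)``; for neutral molecules the shift
terms sum to zero, so this is the neutral-group truncation that avoids
splitting molecular charge groups at the cutoff sphere.

Energy overflow discipline: any hard overlap returns ``+inf``; the Boltzmann
factor ``exp(-beta*inf)`` is exactly 0.0 and never NaN.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

COULOMB_CONSTANT = 332.06371


@njit(cache=True)
def _site_system_energy(x, y, z, sig, eps, q, ccx, ccy, ccz,
                        pos, sigs, epss, qs, molid, mol_cent, excl,
                        box, rcut, style, coul):
    """Energy of one site (own molecular centroid at (ccx, ccy, ccz))
    against every system site outside molecule ``excl``."""
    rc2 = rcut * rcut
    e = 0.0
    for j in range(pos.shape[0]):
        mj = molid[j]
        if mj == excl:
            continue
        dx = x - pos[j, 0]
        dy = y - pos[j, 1]
        dz = z - pos[j, 2]
        dx -= box[0] * math.floor(dx / box[0] + 0.5)
        dy -= box[1] * math.floor(dy / box[1] + 0.5)
        dz -= box[2] * math.floor(dz / box[2] + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if style == 0:
            if r2 < rc2:
                eij = math.sqrt(eps * epss[j])
                if eij > 0.0:
                    if r2 <= 0.0:
                        return np.inf
                    sij = 0.5 * (sig + sigs[j])
                    s2 = sij * sij / r2
                    s6 = s2 * s2 * s2
                    e += 4.0 * eij * (s6 * s6 - s6)
            if coul == 1:
                qq = q * qs[j]
                if qq != 0.0:
                    gx = ccx - mol_cent[mj, 0]
                    gy = ccy - mol_cent[mj, 1]
                    gz = ccz - mol_cent[mj, 2]
                    gx -= box[0] * math.floor(gx / box[0] + 0.5)
                    gy -= box[1] * math.floor(gy / box[1] + 0.5)
                    gz -= box[2] * math.floor(gz / box[2] + 0.5)
                    if gx * gx + gy * gy + gz * gz < rc2:
                        if r2 <= 0.0:
                            return np.inf
                        r = math.sqrt(r2)
                        e += COULOMB_CONSTANT * qq * (1.0 / r - 1.0 / rcut)
        elif style == 1:
            sij = 0.5 * (sig + sigs[j])
            if r2 < sij * sij:
                return np.inf
        else:
            sij = 0.5 * (sig + sigs[j])
            ax = abs(dx)
            ay = abs(dy)
            az = abs(dz)
            m = ax
            if ay > m:
                m = ay
            if az > m:
                m = az
            if m < sij:
                return np.inf
    return e


@njit(cache=True)
def insertion_energy_kernel(ppos, psig, peps, pq, ccx, ccy, ccz,
                            pos, sigs, epss, qs, molid, mol_cent,
                            excl, box, rcut, style, coul):
    e = 0.0
    for p in range(ppos.shape[0]):
        e += _site_system_energy(ppos[p, 0], ppos[p, 1], ppos[p, 2],
                                 psig[p], peps[p], pq[p], ccx, ccy, ccz,
                                 pos, sigs, epss, qs, molid, mol_cent, excl,
                                 box, rcut, style, coul)
        if e == np.inf:
            return np.inf
    return e


@njit(cache=True)
def total_energy_kernel(pos, sigs, epss, qs, molid, mol_cent,
                        box, rcut, style, coul):
    e = 0.0
    for i in range(pos.shape[0]):
        mi = molid[i]
        ei = _site_system_energy(pos[i, 0], pos[i, 1], pos[i, 2],
                                 sigs[i], epss[i], qs[i],
                                 mol_cent[mi, 0], mol_cent[mi, 1],
                                 mol_cent[mi, 2],
                                 pos, sigs, epss, qs, molid, mol_cent, mi,
                                 box, rcut, style, coul)
        if ei == np.inf:
            return np.inf
        e += ei
    return 0.5 * e


@njit(cache=True)
def min_distance_kernel(ppos, pos, box):
    """Minimum minimum-image distance between probe sites and system sites."""
    best = np.inf
    for p in range(ppos.shape[0]):
        for j in range(pos.shape[0]):
            dx = ppos[p, 0] - pos[j, 0]
            dy = ppos[p, 1] - pos[j, 1]
            dz = ppos[p, 2] - pos[j, 2]
            dx -= box[0] * math.floor(dx / box[0] + 0.5)
            dy -= box[1] * math.floor(dy / box[1] + 0.5)
            dz -= box[2] * math.floor(dz / box[2] + 0.5)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < best:
                best = r2
    return math.sqrt(best)


@njit(cache=True)
def _axis_angle_matrix(ax, ay, az, angle):
    n = math.sqrt(ax * ax + ay * ay + az * az)
    if n < 1e-12:
        ax, ay, az, n = 1.0, 0.0, 0.0, 1.0
    ax /= n
    ay /= n
    az /= n
    c = math.cos(angle)
    s = math.sin(angle)
    cc = 1.0 - c
    r = np.empty((3, 3))
    r[0, 0] = c + ax * ax * cc
    r[0, 1] = ax * ay * cc - az * s
    r[0, 2] = ax * az * cc + ay * s
    r[1, 0] = ay * ax * cc + az * s
    r[1, 1] = c + ay * ay * cc
    r[1, 2] = ay * az * cc - ax * s
    r[2, 0] = az * ax * cc - ay * s
    r[2, 1] = az * ay * cc + ax * s
    r[2, 2] = c + az * az * cc
    return r


@njit(cache=True)
def mc_sweep_kernel(centroids, rotmats, pos, body, sigs, epss, qs, molid,
                    box, rcut, style, coul, beta, max_trans, max_rot,
                    rand_trans, rand_axis, rand_angle, rand_acc, do_rot):
    """One Metropolis sweep: one attempted rigid move per molecule.

    Mutates ``centroids``, ``rotmats`` and ``pos`` in place; returns
    (total energy change, accepted-move count).  Random numbers are supplied
    by the caller so determinism is owned by one named RNG stream.
    """
    n_mol = centroids.shape[0]
    ms = body.shape[0]
    trial = np.empty((ms, 3))
    rn = np.empty((3, 3))
    d_e = 0.0
    n_acc = 0
    for m in range(n_mol):
        s0 = m * ms
        e_old = 0.0
        for p in range(ms):
            e_old += _site_system_energy(
                pos[s0 + p, 0], pos[s0 + p, 1], pos[s0 + p, 2],
                sigs[s0 + p], epss[s0 + p], qs[s0 + p],
                centroids[m, 0], centroids[m, 1], centroids[m, 2],
                pos, sigs, epss, qs, molid, centroids, m,
                box, rcut, style, coul)
        cx = centroids[m, 0] + (2.0 * rand_trans[m, 0] - 1.0) * max_trans
        cy = centroids[m, 1] + (2.0 * rand_trans[m, 1] - 1.0) * max_trans
        cz = centroids[m, 2] + (2.0 * rand_trans[m, 2] - 1.0) * max_trans
        cx -= box[0] * math.floor(cx / box[0])
        cy -= box[1] * math.floor(cy / box[1])
        cz -= box[2] * math.floor(cz / box[2])
        if do_rot:
            step = _axis_angle_matrix(rand_axis[m, 0], rand_axis[m, 1],
                                      rand_axis[m, 2],
                                      (2.0 * rand_angle[m] - 1.0) * max_rot)
            for a in range(3):
                for b in range(3):
                    acc = 0.0
                    for k in range(3):
                        acc += step[a, k] * rotmats[m, k, b]
                    rn[a, b] = acc
        else:
            for a in range(3):
                for b in range(3):
                    rn[a, b] = rotmats[m, a, b]
        for p in range(ms):
            trial[p, 0] = cx + rn[0, 0] * body[p, 0] + rn[0, 1] * body[p, 1] + rn[0, 2] * body[p, 2]
            trial[p, 1] = cy + rn[1, 0] * body[p, 0] + rn[1, 1] * body[p, 1] + rn[1, 2] * body[p, 2]
            trial[p, 2] = cz + rn[2, 0] * body[p, 0] + rn[2, 1] * body[p, 1] + rn[2, 2] * body[p, 2]
        e_new = 0.0
        for p in range(ms):
            e_new += _site_system_energy(
                trial[p, 0], trial[p, 1], trial[p, 2],
                sigs[s0 + p], epss[s0 + p], qs[s0 + p],
                cx, cy, cz,
                pos, sigs, epss, qs, molid, centroids, m,
                box, rcut, style, coul)
            if e_new == np.inf:
                break
        d = e_new - e_old
        accept = False
        if d <= 0.0:
            accept = True
        elif d < np.inf and rand_acc[m] < math.exp(-beta * d):
            accept = True
        if accept:
            centroids[m, 0] = cx
            centroids[m, 1] = cy
            centroids[m, 2] = cz
            for a in range(3):
                for b in range(3):
                    rotmats[m, a, b] = rn[a, b]
            for p in range(ms):
                pos[s0 + p, 0] = trial[p, 0]
                pos[s0 + p, 1] = trial[p, 1]
                pos[s0 + p, 2] = trial[p, 2]
            d_e += d
            n_acc += 1
    return d_e, n_acc


@njit(cache=True)
def widom_batch_kernel(ins_pos, ins_rot, pbody, psig, peps, pq,
                       pos, sigs, epss, qs, molid, mol_cent,
                       box, rcut, style, coul, beta, out_b):
    """Boltzmann factor of each trial insertion pose; fills ``out_b``."""
    k_tot = ins_pos.shape[0]
    ms = pbody.shape[0]
    site = np.empty((ms, 3))
    for k in range(k_tot):
        for p in range(ms):
            site[p, 0] = (ins_pos[k, 0] + ins_rot[k, 0, 0] * pbody[p, 0]
                          + ins_rot[k, 0, 1] * pbody[p, 1] + ins_rot[k, 0, 2] * pbody[p, 2])
            site[p, 1] = (ins_pos[k, 1] + ins_rot[k, 1, 0] * pbody[p, 0]
                          + ins_rot[k, 1, 1] * pbody[p, 1] + ins_rot[k, 1, 2] * pbody[p, 2])
            site[p, 2] = (ins_pos[k, 2] + ins_rot[k, 2, 0] * pbody[p, 0]
                          + ins_rot[k, 2, 1] * pbody[p, 1] + ins_rot[k, 2, 2] * pbody[p, 2])
        e = insertion_energy_kernel(site, psig, peps, pq,
                                    ins_pos[k, 0], ins_pos[k, 1], ins_pos[k, 2],
                                    pos, sigs, epss, qs, molid, mol_cent,
                                    -1, box, rcut, style, coul)
        if e == np.inf:
            out_b[k] = 0.0
        else:
            out_b[k] = math.exp(-beta * e)
    return out_b


@njit(cache=True)
def grid_screen_kernel(n_side, cell_edge, pbody, psig, peps, pq,
                       pos, sigs, epss, qs, molid, mol_cent,
                       box, rcut, style, coul,
                       beta, d_min, b_threshold, status, b_center):
    """Two-level screening of every cell of a uniform cubic mesh.

    ``status``: 0 = failed first level (overlap), 1 = failed second level,
    2 = accepted.  ``b_center`` holds the Boltzmann factor at the cell centre
    for every cell that reached level two (0 otherwise).
    First level: minimum probe-to-system distance strictly greater than
    ``d_min``.  Second level: centre Boltzmann factor strictly greater than
    ``b_threshold``; a disabled threshold (<= 0) rejects only true hard
    overlaps (infinite centre energy), so exp() underflow at huge finite
    energies cannot silently drop a cell.
    """
    ms = pbody.shape[0]
    site = np.empty((ms, 3))
    d2 = d_min * d_min
    idx = 0
    for i in range(n_side):
        for j in range(n_side):
            for k in range(n_side):
                cx = (i + 0.5) * cell_edge
                cy = (j + 0.5) * cell_edge
                cz = (k + 0.5) * cell_edge
                for p in range(ms):
                    site[p, 0] = cx + pbody[p, 0]
                    site[p, 1] = cy + pbody[p, 1]
                    site[p, 2] = cz + pbody[p, 2]
                ok = True
                for p in range(ms):
                    if not ok:
                        break
                    for s in range(pos.shape[0]):
                        dx = site[p, 0] - pos[s, 0]
                        dy = site[p, 1] - pos[s, 1]
                        dz = site[p, 2] - pos[s, 2]
                        dx -= box[0] * math.floor(dx / box[0] + 0.5)
                        dy -= box[1] * math.floor(dy / box[1] + 0.5)
                        dz -= box[2] * math.floor(dz / box[2] + 0.5)
                        if dx * dx + dy * dy + dz * dz <= d2:
                            ok = False
                            break
                if not ok:
                    status[idx] = 0
                    b_center[idx] = 0.0
                else:
                    e = insertion_energy_kernel(site, psig, peps, pq,
                                                cx, cy, cz,
                                                pos, sigs, epss, qs, molid,
                                                mol_cent, -1,
                                                box, rcut, style, coul)
                    b = 0.0 if e == np.inf else math.exp(-beta * e)
                    b_center[idx] = b
                    if b_threshold <= 0.0:
                        status[idx] = 2 if e < np.inf else 1
                    else:
                        status[idx] = 2 if b > b_threshold else 1
                idx += 1
    return idx


@njit(cache=True)
def detailed_average_kernel(centers, b_centers, cell_edge, upper_bracket,
                            frac_lo, frac_hi, dirs, rots, include_center,
                            pbody, psig, peps, pq, pos, sigs, epss, qs,
                            molid, mol_cent,
                            box, rcut, style, coul, beta, out_mean):
    """Mean Boltzmann factor over the translation x rotation pose stencil.

    Translation step is ``frac_lo * D`` when the centre Boltzmann factor is
    below ``upper_bracket`` and ``frac_hi * D`` at or above it.
    """
    n_cells = centers.shape[0]
    n_dir = dirs.shape[0]
    n_rot = rots.shape[0]
    ms = pbody.shape[0]
    site = np.empty((ms, 3))
    for a in range(n_cells):
        step = cell_edge * (frac_hi if b_centers[a] >= upper_bracket else frac_lo)
        tot = 0.0
        cnt = 0
        if include_center:
            tot += b_centers[a]
            cnt += 1
        for t in range(n_dir):
            tx = centers[a, 0] + step * dirs[t, 0]
            ty = centers[a, 1] + step * dirs[t, 1]
            tz = centers[a, 2] + step * dirs[t, 2]
            for r in range(n_rot):
                for p in range(ms):
                    site[p, 0] = (tx + rots[r, 0, 0] * pbody[p, 0]
                                  + rots[r, 0, 1] * pbody[p, 1] + rots[r, 0, 2] * pbody[p, 2])
                    site[p, 1] = (ty + rots[r, 1, 0] * pbody[p, 0]
                                  + rots[r, 1, 1] * pbody[p, 1] + rots[r, 1, 2] * pbody[p, 2])
                    site[p, 2] = (tz + rots[r, 2, 0] * pbody[p, 0]
                                  + rots[r, 2, 1] * pbody[p, 1] + rots[r, 2, 2] * pbody[p, 2])
                e = insertion_energy_kernel(site, psig, peps, pq,
                                            tx, ty, tz,
                                            pos, sigs, epss, qs, molid,
                                            mol_cent, -1,
                                            box, rcut, style, coul)
                tot += 0.0 if e == np.inf else math.exp(-beta * e)
                cnt += 1
        out_mean[a] = tot / cnt
    return out_mean
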