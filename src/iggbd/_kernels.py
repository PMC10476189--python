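"""Numba kernels for force evaluation, RPY mobility and BD propagation.

These are implementation details; the public API lives in
:mod:`iggbd.potentials`, :mod:`iggbd.hydrodynamics` and :mod:`iggbd.engine`.
All kernels work on flat float64 arrays in the package unit system
(nm, us, kcal/mol).

Conventions baked in here:

* positions are kept *unwrapped*; periodic images enter only through
  minimum-image distances in the steric pair terms (bonded terms always use
  the raw intra-molecule geometry),
* the mobility matrix is a *diffusion* matrix D (nm^2/us); the
  Ermak-McCammon displacement is ``(D @ F) dt / kBT + sqrt(2 dt) L z`` with
  ``L L^T = D``,
* mobility coupling is restricted to user-defined bead groups (one group per
  molecule for intra-molecule RPY, one bead per group for free draining, one
  global group for all-pairs RPY).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the propagators
STATUS_OK = 0
STATUS_REACTED = 1
STATUS_ESCAPED = 2
STATUS_UNSTABLE = 3


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def compute_forces(pos, box, periodic,
                   bond_i, bond_j, bond_req, bond_kap,
                   ang_i, ang_j, ang_k, ang_teq, ang_xi,
                   act_i, act_j, act_sig, n_act,
                   k_ov, wall_on, wall_ztop, a_core,
                   rest_bead, rest_pt, rest_req, rest_kap,
                   bond_pref, F, E):
    """Fill per-bead forces F (N,3) and energies E (4,) = bond/angle/steric/wall."""
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    for c in range(4):
        E[c] = 0.0

    # bonds (unwrapped geometry)
    for b in range(bond_i.shape[0]):
        i = bond_i[b]
        j = bond_j[b]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - bond_req[b]
        E[0] += bond_pref * bond_kap[b] * dr * dr
        # dU/dr = 2*pref*kappa*dr
        coef = -2.0 * bond_pref * bond_kap[b] * dr / r
        F[i, 0] += coef * dx
        F[i, 1] += coef * dy
        F[i, 2] += coef * dz
        F[j, 0] -= coef * dx
        F[j, 1] -= coef * dy
        F[j, 2] -= coef * dz

    # angles (apex j)
    for a in range(ang_i.shape[0]):
        i = ang_i[a]
        j = ang_j[a]
        k = ang_k[a]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nv = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux /= nu
        uy /= nu
        uz /= nu
        vx /= nv
        vy /= nv
        vz /= nv
        c = ux * vx + uy * vy + uz * vz
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s = np.sqrt(1.0 - c * c)
        if s < 1.0e-8:
            s = 1.0e-8
        dth = theta - ang_teq[a]
        E[1] += bond_pref * ang_xi[a] * dth * dth
        dudth = 2.0 * bond_pref * ang_xi[a] * dth
        # dtheta/dr_i = (c*u_hat - v_hat)/(|u| s);  analogous for k
        ci = -dudth / (nu * s)
        ck = -dudth / (nv * s)
        fix = ci * (c * ux - vx)
        fiy = ci * (c * uy - vy)
        fiz = ci * (c * uz - vz)
        fkx = ck * (c * vx - ux)
        fky = ck * (c * vy - uy)
        fkz = ck * (c * vz - uz)
        F[i, 0] += fix
        F[i, 1] += fiy
        F[i, 2] += fiz
        F[k, 0] += fkx
        F[k, 1] += fky
        F[k, 2] += fkz
        F[j, 0] -= fix + fkx
        F[j, 1] -= fiy + fky
        F[j, 2] -= fiz + fkz

    # steric repulsion over the active inter-molecular pair list
    for p in range(n_act):
        i = act_i[p]
        j = act_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic[0]:
            dx -= box[0] * np.round(dx / box[0])
        if periodic[1]:
            dy -= box[1] * np.round(dy / box[1])
        if periodic[2]:
            dz -= box[2] * np.round(dz / box[2])
        sig = act_sig[p]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < sig * sig:
            d = np.sqrt(d2)
            ov = sig - d
            E[2] += 0.5 * k_ov * ov * ov
            coef = k_ov * ov / d
            F[i, 0] += coef * dx
            F[i, 1] += coef * dy
            F[i, 2] += coef * dz
            F[j, 0] -= coef * dx
            F[j, 1] -= coef * dy
            F[j, 2] -= coef * dz

    # walls at z=0 and optionally z=wall_ztop
    if wall_on == 1:
        for i in range(n):
            zlo = pos[i, 2] - a_core[i]
            if zlo < 0.0:
                E[3] += 0.5 * k_ov * zlo * zlo
                F[i, 2] += -k_ov * zlo
            if wall_ztop > 0.0:
                zhi = (wall_ztop - pos[i, 2]) - a_core[i]
                if zhi < 0.0:
                    E[3] += 0.5 * k_ov * zhi * zhi
                    F[i, 2] -= -k_ov * zhi

    # point restraints (tethers)
    for t in range(rest_bead.shape[0]):
        i = rest_bead[t]
        dx = pos[i, 0] - rest_pt[t, 0]
        dy = pos[i, 1] - rest_pt[t, 1]
        dz = pos[i, 2] - rest_pt[t, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1.0e-12:
            continue
        dr = r - rest_req[t]
        E[0] += bond_pref * rest_kap[t] * dr * dr
        coef = -2.0 * bond_pref * rest_kap[t] * dr / r
        F[i, 0] += coef * dx
        F[i, 1] += coef * dy
        F[i, 2] += coef * dz
    return 0


@njit(cache=True, fastmath=True)
def rebuild_neighbour_list(pos, box, periodic, cand_i, cand_j, cand_sig,
                           skin, act_i, act_j, act_sig):
    """Select candidate pairs within sigma+skin (minimum image). Returns count."""
    n_act = 0
    for p in range(cand_i.shape[0]):
        i = cand_i[p]
        j = cand_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        if periodic[0]:
            dx -= box[0] * np.round(dx / box[0])
        if periodic[1]:
            dy -= box[1] * np.round(dy / box[1])
        if periodic[2]:
            dz -= box[2] * np.round(dz / box[2])
        cut = cand_sig[p] + skin
        if dx * dx + dy * dy + dz * dz < cut * cut:
            act_i[n_act] = i
            act_j[n_act] = j
            act_sig[n_act] = cand_sig[p]
            n_act += 1
    return n_act


# ---------------------------------------------------------------------------
# RPY mobility
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rpy_pair_coeffs(r, ai, aj, kt6pe):
    """Scalar coefficients (c_iso, c_rr) of D = c_iso*I + c_rr*rhat rhat."""
    if r >= ai + aj:
        pref = kt6pe * 6.0 / (8.0 * r)
        a2 = ai * ai + aj * aj
        c_iso = pref * (1.0 + a2 / (3.0 * r * r))
        c_rr = pref * (1.0 - a2 / (r * r))
    elif r > abs(ai - aj):
        pref = kt6pe / (ai * aj)
        dij = ai - aj
        num = 16.0 * r * r * r * (ai + aj) - (dij * dij + 3.0 * r * r) ** 2
        c_iso = pref * num / (32.0 * r * r * r)
        c_rr = pref * 3.0 * (dij * dij - r * r) ** 2 / (32.0 * r * r * r)
    else:
        amax = ai if ai > aj else aj
        c_iso = kt6pe / amax
        c_rr = 0.0
    return c_iso, c_rr


@njit(cache=True, fastmath=True)
def build_mobility(pos, a_h, grp_start, box, periodic, use_min_image,
                   kt6pe, M):
    """Fill the (3N, 3N) diffusion matrix, coupling beads inside each group.

    kt6pe = k_B T / (6 pi eta).  Only group-block entries are written;
    callers must supply a zero-initialised M (the block pattern is static,
    so zeroing once is enough).
    """
    n_grp = grp_start.shape[0] - 1
    for g in range(n_grp):
        s = grp_start[g]
        e = grp_start[g + 1]
        for i in range(s, e):
            d_self = kt6pe / a_h[i]
            for c in range(3):
                M[3 * i + c, 3 * i + c] = d_self
            for j in range(i + 1, e):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                if use_min_image:
                    if periodic[0]:
                        dx -= box[0] * np.round(dx / box[0])
                    if periodic[1]:
                        dy -= box[1] * np.round(dy / box[1])
                    if periodic[2]:
                        dz -= box[2] * np.round(dz / box[2])
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r < 1.0e-12:
                    c_iso = kt6pe / (a_h[i] if a_h[i] > a_h[j] else a_h[j])
                    for c in range(3):
                        M[3 * i + c, 3 * j + c] = c_iso
                        M[3 * j + c, 3 * i + c] = c_iso
                    continue
                c_iso, c_rr = _rpy_pair_coeffs(r, a_h[i], a_h[j], kt6pe)
                ex = dx / r
                ey = dy / r
                ez = dz / r
                xx = c_iso + c_rr * ex * ex
                yy = c_iso + c_rr * ey * ey
                zz = c_iso + c_rr * ez * ez
                xy = c_rr * ex * ey
                xz = c_rr * ex * ez
                yz = c_rr * ey * ez
                M[3 * i, 3 * j] = xx
                M[3 * i, 3 * j + 1] = xy
                M[3 * i, 3 * j + 2] = xz
                M[3 * i + 1, 3 * j] = xy
                M[3 * i + 1, 3 * j + 1] = yy
                M[3 * i + 1, 3 * j + 2] = yz
                M[3 * i + 2, 3 * j] = xz
                M[3 * i + 2, 3 * j + 1] = yz
                M[3 * i + 2, 3 * j + 2] = zz
                for c1 in range(3):
                    for c2 in range(3):
                        M[3 * j + c1, 3 * i + c2] = M[3 * i + c2, 3 * j + c1]
    return 0


@njit(cache=True, fastmath=True)
def cholesky_groups(M, grp_start, L):
    """Per-group Cholesky factors of the block-diagonal diffusion matrix.

    Hand-rolled (blocks are tiny; a LAPACK round-trip per step would
    dominate the runtime).  Only the lower triangle of each block of L is
    written.  Returns -1 if a block is not positive definite.
    """
    n_grp = grp_start.shape[0] - 1
    for g in range(n_grp):
        s3 = 3 * grp_start[g]
        e3 = 3 * grp_start[g + 1]
        for i in range(s3, e3):
            for j in range(s3, i + 1):
                L[i, j] = M[i, j]
        for j in range(s3, e3):
            s = L[j, j]
            for k in range(s3, j):
                s -= L[j, k] * L[j, k]
            if s <= 0.0:
                return -1
            d = np.sqrt(s)
            L[j, j] = d
            for i in range(j + 1, e3):
                s2 = L[i, j]
                for k in range(s3, j):
                    s2 -= L[i, k] * L[j, k]
                L[i, j] = s2 / d
    return 0


@njit(cache=True, inline="always")
def _group_matvec(A, grp_start, x, out):
    """out = A @ x exploiting the group-block structure (A lower/symmetric)."""
    n_grp = grp_start.shape[0] - 1
    for g in range(n_grp):
        s3 = 3 * grp_start[g]
        e3 = 3 * grp_start[g + 1]
        for i in range(s3, e3):
            acc = 0.0
            for j in range(s3, e3):
                acc += A[i, j] * x[j]
            out[i] = acc
    return 0


# ---------------------------------------------------------------------------
# propagators
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def run_bd(pos, n_steps, dt, kbt,
           box, periodic,
           bond_i, bond_j, bond_req, bond_kap,
           ang_i, ang_j, ang_k, ang_teq, ang_xi,
           cand_i, cand_j, cand_sig, skin,
           k_ov, wall_on, wall_ztop, a_core,
           rest_bead, rest_pt, rest_req, rest_kap,
           bond_pref,
           a_h, grp_start, use_min_image, kt6pe, mob_stride,
           frozen, stab_limit,
           sample_every, samples, energies_out,
           seed):
    """Ermak-McCammon propagation with on-the-fly sampling.

    ``samples`` has shape (n_samples, N, 3) with n_samples =
    n_steps//sample_every + 1; frame 0 is the initial configuration.
    Returns (status, step_reached).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n3 = 3 * n
    M = np.zeros((n3, n3))
    L = np.zeros((n3, n3))
    F = np.zeros((n, 3))
    E = np.zeros(4)
    fvec = np.empty(n3)
    drift = np.empty(n3)
    noise = np.empty(n3)

    n_cand = cand_i.shape[0]
    act_i = np.empty(n_cand, dtype=np.int64)
    act_j = np.empty(n_cand, dtype=np.int64)
    act_sig = np.empty(n_cand)
    n_act = rebuild_neighbour_list(pos, box, periodic, cand_i, cand_j,
                                   cand_sig, skin, act_i, act_j, act_sig)
    acc_disp = 0.0

    samples[0] = pos
    sample_idx = 1
    sqrt2dt = np.sqrt(2.0 * dt)

    for step in range(n_steps):
        if step % mob_stride == 0:
            build_mobility(pos, a_h, grp_start, box, periodic,
                           use_min_image, kt6pe, M)
            if cholesky_groups(M, grp_start, L) != 0:
                return STATUS_UNSTABLE, step
        compute_forces(pos, box, periodic,
                       bond_i, bond_j, bond_req, bond_kap,
                       ang_i, ang_j, ang_k, ang_teq, ang_xi,
                       act_i, act_j, act_sig, n_act,
                       k_ov, wall_on, wall_ztop, a_core,
                       rest_bead, rest_pt, rest_req, rest_kap,
                       bond_pref, F, E)
        for i in range(n):
            fvec[3 * i] = F[i, 0]
            fvec[3 * i + 1] = F[i, 1]
            fvec[3 * i + 2] = F[i, 2]
        _group_matvec(M, grp_start, fvec, drift)
        z = np.random.standard_normal(n3)
        # noise = L @ z within groups (L lower triangular)
        n_grp = grp_start.shape[0] - 1
        for g in range(n_grp):
            s3 = 3 * grp_start[g]
            e3 = 3 * grp_start[g + 1]
            for i in range(s3, e3):
                acc = 0.0
                for j in range(s3, i + 1):
                    acc += L[i, j] * z[j]
                noise[i] = acc
        max_disp = 0.0
        for i in range(n):
            if frozen[i] == 1:
                continue
            ddx = drift[3 * i] * dt / kbt + sqrt2dt * noise[3 * i]
            ddy = drift[3 * i + 1] * dt / kbt + sqrt2dt * noise[3 * i + 1]
            ddz = drift[3 * i + 2] * dt / kbt + sqrt2dt * noise[3 * i + 2]
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if d > max_disp:
                max_disp = d
        if max_disp > stab_limit:
            return STATUS_UNSTABLE, step
        acc_disp += max_disp
        if acc_disp > 0.45 * skin and n_cand > 0:
            n_act = rebuild_neighbour_list(pos, box, periodic, cand_i, cand_j,
                                           cand_sig, skin, act_i, act_j,
                                           act_sig)
            acc_disp = 0.0
        if (step + 1) % sample_every == 0 and sample_idx < samples.shape[0]:
            samples[sample_idx] = pos
            for c in range(4):
                energies_out[sample_idx, c] = E[c]
            sample_idx += 1
    return STATUS_OK, n_steps


@njit(cache=True, fastmath=True)
def run_nam(pos, n_steps, dt, kbt,
            box, periodic,
            bond_i, bond_j, bond_req, bond_kap,
            ang_i, ang_j, ang_k, ang_teq, ang_xi,
            cand_i, cand_j, cand_sig, skin,
            k_ov, wall_on, wall_ztop, a_core,
            rest_bead, rest_pt, rest_req, rest_kap,
            bond_pref,
            a_h, grp_start, use_min_image, kt6pe, mob_stride,
            frozen, stab_limit,
            center_beads, tip_beads, target_pos, react_dist,
            esc_center_pos, esc_dist,
            record_bead, record_origin, record_every, record_zr,
            seed):
    """Propagate until a binding/escape criterion fires.

    * reaction: any bead in ``tip_beads`` within ``react_dist`` of
      ``target_pos`` (minimum image in periodic directions),
    * escape (only if ``esc_dist > 0``): geometric centre of
      ``center_beads`` farther than ``esc_dist`` from ``esc_center_pos``.

    If ``record_every > 0``, the (z, rho) position of ``record_bead``
    relative to ``record_origin`` is appended to ``record_zr`` every
    ``record_every`` steps (rho measured in the xy plane, minimum image).
    Returns (status, step_reached, n_recorded).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n3 = 3 * n
    M = np.zeros((n3, n3))
    L = np.zeros((n3, n3))
    F = np.zeros((n, 3))
    E = np.zeros(4)
    fvec = np.empty(n3)
    drift = np.empty(n3)
    noise = np.empty(n3)

    n_cand = cand_i.shape[0]
    act_i = np.empty(n_cand, dtype=np.int64)
    act_j = np.empty(n_cand, dtype=np.int64)
    act_sig = np.empty(n_cand)
    n_act = rebuild_neighbour_list(pos, box, periodic, cand_i, cand_j,
                                   cand_sig, skin, act_i, act_j, act_sig)
    acc_disp = 0.0
    n_rec = 0
    sqrt2dt = np.sqrt(2.0 * dt)

    for step in range(n_steps):
        if step % mob_stride == 0:
            build_mobility(pos, a_h, grp_start, box, periodic,
                           use_min_image, kt6pe, M)
            if cholesky_groups(M, grp_start, L) != 0:
                return STATUS_UNSTABLE, step, n_rec
        compute_forces(pos, box, periodic,
                       bond_i, bond_j, bond_req, bond_kap,
                       ang_i, ang_j, ang_k, ang_teq, ang_xi,
                       act_i, act_j, act_sig, n_act,
                       k_ov, wall_on, wall_ztop, a_core,
                       rest_bead, rest_pt, rest_req, rest_kap,
                       bond_pref, F, E)
        for i in range(n):
            fvec[3 * i] = F[i, 0]
            fvec[3 * i + 1] = F[i, 1]
            fvec[3 * i + 2] = F[i, 2]
        _group_matvec(M, grp_start, fvec, drift)
        z = np.random.standard_normal(n3)
        n_grp = grp_start.shape[0] - 1
        for g in range(n_grp):
            s3 = 3 * grp_start[g]
            e3 = 3 * grp_start[g + 1]
            for i in range(s3, e3):
                acc = 0.0
                for j in range(s3, i + 1):
                    acc += L[i, j] * z[j]
                noise[i] = acc
        max_disp = 0.0
        for i in range(n):
            if frozen[i] == 1:
                continue
            ddx = drift[3 * i] * dt / kbt + sqrt2dt * noise[3 * i]
            ddy = drift[3 * i + 1] * dt / kbt + sqrt2dt * noise[3 * i + 1]
            ddz = drift[3 * i + 2] * dt / kbt + sqrt2dt * noise[3 * i + 2]
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            d = np.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            if d > max_disp:
                max_disp = d
        if max_disp > stab_limit:
            return STATUS_UNSTABLE, step, n_rec
        acc_disp += max_disp
        if acc_disp > 0.45 * skin and n_cand > 0:
            n_act = rebuild_neighbour_list(pos, box, periodic, cand_i, cand_j,
                                           cand_sig, skin, act_i, act_j,
                                           act_sig)
            acc_disp = 0.0

        # reaction criterion
        for t in range(tip_beads.shape[0]):
            i = tip_beads[t]
            dx = pos[i, 0] - target_pos[0]
            dy = pos[i, 1] - target_pos[1]
            dz = pos[i, 2] - target_pos[2]
            if periodic[0]:
                dx -= box[0] * np.round(dx / box[0])
            if periodic[1]:
                dy -= box[1] * np.round(dy / box[1])
            if periodic[2]:
                dz -= box[2] * np.round(dz / box[2])
            if dx * dx + dy * dy + dz * dz < react_dist * react_dist:
                return STATUS_REACTED, step + 1, n_rec
        # escape criterion
        if esc_dist > 0.0:
            cx = 0.0
            cy = 0.0
            cz = 0.0
            nc = center_beads.shape[0]
            for t in range(nc):
                cx += pos[center_beads[t], 0]
                cy += pos[center_beads[t], 1]
                cz += pos[center_beads[t], 2]
            cx = cx / nc - esc_center_pos[0]
            cy = cy / nc - esc_center_pos[1]
            cz = cz / nc - esc_center_pos[2]
            if periodic[0]:
                cx -= box[0] * np.round(cx / box[0])
            if periodic[1]:
                cy -= box[1] * np.round(cy / box[1])
            if periodic[2]:
                cz -= box[2] * np.round(cz / box[2])
            if cx * cx + cy * cy + cz * cz > esc_dist * esc_dist:
                return STATUS_ESCAPED, step + 1, n_rec
        if record_every > 0 and (step + 1) % record_every == 0 \
                and n_rec < record_zr.shape[0]:
            i = record_bead
            dx = pos[i, 0] - record_origin[0]
            dy = pos[i, 1] - record_origin[1]
            if periodic[0]:
                dx -= box[0] * np.round(dx / box[0])
            if periodic[1]:
                dy -= box[1] * np.round(dy / box[1])
            record_zr[n_rec, 0] = pos[i, 2]
            record_zr[n_rec, 1] = np.sqrt(dx * dx + dy * dy)
            n_rec += 1
    return STATUS_OK, n_steps, n_rec
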