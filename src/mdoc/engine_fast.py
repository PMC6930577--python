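"""Jit-compiled inner loop for restrained dynamics.

This module contains a numba translation of the per-step work of
:func:`mdoc.engine.run_mdoc` (force field, pseudo-forces, memory updates,
velocity-Verlet + weak coupling).  The physics is defined by the plain
numpy implementations in :mod:`mdoc.system`, :mod:`mdoc.rdc` and
:mod:`mdoc.scalar`; an equivalence test holds the two paths together.
Summation order differs between the paths, so trajectories agree only to
floating-point accumulation accuracy over short stretches.
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is expected to be present
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return deco

from .constants import ACC_UNIT, KB

_NOPT = dict(cache=True)


@njit(**_NOPT)
def _ff_forces(x, f,
               bond_i, bond_j, bond_r0, bond_k,
               ang_i, ang_j, ang_k, ang_t0, ang_ka,
               tor_a, tor_b, tor_c, tor_d, tor_n, tor_g, tor_v,
               nb_i, nb_j, nb_sig, nb_eps, nb_qq, cutoff):
    n = x.shape[0]
    for a in range(n):
        for d in range(3):
            f[a, d] = 0.0
    energy = 0.0
    # bonds
    for b in range(bond_i.shape[0]):
        i, j = bond_i[b], bond_j[b]
        vx = x[i, 0] - x[j, 0]
        vy = x[i, 1] - x[j, 1]
        vz = x[i, 2] - x[j, 2]
        r = np.sqrt(vx * vx + vy * vy + vz * vz)
        dr = r - bond_r0[b]
        energy += 0.5 * bond_k[b] * dr * dr
        c = bond_k[b] * dr / r
        f[i, 0] -= c * vx
        f[i, 1] -= c * vy
        f[i, 2] -= c * vz
        f[j, 0] += c * vx
        f[j, 1] += c * vy
        f[j, 2] += c * vz
    # angles
    for b in range(ang_i.shape[0]):
        i, j, k = ang_i[b], ang_j[b], ang_k[b]
        r1x = x[i, 0] - x[j, 0]
        r1y = x[i, 1] - x[j, 1]
        r1z = x[i, 2] - x[j, 2]
        r2x = x[k, 0] - x[j, 0]
        r2y = x[k, 1] - x[j, 1]
        r2z = x[k, 2] - x[j, 2]
        n1 = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
        n2 = np.sqrt(r2x * r2x + r2y * r2y + r2z * r2z)
        u1x, u1y, u1z = r1x / n1, r1y / n1, r1z / n1
        u2x, u2y, u2z = r2x / n2, r2y / n2, r2z / n2
        c = u1x * u2x + u1y * u2y + u1z * u2z
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        theta = np.arccos(c)
        s2 = 1.0 - c * c
        if s2 < 1e-14:
            s2 = 1e-14
        s = np.sqrt(s2)
        dth = theta - ang_t0[b]
        energy += 0.5 * ang_ka[b] * dth * dth
        pref = ang_ka[b] * dth
        gix = -(u2x - c * u1x) / (n1 * s)
        giy = -(u2y - c * u1y) / (n1 * s)
        giz = -(u2z - c * u1z) / (n1 * s)
        gkx = -(u1x - c * u2x) / (n2 * s)
        gky = -(u1y - c * u2y) / (n2 * s)
        gkz = -(u1z - c * u2z) / (n2 * s)
        f[i, 0] -= pref * gix
        f[i, 1] -= pref * giy
        f[i, 2] -= pref * giz
        f[k, 0] -= pref * gkx
        f[k, 1] -= pref * gky
        f[k, 2] -= pref * gkz
        f[j, 0] += pref * (gix + gkx)
        f[j, 1] += pref * (giy + gky)
        f[j, 2] += pref * (giz + gkz)
    # torsions
    for b in range(tor_a.shape[0]):
        phi, g = _dihedral_grad(x, tor_a[b], tor_b[b], tor_c[b], tor_d[b])
        arg = tor_n[b] * phi - tor_g[b]
        energy += 0.5 * tor_v[b] * (1.0 + np.cos(arg))
        dEdphi = -0.5 * tor_v[b] * tor_n[b] * np.sin(arg)
        idx4 = (tor_a[b], tor_b[b], tor_c[b], tor_d[b])
        for q in range(4):
            a = idx4[q]
            f[a, 0] -= dEdphi * g[q, 0]
            f[a, 1] -= dEdphi * g[q, 1]
            f[a, 2] -= dEdphi * g[q, 2]
    # nonbonded
    for b in range(nb_i.shape[0]):
        i, j = nb_i[b], nb_j[b]
        vx = x[i, 0] - x[j, 0]
        vy = x[i, 1] - x[j, 1]
        vz = x[i, 2] - x[j, 2]
        r2 = vx * vx + vy * vy + vz * vz
        r = np.sqrt(r2)
        if r < 0.1:
            return np.nan  # signals singularity to the caller
        if r >= cutoff:
            continue
        sr6 = (nb_sig[b] / r) ** 6
        e_lj = 4.0 * nb_eps[b] * (sr6 * sr6 - sr6)
        e_c = nb_qq[b] / r
        energy += e_lj + e_c
        dEdr = -(24.0 * nb_eps[b] * (2.0 * sr6 * sr6 - sr6) + e_c) / r
        c = dEdr / r
        f[i, 0] -= c * vx
        f[i, 1] -= c * vy
        f[i, 2] -= c * vz
        f[j, 0] += c * vx
        f[j, 1] += c * vy
        f[j, 2] += c * vz
    return energy


@njit(**_NOPT)
def _dihedral_grad(x, ia, ib, ic, id_):
    b1 = x[ib] - x[ia]
    b2 = x[ic] - x[ib]
    b3 = x[id_] - x[ic]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
    n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
    n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
    xx = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
    cr = np.cross(n1, n2)
    yy = (cr[0] * b2[0] + cr[1] * b2[1] + cr[2] * b2[2]) / nb2
    phi = np.arctan2(yy, xx)
    g = np.zeros((4, 3))
    g1 = -(nb2 / n1sq) * n1
    g4 = (nb2 / n2sq) * n2
    c1 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (nb2 * nb2)
    c3 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (nb2 * nb2)
    for d in range(3):
        g[0, d] = g1[d]
        g[3, d] = g4[d]
        g[1, d] = -(1.0 + c1) * g1[d] + c3 * g4[d]
        g[2, d] = c1 * g1[d] - (1.0 + c3) * g4[d]
    return phi, g


@njit(**_NOPT)
def _observe_rdc(x, rdc_bi, rdc_bj, rdc_group, rdc_wt, rdc_d, n_groups, out):
    for g in range(n_groups):
        for a in range(3):
            for b in range(3):
                out[g, a, b] = 0.0
    for p in range(rdc_bi.shape[0]):
        i, j = rdc_bi[p], rdc_bj[p]
        g = rdc_group[p]
        vx = x[i, 0] - x[j, 0]
        vy = x[i, 1] - x[j, 1]
        vz = x[i, 2] - x[j, 2]
        r = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux, uy, uz = vx / r, vy / r, vz / r
        d = rdc_d[g] * rdc_wt[p]
        out[g, 0, 0] += d * (1.5 * ux * ux - 0.5)
        out[g, 1, 1] += d * (1.5 * uy * uy - 0.5)
        out[g, 2, 2] += d * (1.5 * uz * uz - 0.5)
        out[g, 0, 1] += d * 1.5 * ux * uy
        out[g, 1, 0] += d * 1.5 * ux * uy
        out[g, 0, 2] += d * 1.5 * ux * uz
        out[g, 2, 0] += d * 1.5 * ux * uz
        out[g, 1, 2] += d * 1.5 * uy * uz
        out[g, 2, 1] += d * 1.5 * uy * uz


@njit(**_NOPT)
def _pseudo_forces(x, f, ramp,
                   rdc_bi, rdc_bj, rdc_group, rdc_wt, rdc_d, rdc_width, rdc_exp,
                   rdc_S, rdc_N, k_rdc,
                   noe_i, noe_h, noe_npart, noe_target, noe_width, noe_S, noe_N, k_noe,
                   j_atoms, j_exp, j_width, j_dchi, j_xi, j_nsub, j_params, j_S, j_N, k_j):
    # RDC: tanh mismatch per tensor component on the memory mean,
    # orientational derivative on the instantaneous unit vector
    n_groups = rdc_d.shape[0]
    fmat = np.empty((n_groups, 3, 3))
    for g in range(n_groups):
        if rdc_N[g] <= 0.0:
            continue
        for a in range(3):
            for b in range(3):
                fmat[g, a, b] = np.tanh(
                    (rdc_S[g, a, b] / rdc_N[g] - rdc_exp[g, a, b]) / rdc_width[g]
                )
    for p in range(rdc_bi.shape[0]):
        g = rdc_group[p]
        if rdc_N[g] <= 0.0:
            continue
        i, j = rdc_bi[p], rdc_bj[p]
        vx = x[i, 0] - x[j, 0]
        vy = x[i, 1] - x[j, 1]
        vz = x[i, 2] - x[j, 2]
        r = np.sqrt(vx * vx + vy * vy + vz * vz)
        ux, uy, uz = vx / r, vy / r, vz / r
        d3 = 3.0 * rdc_d[g]
        gx = d3 * (fmat[g, 0, 0] * ux + fmat[g, 0, 1] * uy + fmat[g, 0, 2] * uz)
        gy = d3 * (fmat[g, 1, 0] * ux + fmat[g, 1, 1] * uy + fmat[g, 1, 2] * uz)
        gz = d3 * (fmat[g, 2, 0] * ux + fmat[g, 2, 1] * uy + fmat[g, 2, 2] * uz)
        dot = gx * ux + gy * uy + gz * uz
        px = (gx - dot * ux) / r
        py = (gy - dot * uy) / r
        pz = (gz - dot * uz) / r
        pref = -ramp * k_rdc * rdc_width[g] * rdc_wt[p]
        f[i, 0] += pref * px
        f[i, 1] += pref * py
        f[i, 2] += pref * pz
        f[j, 0] -= pref * px
        f[j, 1] -= pref * py
        f[j, 2] -= pref * pz
    # NOE central forces
    for m in range(noe_i.shape[0]):
        if noe_N[m] <= 0.0:
            continue
        r_bar = (noe_S[m] / noe_N[m]) ** (-1.0 / 6.0)
        mag = ramp * k_noe * noe_width[m] * np.tanh((r_bar - noe_target[m]) / noe_width[m])
        colw = noe_npart[m] / 3.0
        i = noe_i[m]
        for col in range(3):
            h = noe_h[m, col]
            vx = x[i, 0] - x[h, 0]
            vy = x[i, 1] - x[h, 1]
            vz = x[i, 2] - x[h, 2]
            r = np.sqrt(vx * vx + vy * vy + vz * vz)
            c = -mag * colw / r
            f[i, 0] += c * vx
            f[i, 1] += c * vy
            f[i, 2] += c * vz
            f[h, 0] -= c * vx
            f[h, 1] -= c * vy
            f[h, 2] -= c * vz
    # 3J chain-rule forces
    for q in range(j_atoms.shape[0]):
        if j_N[q] <= 0.0:
            continue
        phi, g = _dihedral_grad(x, j_atoms[q, 0], j_atoms[q, 1], j_atoms[q, 2], j_atoms[q, 3])
        j_mean = j_S[q] / j_N[q]
        c_, s_ = np.cos(phi), np.sin(phi)
        dj = -2.0 * j_params[q, 0] * c_ * s_ - j_params[q, 1] * s_
        for t in range(j_nsub[q]):
            arg = j_xi[q, t] * phi + j_params[q, 5] * abs(j_dchi[q, t])
            dj -= j_dchi[q, t] * j_params[q, 4] * 2.0 * np.cos(arg) * np.sin(arg) * j_xi[q, t]
        pref = -ramp * k_j * j_width[q] * np.tanh((j_mean - j_exp[q]) / j_width[q]) * dj
        for t in range(4):
            a = j_atoms[q, t]
            f[a, 0] += pref * g[t, 0]
            f[a, 1] += pref * g[t, 1]
            f[a, 2] += pref * g[t, 2]


@njit(**_NOPT)
def _observe_scalars(x, noe_i, noe_h, j_atoms, j_dchi, j_xi, j_nsub, j_params,
                     noe_out, j_out):
    for m in range(noe_i.shape[0]):
        acc = 0.0
        i = noe_i[m]
        for col in range(3):
            h = noe_h[m, col]
            vx = x[i, 0] - x[h, 0]
            vy = x[i, 1] - x[h, 1]
            vz = x[i, 2] - x[h, 2]
            r2 = vx * vx + vy * vy + vz * vz
            acc += r2 ** -3.0
        noe_out[m] = acc / 3.0
    for q in range(j_atoms.shape[0]):
        phi, _ = _dihedral_grad(x, j_atoms[q, 0], j_atoms[q, 1], j_atoms[q, 2], j_atoms[q, 3])
        c_ = np.cos(phi)
        jv = j_params[q, 0] * c_ * c_ + j_params[q, 1] * c_ + j_params[q, 2]
        for t in range(j_nsub[q]):
            arg = j_xi[q, t] * phi + j_params[q, 5] * abs(j_dchi[q, t])
            jv += j_dchi[q, t] * (j_params[q, 3] + j_params[q, 4] * np.cos(arg) ** 2)
        j_out[q] = jv


@njit(**_NOPT)
def run_chunk(x, v, f, masses, t0, n_steps, dt, tau, rho, temp, tau_t,
              remove_com,
              bond_i, bond_j, bond_r0, bond_k,
              ang_i, ang_j, ang_k, ang_t0, ang_ka,
              tor_a, tor_b, tor_c, tor_d, tor_n, tor_g, tor_v,
              nb_i, nb_j, nb_sig, nb_eps, nb_qq, cutoff,
              rdc_bi, rdc_bj, rdc_group, rdc_wt, rdc_d, rdc_width, rdc_exp,
              rdc_S, rdc_N, k_rdc,
              noe_i, noe_h, noe_npart, noe_target, noe_width, noe_S, noe_N, k_noe,
              j_atoms, j_exp, j_width, j_dchi, j_xi, j_nsub, j_params, j_S, j_N, k_j,
              every, drop_steps, step0,
              snap_x, snap_rdc, snap_noe, snap_j, snap_t, snap_e, snap_count):
    """Advance n_steps; record snapshots into the provided buffers.

    Returns (new time, snapshot count, status) with status 0 = ok,
    1 = singular nonbonded contact, 2 = non-finite coordinates.
    """
    n = x.shape[0]
    decay = np.exp(-dt / tau)
    rdc_obs = np.empty_like(rdc_exp)
    noe_obs = np.empty(noe_i.shape[0])
    j_obs = np.empty(j_atoms.shape[0])
    t = t0
    count = snap_count
    for step in range(n_steps):
        # velocity Verlet: drift with old forces
        for a in range(n):
            am = ACC_UNIT / masses[a]
            for d_ in range(3):
                acc = am * f[a, d_]
                x[a, d_] += v[a, d_] * dt + 0.5 * acc * dt * dt
                v[a, d_] += 0.5 * acc * dt
        if not np.isfinite(x).all():
            return t, count, 2
        # new forces at advanced coordinates (pseudo part uses previous means)
        e_ff = _ff_forces(x, f, bond_i, bond_j, bond_r0, bond_k,
                          ang_i, ang_j, ang_k, ang_t0, ang_ka,
                          tor_a, tor_b, tor_c, tor_d, tor_n, tor_g, tor_v,
                          nb_i, nb_j, nb_sig, nb_eps, nb_qq, cutoff)
        if np.isnan(e_ff):
            return t, count, 1
        t = t + dt
        ramp = 1.0 - np.exp(-t / rho)
        _pseudo_forces(x, f, ramp,
                       rdc_bi, rdc_bj, rdc_group, rdc_wt, rdc_d, rdc_width, rdc_exp,
                       rdc_S, rdc_N, k_rdc,
                       noe_i, noe_h, noe_npart, noe_target, noe_width, noe_S, noe_N, k_noe,
                       j_atoms, j_exp, j_width, j_dchi, j_xi, j_nsub, j_params, j_S, j_N, k_j)
        # kick with new forces
        ke = 0.0
        for a in range(n):
            am = ACC_UNIT / masses[a]
            for d_ in range(3):
                v[a, d_] += 0.5 * am * f[a, d_] * dt
        # thermostat (weak coupling) + COM drift removal
        for a in range(n):
            ke += 0.5 * 0.01 * masses[a] * (v[a, 0] ** 2 + v[a, 1] ** 2 + v[a, 2] ** 2)
        t_inst = 2.0 * ke / ((3 * n - 3) * KB)
        if t_inst > 0.0:
            lam = np.sqrt(1.0 + dt / tau_t * (temp / t_inst - 1.0))
            if lam < 0.8:
                lam = 0.8
            elif lam > 1.25:
                lam = 1.25
            for a in range(n):
                for d_ in range(3):
                    v[a, d_] *= lam
        if remove_com:
            mtot = 0.0
            cx = cy = cz = 0.0
            for a in range(n):
                mtot += masses[a]
                cx += masses[a] * v[a, 0]
                cy += masses[a] * v[a, 1]
                cz += masses[a] * v[a, 2]
            cx /= mtot
            cy /= mtot
            cz /= mtot
            for a in range(n):
                v[a, 0] -= cx
                v[a, 1] -= cy
                v[a, 2] -= cz
        # memory updates with the observables at the new coordinates
        if rdc_d.shape[0] > 0:
            _observe_rdc(x, rdc_bi, rdc_bj, rdc_group, rdc_wt, rdc_d,
                         rdc_d.shape[0], rdc_obs)
            for g in range(rdc_d.shape[0]):
                rdc_N[g] = rdc_N[g] * decay + dt
                for a in range(3):
                    for b in range(3):
                        rdc_S[g, a, b] = rdc_S[g, a, b] * decay + rdc_obs[g, a, b] * dt
        if noe_i.shape[0] > 0 or j_atoms.shape[0] > 0:
            _observe_scalars(x, noe_i, noe_h, j_atoms, j_dchi, j_xi, j_nsub,
                             j_params, noe_obs, j_obs)
            for m in range(noe_i.shape[0]):
                noe_N[m] = noe_N[m] * decay + dt
                noe_S[m] = noe_S[m] * decay + noe_obs[m] * dt
            for q in range(j_atoms.shape[0]):
                j_N[q] = j_N[q] * decay + dt
                j_S[q] = j_S[q] * decay + j_obs[q] * dt
        # snapshots
        gstep = step0 + step + 1
        if gstep % every == 0 and gstep > drop_steps:
            for a in range(n):
                for d_ in range(3):
                    snap_x[count, a, d_] = x[a, d_]
            for g in range(rdc_d.shape[0]):
                for a in range(3):
                    for b in range(3):
                        snap_rdc[count, g, a, b] = rdc_S[g, a, b] / rdc_N[g]
            for m in range(noe_i.shape[0]):
                snap_noe[count, m] = noe_S[m] / noe_N[m]
            for q in range(j_atoms.shape[0]):
                snap_j[count, q] = j_S[q] / j_N[q]
            snap_t[count] = t
            snap_e[count] = e_ff
            count += 1
    return t, count, 0
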