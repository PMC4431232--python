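"""Numba-accelerated pairwise and integration kernels.

Everything in here works on bare float64 arrays; the public modules wrap
these in typed interfaces. All loops are O(n^2) over pairs — adequate for
the few hundred particles this tool targets (documented scaling limit).
Falls back to the same code uncompiled if numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco

_WCA_CUT = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def dipolar_fields(pos, mom, mu0):
    """Dipolar field B_i (T) at every particle from all others."""
    n = pos.shape[0]
    B = np.zeros((n, 3))
    pref = mu0 / (4.0 * np.pi)
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            r = np.sqrt(r2)
            inv_r = 1.0 / r
            ux = rx * inv_r
            uy = ry * inv_r
            uz = rz * inv_r
            c = pref / (r2 * r)
            mj_u = mom[j, 0] * ux + mom[j, 1] * uy + mom[j, 2] * uz
            B[i, 0] += c * (3.0 * mj_u * ux - mom[j, 0])
            B[i, 1] += c * (3.0 * mj_u * uy - mom[j, 1])
            B[i, 2] += c * (3.0 * mj_u * uz - mom[j, 2])
            mi_u = mom[i, 0] * ux + mom[i, 1] * uy + mom[i, 2] * uz
            B[j, 0] += c * (3.0 * mi_u * ux - mom[i, 0])
            B[j, 1] += c * (3.0 * mi_u * uy - mom[i, 1])
            B[j, 2] += c * (3.0 * mi_u * uz - mom[i, 2])
    return B


@njit(cache=True)
def dipolar_energy(pos, mom, mu0):
    """Total dipole-dipole energy (J), summed over unordered pairs."""
    n = pos.shape[0]
    e = 0.0
    pref = mu0 / (4.0 * np.pi)
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            r = np.sqrt(r2)
            inv_r = 1.0 / r
            ux = rx * inv_r
            uy = ry * inv_r
            uz = rz * inv_r
            mi_u = mom[i, 0] * ux + mom[i, 1] * uy + mom[i, 2] * uz
            mj_u = mom[j, 0] * ux + mom[j, 1] * uy + mom[j, 2] * uz
            mimj = (mom[i, 0] * mom[j, 0] + mom[i, 1] * mom[j, 1]
                    + mom[i, 2] * mom[j, 2])
            e += -(pref / (r2 * r)) * (3.0 * mi_u * mj_u - mimj)
    return e


@njit(cache=True)
def wca_total_energy(pos, diam, eps):
    """Total WCA energy (J) with per-pair contact sigma = (d_i + d_j)/2."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(rx * rx + ry * ry + rz * rz)
            sig = 0.5 * (diam[i] + diam[j])
            if r < _WCA_CUT * sig:
                sr2 = (sig / r) ** 2
                sr6 = sr2 * sr2 * sr2
                e += 4.0 * eps * (sr6 * sr6 - sr6) + eps
    return e


@njit(cache=True)
def pair_forces_kernel(pos, mom, diam, eps, mu0):
    """Dipolar + WCA forces (N), F_i = -grad_i (H_DD + H_WCA)."""
    n = pos.shape[0]
    F = np.zeros((n, 3))
    pref = 3.0 * mu0 / (4.0 * np.pi)
    for i in range(n):
        for j in range(i + 1, n):
            rx = pos[i, 0] - pos[j, 0]
            ry = pos[i, 1] - pos[j, 1]
            rz = pos[i, 2] - pos[j, 2]
            r2 = rx * rx + ry * ry + rz * rz
            r = np.sqrt(r2)
            inv_r = 1.0 / r
            ux = rx * inv_r
            uy = ry * inv_r
            uz = rz * inv_r
            mi_u = mom[i, 0] * ux + mom[i, 1] * uy + mom[i, 2] * uz
            mj_u = mom[j, 0] * ux + mom[j, 1] * uy + mom[j, 2] * uz
            mimj = (mom[i, 0] * mom[j, 0] + mom[i, 1] * mom[j, 1]
                    + mom[i, 2] * mom[j, 2])
            c = pref / (r2 * r2)
            fx = c * (mi_u * mom[j, 0] + mj_u * mom[i, 0]
                      + (mimj - 5.0 * mi_u * mj_u) * ux)
            fy = c * (mi_u * mom[j, 1] + mj_u * mom[i, 1]
                      + (mimj - 5.0 * mi_u * mj_u) * uy)
            fz = c * (mi_u * mom[j, 2] + mj_u * mom[i, 2]
                      + (mimj - 5.0 * mi_u * mj_u) * uz)
            sig = 0.5 * (diam[i] + diam[j])
            if r < _WCA_CUT * sig:
                sr2 = (sig / r) ** 2
                sr6 = sr2 * sr2 * sr2
                fmag = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) * inv_r
                fx += fmag * ux
                fy += fmag * uy
                fz += fmag * uz
            F[i, 0] += fx
            F[i, 1] += fy
            F[i, 2] += fz
            F[j, 0] -= fx
            F[j, 1] -= fy
            F[j, 2] -= fz
    return F


@njit(cache=True)
def _llg_rhs(mom, B, mmag, alpha, gamma):
    n = mom.shape[0]
    out = np.empty((n, 3))
    c1 = gamma / (1.0 + alpha * alpha)
    for i in range(n):
        mx, my, mz = mom[i, 0], mom[i, 1], mom[i, 2]
        bx, by, bz = B[i, 0], B[i, 1], B[i, 2]
        # m x B
        px = my * bz - mz * by
        py = mz * bx - mx * bz
        pz = mx * by - my * bx
        # m x (m x B)
        qx = my * pz - mz * py
        qy = mz * px - mx * pz
        qz = mx * py - my * px
        a = alpha / mmag[i]
        out[i, 0] = -c1 * (px + a * qx)
        out[i, 1] = -c1 * (py + a * qy)
        out[i, 2] = -c1 * (pz + a * qz)
    return out


@njit(cache=True)
def llg_run(pos, mom, mmag, bext, alpha, gamma, dt, kT, mu0,
            record_every, seed):
    """Heun-integrated stochastic LLG at fixed positions.

    ``bext`` has shape (n_steps, 3): the uniform external field per step.
    Thermal field variance per component is 2*alpha*kT/(gamma*|m|*dt).
    Moments are renormalized to ``mmag`` every step. Records reduced
    magnetization, dipolar and Zeeman energy, and moment snapshots every
    ``record_every`` steps (always including the final step).

    Returns (mom, rec_steps, mags, e_dip, e_zee, snaps, status) with
    status 0 = ok, 1 = non-finite state detected.
    """
    n = mom.shape[0]
    n_steps = bext.shape[0]
    n_rec = n_steps // record_every
    if n_steps % record_every != 0:
        n_rec += 1
    rec_steps = np.empty(n_rec, dtype=np.int64)
    mags = np.empty((n_rec, 3))
    e_dip = np.empty(n_rec)
    e_zee = np.empty(n_rec)
    snaps = np.empty((n_rec, n, 3))
    status = 0

    np.random.seed(seed)
    msum = mmag.sum()
    noise = kT > 0.0
    amp = np.zeros(n)
    if noise:
        for i in range(n):
            amp[i] = np.sqrt(2.0 * alpha * kT / (gamma * mmag[i] * dt))

    b = np.zeros((n, 3))
    irec = 0
    for step in range(n_steps):
        if noise:
            for i in range(n):
                b[i, 0] = amp[i] * np.random.normal()
                b[i, 1] = amp[i] * np.random.normal()
                b[i, 2] = amp[i] * np.random.normal()
        B1 = dipolar_fields(pos, mom, mu0)
        for i in range(n):
            B1[i, 0] += bext[step, 0] + b[i, 0]
            B1[i, 1] += bext[step, 1] + b[i, 1]
            B1[i, 2] += bext[step, 2] + b[i, 2]
        k1 = _llg_rhs(mom, B1, mmag, alpha, gamma)
        mpred = mom + dt * k1
        B2 = dipolar_fields(pos, mpred, mu0)
        for i in range(n):
            B2[i, 0] += bext[step, 0] + b[i, 0]
            B2[i, 1] += bext[step, 1] + b[i, 1]
            B2[i, 2] += bext[step, 2] + b[i, 2]
        k2 = _llg_rhs(mpred, B2, mmag, alpha, gamma)
        mom = mom + (0.5 * dt) * (k1 + k2)
        for i in range(n):
            norm = np.sqrt(mom[i, 0] ** 2 + mom[i, 1] ** 2 + mom[i, 2] ** 2)
            scale = mmag[i] / norm
            mom[i, 0] *= scale
            mom[i, 1] *= scale
            mom[i, 2] *= scale

        last = step == n_steps - 1
        if (step + 1) % record_every == 0 or last:
            if irec < n_rec:
                rec_steps[irec] = step + 1
                mx = mom[:, 0].sum() / msum
                my = mom[:, 1].sum() / msum
                mz = mom[:, 2].sum() / msum
                mags[irec, 0] = mx
                mags[irec, 1] = my
                mags[irec, 2] = mz
                e_dip[irec] = dipolar_energy(pos, mom, mu0)
                ez = 0.0
                for i in range(n):
                    ez -= (mom[i, 0] * bext[step, 0]
                           + mom[i, 1] * bext[step, 1]
                           + mom[i, 2] * bext[step, 2])
                e_zee[irec] = ez
                snaps[irec] = mom
                if not np.isfinite(e_dip[irec]):
                    status = 1
                irec += 1
    return mom, rec_steps, mags, e_dip, e_zee, snaps, status


@njit(cache=True)
def md_overdamped_run(pos, mom, diam, eps, mu0, dt, drag, kT, box,
                      motion_dim, reflective, n_steps, seed, max_disp):
    """Overdamped (Brownian) translational dynamics at fixed moments.

    dx = F/drag * dt + sqrt(2 kT dt / drag) * xi, reflective or periodic
    box, optional planar confinement. Returns (pos, status) with status
    0 = ok, 1 = per-step displacement exceeded ``max_disp``,
    2 = non-finite position.
    """
    n = pos.shape[0]
    np.random.seed(seed)
    ndim = motion_dim
    status = 0
    sqamp = np.zeros(n)
    if kT > 0.0:
        for i in range(n):
            sqamp[i] = np.sqrt(2.0 * kT * dt / drag[i])
    for step in range(n_steps):
        F = pair_forces_kernel(pos, mom, diam, eps, mu0)
        for i in range(n):
            for a in range(ndim):
                dx = F[i, a] * dt / drag[i]
                if kT > 0.0:
                    dx += sqamp[i] * np.random.normal()
                if abs(dx) > max_disp:
                    status = 1
                    return pos, status
                x = pos[i, a] + dx
                L = box[a]
                if reflective:
                    # fold into [0, 2L] then reflect
                    if x < 0.0 or x > L:
                        x = x % (2.0 * L)
                        if x > L:
                            x = 2.0 * L - x
                else:
                    x = x % L
                if not np.isfinite(x):
                    status = 2
                    return pos, status
                pos[i, a] = x
    return pos, status
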