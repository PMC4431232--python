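"""Independent reference implementations used only by the tests.

Everything here is written from the defining formulas, deliberately not
sharing code with the package: hand-substituted pair energies, in-plane
angle-grid ground-state searches, finite-difference gradients and
piecewise-exponential binding solutions.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MU0 = 4e-7 * np.pi


def dipole_pair_energy_oracle(m1, m2, r12):
    """Direct substitution into the dipole-dipole energy formula."""
    m1, m2, r12 = (np.asarray(v, dtype=float) for v in (m1, m2, r12))
    r = np.sqrt((r12**2).sum())
    rh = r12 / r
    return -MU0 / (4 * np.pi * r**3) * (
        3 * (m1 @ rh) * (m2 @ rh) - m1 @ m2
    )


def planar_pair_matrix(C, phi, angles):
    """Pair energy for all in-plane angle combinations.

    E(a, b) = -C [3 cos(ta - phi) cos(tb - phi) - cos(ta - tb)] where C =
    mu0 m^2 / (4 pi r^3) and phi is the bond angle.
    """
    ca = np.cos(angles - phi)
    diff = np.cos(angles[:, None] - angles[None, :])
    return -C * (3 * ca[:, None] * ca[None, :] - diff)


@njit(cache=True)
def _min3(E12, E13, E23):
    n = E12.shape[0]
    best = 1e300
    ba = bb = bc = 0
    for a in range(n):
        for b in range(n):
            e_ab = E12[a, b]
            for c in range(n):
                e = e_ab + E13[a, c] + E23[b, c]
                if e < best:
                    best = e
                    ba, bb, bc = a, b, c
    return best, ba, bb, bc


@njit(cache=True)
def _min4(E12, E13, E14, E23, E24, E34):
    n = E12.shape[0]
    best = 1e300
    ba = bb = bc = bd = 0
    # row-wise minima give a valid lower bound on the d-sum for pruning
    r14 = np.empty(n)
    r24 = np.empty(n)
    r34 = np.empty(n)
    for k in range(n):
        r14[k] = E14[k].min()
        r24[k] = E24[k].min()
        r34[k] = E34[k].min()
    for a in range(n):
        for b in range(n):
            e_ab = E12[a, b] + r14[a] + r24[b]
            for c in range(n):
                e_abc = e_ab + E13[a, c] + E23[b, c]
                if e_abc + r34[c] > best:
                    continue
                base = E12[a, b] + E13[a, c] + E23[b, c]
                for d in range(n):
                    e = base + E14[a, d] + E24[b, d] + E34[c, d]
                    if e < best:
                        best = e
                        ba, bb, bc, bd = a, b, c, d
    return best, ba, bb, bc, bd


def planar_energy(thetas, positions, moment):
    """Total in-plane dipolar energy at explicit angles (radians)."""
    n = len(thetas)
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            rij = positions[j] - positions[i]
            r = np.hypot(*rij)
            phi = np.arctan2(rij[1], rij[0])
            C = MU0 * moment**2 / (4 * np.pi * r**3)
            e += -C * (
                3 * np.cos(thetas[i] - phi) * np.cos(thetas[j] - phi)
                - np.cos(thetas[i] - thetas[j])
            )
    return e


def brute_force_ground_state(positions, moment, coarse_deg=1.0,
                             refine_deg=None, refine_window_deg=4.0):
    """Exhaustive in-plane angle-grid ground-state energy.

    Searches the full ``coarse_deg`` grid; optionally refines every
    angle on a ``refine_deg`` grid within +/- ``refine_window_deg`` of
    the coarse optimum (used to reach 1 degree on 4 particles within the
    time budget).
    """
    positions = np.asarray(positions, dtype=float)[:, :2]
    n = len(positions)
    angles = np.deg2rad(np.arange(0.0, 360.0, coarse_deg))
    mats = {}
    for i in range(n):
        for j in range(i + 1, n):
            rij = positions[j] - positions[i]
            r = np.hypot(*rij)
            phi = np.arctan2(rij[1], rij[0])
            C = MU0 * moment**2 / (4 * np.pi * r**3)
            mats[(i, j)] = planar_pair_matrix(C, phi, angles)
    if n == 3:
        best, *idx = _min3(mats[(0, 1)], mats[(0, 2)], mats[(1, 2)])
    elif n == 4:
        best, *idx = _min4(mats[(0, 1)], mats[(0, 2)], mats[(0, 3)],
                           mats[(1, 2)], mats[(1, 3)], mats[(2, 3)])
    else:
        raise ValueError("oracle supports 3 or 4 particles")
    theta0 = angles[list(idx)]
    if refine_deg is None:
        return best
    offs = np.deg2rad(np.arange(-refine_window_deg,
                                refine_window_deg + 1e-9, refine_deg))
    grids = np.meshgrid(*([offs] * n), indexing="ij")
    combos = np.stack([g.ravel() for g in grids], axis=1) + theta0
    energies = [planar_energy(t, positions, moment) for t in combos]
    return min(best, min(energies))


def finite_difference_forces(energy_fn, positions, h=1e-12):
    """Central-difference gradient of a total-energy callable."""
    F = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for a in range(3):
            p = positions.copy()
            p[i, a] += h
            ep = energy_fn(p)
            p[i, a] -= 2 * h
            em = energy_fn(p)
            F[i, a] = -(ep - em) / (2 * h)
    return F


def piecewise_langmuir(t_grid, segments, ka, kd, nA, n0=0.0):
    """Closed-form n(t) for piecewise-constant c(t).

    ``segments`` is a list of (t_start, t_end, c); the rate law is linear
    in n on each segment, so the solution is a chained exponential.
    """
    out = np.empty_like(t_grid, dtype=float)
    n = n0
    seg_idx = 0
    t_prev = segments[0][0]
    for k, t in enumerate(t_grid):
        while seg_idx < len(segments) and t > segments[seg_idx][1] + 1e-15:
            t0, t1, c = segments[seg_idx]
            n = _advance(n, c, t1 - t_prev, ka, kd, nA)
            t_prev = t1
            seg_idx += 1
        c = segments[min(seg_idx, len(segments) - 1)][2]
        out[k] = _advance(n, c, t - t_prev, ka, kd, nA)
    return out


def _advance(n, c, dt, ka, kd, nA):
    lam = (ka * c + kd) / nA
    if lam == 0:
        return n
    n_inf = ka * c / lam
    return n_inf + (n - n_inf) * np.exp(-lam * dt)
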