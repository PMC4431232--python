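"""Pairwise dipole-dipole and WCA interactions: energies, fields, forces.

The dipolar pair energy is

    E = -(mu0 / (4 pi r^3)) * [3 (m1.rhat)(m2.rhat) - m1.m2]

and the WCA (truncated-shifted Lennard-Jones) repulsion is

    E = 4 eps [(sigma/r)^12 - (sigma/r)^6] + eps   for r < 2^(1/6) sigma
    E = 0                                          otherwise.

Ensemble-level routines use a per-pair contact sigma = (d_i + d_j)/2 so
the repulsion enforces hard-sphere behavior at the particle diameters;
the scalar :class:`WCAParams.sigma` applies to the single-pair API.
All sums are full all-pairs (no dipolar cutoff).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import MU0, KB
from .ensemble import NanoparticleEnsemble
from .errors import DomainError, SingularityError
from . import _kernels

WCA_CUTOFF_FACTOR = 2.0 ** (1.0 / 6.0)


@dataclass(frozen=True)
class WCAParams:
    """Parameters of the WCA short-range repulsion.

    ``cutoff`` is fixed by definition to ``2^(1/6) * sigma``.
    """

    epsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise DomainError("epsilon and sigma must be positive")

    @property
    def cutoff(self) -> float:
        return WCA_CUTOFF_FACTOR * self.sigma


def default_wca_params(ensemble: NanoparticleEnsemble) -> WCAParams:
    """WCA parameters scaled to the ensemble's dipolar contact energy.

    epsilon defaults to one sixth of the head-to-tail contact energy
    mu0 m^2/(2 pi d^3) of the strongest pair (floored at 1 kB*298K for
    weakly magnetic ensembles): this puts the equilibrium separation of
    an attracting head-to-tail pair at ~1.02 d, i.e. the particles
    behave like hard spheres of their stated diameters instead of being
    crushed well below contact by the strong dipolar attraction.
    """
    m = ensemble.moment_magnitudes.max(initial=0.0)
    d = float(ensemble.diameters.min())
    e_contact = ensemble.constants.mu0 * m * m / (2.0 * math.pi * d**3)
    eps = max(e_contact / 6.0, KB * 298.0)
    return WCAParams(epsilon=eps, sigma=d)


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy components (J); ``total`` is their exact sum."""

    dipolar: float
    wca: float
    zeeman: float

    @property
    def total(self) -> float:
        return self.dipolar + self.wca + self.zeeman


def pair_dipole_energy(m1, m2, r12, mu0: float = MU0) -> float:
    """Dipole-dipole energy (J) of two moments separated by ``r12``."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    r12 = np.asarray(r12, dtype=float)
    r = np.linalg.norm(r12)
    if r == 0:
        raise SingularityError("zero separation between dipoles")
    rhat = r12 / r
    return float(
        -(mu0 / (4.0 * math.pi * r**3))
        * (3.0 * np.dot(m1, rhat) * np.dot(m2, rhat) - np.dot(m1, m2))
    )


def _check_separations(ensemble: NanoparticleEnsemble) -> None:
    pos = ensemble.positions
    for i in range(ensemble.n):
        d2 = np.sum((pos[i + 1:] - pos[i]) ** 2, axis=1)
        if d2.size and d2.min() == 0.0:
            j = i + 1 + int(np.argmin(d2))
            raise SingularityError(f"particles {i} and {j} coincide")


def dipolar_field(ensemble: NanoparticleEnsemble, i: int) -> np.ndarray:
    """Dipolar field (T) at particle ``i`` from all other particles.

    Consistent with :func:`pair_dipole_energy` through
    H_DD = -1/2 sum_i m_i . B_i.
    """
    if not 0 <= i < ensemble.n:
        raise DomainError(f"particle index {i} out of range")
    _check_separations(ensemble)
    B = _kernels.dipolar_fields(
        ensemble.positions, ensemble.moments, ensemble.constants.mu0
    )
    return B[i]


def dipolar_fields(ensemble: NanoparticleEnsemble) -> np.ndarray:
    """Dipolar field (T) at every particle, shape (n, 3)."""
    _check_separations(ensemble)
    return _kernels.dipolar_fields(
        ensemble.positions, ensemble.moments, ensemble.constants.mu0
    )


def wca_energy(r, params: WCAParams):
    """WCA energy (J) at separation ``r`` (scalar or array)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("separation must be positive")
    sr6 = (params.sigma / r) ** 6
    e = np.where(r < params.cutoff,
                 4.0 * params.epsilon * (sr6 * sr6 - sr6) + params.epsilon,
                 0.0)
    return float(e) if e.ndim == 0 else e


def pair_forces(
    ensemble: NanoparticleEnsemble, params: WCAParams | None = None
) -> np.ndarray:
    """Forces F_i = -grad_i (H_DD + H_WCA), shape (n, 3), in N.

    Analytic dipolar force; WCA with per-pair contact sigma. The summed
    force vanishes (isolated system).
    """
    if params is None:
        params = default_wca_params(ensemble)
    _check_separations(ensemble)
    return _kernels.pair_forces_kernel(
        ensemble.positions,
        ensemble.moments,
        ensemble.diameters,
        params.epsilon,
        ensemble.constants.mu0,
    )


def total_energy(
    ensemble: NanoparticleEnsemble,
    B_ext=None,
    params: WCAParams | None = None,
) -> EnergyBreakdown:
    """Dipolar + WCA + Zeeman energy breakdown of the ensemble."""
    if params is None:
        params = default_wca_params(ensemble)
    _check_separations(ensemble)
    mu0 = ensemble.constants.mu0
    e_dip = _kernels.dipolar_energy(ensemble.positions, ensemble.moments, mu0)
    e_wca = _kernels.wca_total_energy(
        ensemble.positions, ensemble.diameters, params.epsilon
    )
    if B_ext is None:
        e_zee = 0.0
    else:
        B_ext = np.asarray(B_ext, dtype=float).reshape(3)
        e_zee = float(-(ensemble.moments @ B_ext).sum())
    return EnergyBreakdown(dipolar=float(e_dip), wca=float(e_wca),
                           zeeman=e_zee)
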