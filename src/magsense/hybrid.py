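"""Translational dynamics and the alternating SD/MD scheduler.

Particle translation is overdamped Langevin motion under dipolar + WCA
forces (viscous gel, inertia negligible): dx = F/drag dt + thermal kick.
The hybrid scheduler exploits the separation between fast magnetic and
slow translational time scales: moments are relaxed to their ground
state at fixed positions, then positions advance for a block of MD steps
at fixed moments, alternating until the step budget is spent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import KB
from .ensemble import NanoparticleEnsemble
from .errors import DomainError, StabilityError
from .interactions import EnergyBreakdown, WCAParams, default_wca_params, total_energy
from .spin_dynamics import RelaxResult, SDParams, Trajectory, relax
from . import _kernels

#: Default solvent viscosity (Pa s) for the Stokes drag estimate.
ETA_WATER = 1.0e-3

#: Cobalt mass density (kg/m^3), used for the (unused in overdamped mode)
#: particle mass bookkeeping.
RHO_COBALT = 8900.0


def stokes_drag(diameter: float, eta: float = ETA_WATER) -> float:
    """Stokes drag coefficient 6 pi eta r (kg/s)."""
    if diameter <= 0 or eta <= 0:
        raise DomainError("diameter and eta must be positive")
    return 6.0 * math.pi * eta * (diameter / 2.0)


@dataclass(frozen=True)
class MDParams:
    """Translational-integrator parameters.

    ``drag`` defaults (when None) to the per-particle Stokes value
    6 pi eta r in water; ``mass`` is kept for bookkeeping (the default
    integrator is overdamped and does not use it).
    """

    dt: float = 1e-10
    drag: float | None = None
    mass: float | None = None
    temperature: float = 298.0
    seed: int = 0
    eta: float = ETA_WATER

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.drag is not None and self.drag < 0:
            raise DomainError("drag must be non-negative")
        if self.mass is not None and self.mass <= 0:
            raise DomainError("mass must be positive")

    def drag_array(self, ensemble: NanoparticleEnsemble) -> np.ndarray:
        if self.drag is not None:
            return np.full(ensemble.n, float(self.drag))
        return np.array([stokes_drag(d, self.eta) for d in ensemble.diameters])


@dataclass(frozen=True)
class HybridSchedule:
    """MD step budget and SD cadence of the alternating scheduler."""

    total_steps: int
    sd_every: int
    sd_budget: int = 20_000

    def __post_init__(self) -> None:
        if not self.total_steps >= self.sd_every >= 1:
            raise DomainError("require total_steps >= sd_every >= 1")
        if self.sd_budget < 1:
            raise DomainError("sd_budget must be >= 1")


def md_integrate(
    ensemble: NanoparticleEnsemble,
    params: MDParams,
    n_steps: int,
    B_ext=None,
    wca: WCAParams | None = None,
) -> NanoparticleEnsemble:
    """Advance positions ``n_steps`` overdamped steps at fixed moments.

    A uniform ``B_ext`` exerts no translational force and is accepted
    only for signature symmetry. Raises :class:`StabilityError` when any
    per-step displacement exceeds half a contact diameter (advice:
    halve dt).
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    if wca is None:
        wca = default_wca_params(ensemble)
    out = ensemble.copy()
    drag = params.drag_array(out)
    if np.any(drag <= 0):
        raise DomainError("overdamped integration requires positive drag")
    max_disp = 0.5 * float(out.diameters.min())
    pos, status = _kernels.md_overdamped_run(
        out.positions,
        out.moments,
        out.diameters,
        wca.epsilon,
        out.constants.mu0,
        params.dt,
        drag,
        KB * params.temperature,
        out.box,
        out.motion_dim,
        out.boundary == "reflective",
        n_steps,
        params.seed,
        max_disp,
    )
    if status == 1:
        raise StabilityError(
            "MD step displacement exceeded sigma/2; reduce dt"
        )
    if status == 2:
        raise StabilityError("MD produced non-finite positions; reduce dt")
    out.positions = pos
    return out


def hybrid_run(
    ensemble: NanoparticleEnsemble,
    schedule: HybridSchedule,
    md: MDParams | None = None,
    sd: SDParams | None = None,
    wca: WCAParams | None = None,
    relax_tol: float = 1e-24,
) -> Trajectory:
    """Alternate [SD relax at fixed positions] -> [MD block at fixed moments].

    Snapshots (positions + moments), the energy breakdown and the reduced
    magnetization are recorded at every SD point. Seeds for successive MD
    blocks are derived as ``md.seed + block_index`` so a single-block run
    equals a manual relax + md_integrate with the same seed.
    """
    md = md or MDParams()
    sd = sd or SDParams()
    if wca is None:
        wca = default_wca_params(ensemble)
    window = min(schedule.sd_budget, 2000)
    max_windows = max(1, schedule.sd_budget // window)

    def do_relax(ens: NanoparticleEnsemble) -> RelaxResult:
        return relax(ens, sd, tol=relax_tol, window=window,
                     max_windows=max_windows)

    times: list[float] = []
    snaps_pos: list[np.ndarray] = []
    snaps_mom: list[np.ndarray] = []
    energies: list[EnergyBreakdown] = []
    mags: list[np.ndarray] = []

    state = ensemble.copy()
    t_md = 0.0
    block = 0

    def record(ens: NanoparticleEnsemble) -> None:
        times.append(t_md)
        snaps_pos.append(ens.positions.copy())
        snaps_mom.append(ens.moments.copy())
        energies.append(total_energy(ens, params=wca))
        mags.append(ens.reduced_magnetization())

    res = do_relax(state)
    state = res.ensemble
    record(state)

    steps_left = schedule.total_steps
    while steps_left > 0:
        n = min(schedule.sd_every, steps_left)
        block_md = MDParams(
            dt=md.dt, drag=md.drag, mass=md.mass,
            temperature=md.temperature, seed=md.seed + block, eta=md.eta,
        )
        state = md_integrate(state, block_md, n, wca=wca)
        t_md += n * md.dt
        steps_left -= n
        block += 1
        res = do_relax(state)
        state = res.ensemble
        record(state)

    return Trajectory(
        times=np.asarray(times),
        moments=np.asarray(snaps_mom),
        energies=energies,
        magnetization=np.asarray(mags),
        positions=np.asarray(snaps_pos),
        final_ensemble=state,
    )
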