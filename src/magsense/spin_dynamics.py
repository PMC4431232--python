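"""Langevin spin dynamics of moment orientations at fixed positions.

The equation of motion is the stochastic Landau-Lifshitz-Gilbert form

    dm/dt = -gamma/(1+a^2) m x (B+b) - gamma a /((1+a^2)|m|) m x (m x (B+b))

with damping ``a``, effective field ``B`` (external + dipolar) and a
thermal field ``b`` of per-component variance 2 a kB T/(gamma |m| dt),
integrated with a Heun predictor-corrector and per-step moment
renormalization. T = 0 damped integration is used for ground-state
relaxation; a rotating, oscillating, amplitude-damped field protocol
shakes frustrated configurations out of local minima before a final
relaxation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .ensemble import NanoparticleEnsemble
from .errors import DomainError, IntegrationError
from .interactions import EnergyBreakdown, WCAParams, total_energy
from . import _kernels


@dataclass(frozen=True)
class SDParams:
    """Spin-integrator parameters (all overridable defaults)."""

    alpha: float = 0.1
    dt: float = 1e-13
    gamma: float = 1.76e11
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise DomainError("dt must be positive")
        if self.alpha < 0:
            raise DomainError("alpha must be non-negative")


# ---------------------------------------------------------------------------
# field protocols


class FieldProtocol:
    """Time-dependent uniform external field B(t)."""

    def series(self, dt: float, n_steps: int) -> np.ndarray:
        """Field at each step midpoint, shape (n_steps, 3)."""
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantField(FieldProtocol):
    B: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def series(self, dt: float, n_steps: int) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.B, dtype=float),
                               (n_steps, 3)).copy()


ZERO_FIELD = ConstantField()


@dataclass(frozen=True)
class DemagProtocol(FieldProtocol):
    """Sinusoidally oscillating, rotating, amplitude-damped field.

    B(t) = A(t) sin(2 pi n_osc t / T) * u(phi(t), theta(t)) with the
    amplitude decaying from B0 to 0 over ``duration`` (linearly by
    default), azimuth advancing ``azimuthal_turns`` full turns and the
    polar angle sweeping [0, pi] ``polar_turns`` times. Only the turn
    counts and the amplitude bounds are physical inputs; the waveform
    parametrization is one valid reading of them.
    """

    B0: float = 0.05
    n_oscillations: int = 30
    azimuthal_turns: int = 7
    polar_turns: int = 3
    duration: float = 1e-7
    damping_shape: str = "linear"

    def __post_init__(self) -> None:
        if self.B0 < 0 or self.duration <= 0:
            raise DomainError("B0 must be >= 0 and duration > 0")
        if min(self.n_oscillations, self.azimuthal_turns,
               self.polar_turns) < 0:
            raise DomainError("turn counts must be non-negative")
        if self.damping_shape not in ("linear", "exponential"):
            raise DomainError("damping_shape must be linear or exponential")

    def series(self, dt: float, n_steps: int) -> np.ndarray:
        t = (np.arange(n_steps) + 0.5) * dt
        x = np.clip(t / self.duration, 0.0, 1.0)
        if self.damping_shape == "linear":
            amp = self.B0 * (1.0 - x)
        else:
            amp = self.B0 * np.exp(-5.0 * x) * (1.0 - x > 0)
        osc = np.sin(2.0 * math.pi * self.n_oscillations * x)
        phi = 2.0 * math.pi * self.azimuthal_turns * x
        theta = 0.5 * math.pi * (1.0 + np.cos(2.0 * math.pi
                                              * self.polar_turns * x))
        s = amp * osc
        out = np.empty((n_steps, 3))
        out[:, 0] = s * np.sin(theta) * np.cos(phi)
        out[:, 1] = s * np.sin(theta) * np.sin(phi)
        out[:, 2] = s * np.cos(theta)
        return out


@dataclass(frozen=True)
class FieldSweep:
    """Field sweep along an axis for magnetization/GMR curves."""

    B_max: float
    n_steps: int
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    mode: str = "loop"

    def __post_init__(self) -> None:
        if self.B_max < 0:
            raise DomainError("B_max must be >= 0")
        if self.n_steps < 2:
            raise DomainError("n_steps must be >= 2")
        if self.mode not in ("loop", "half"):
            raise DomainError("mode must be 'loop' or 'half'")

    @property
    def unit_axis(self) -> np.ndarray:
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0:
            raise DomainError("sweep axis must be non-zero")
        return a / n

    def field_values(self) -> np.ndarray:
        down = np.linspace(self.B_max, -self.B_max, self.n_steps)
        if self.mode == "half":
            return down
        up = np.linspace(-self.B_max, self.B_max, self.n_steps)[1:]
        return np.concatenate([down, up])


# ---------------------------------------------------------------------------
# trajectory record


@dataclass
class Trajectory:
    """Sampled time series of an SD (or hybrid SD/MD) run."""

    times: np.ndarray
    moments: np.ndarray  # (n_rec, n, 3)
    energies: list[EnergyBreakdown]
    magnetization: np.ndarray  # (n_rec, 3), reduced M/Ms
    positions: np.ndarray | None = None  # (n_rec, n, 3) for hybrid runs
    final_ensemble: NanoparticleEnsemble | None = None

    def __post_init__(self) -> None:
        n_rec = len(self.times)
        if not (len(self.energies) == n_rec
                and self.magnetization.shape[0] == n_rec
                and self.moments.shape[0] == n_rec):
            raise DomainError("trajectory series lengths differ")
        if np.any(np.linalg.norm(self.magnetization, axis=1) > 1.0 + 1e-9):
            raise DomainError("|M|/Ms must not exceed 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class RelaxResult:
    ensemble: NanoparticleEnsemble
    energy: EnergyBreakdown
    converged: bool
    n_steps: int


# ---------------------------------------------------------------------------
# integration drivers


def _run_llg(ensemble, bext, params, record_every):
    mom, rec_steps, mags, e_dip, e_zee, snaps, status = _kernels.llg_run(
        ensemble.positions,
        ensemble.moments.copy(),
        ensemble.moment_magnitudes,
        bext,
        params.alpha,
        params.gamma,
        params.dt,
        ensemble.constants.kB * ensemble.temperature,
        ensemble.constants.mu0,
        record_every,
        params.seed,
    )
    if status != 0:
        raise IntegrationError(
            "spin integration diverged; reduce dt (gamma*B*dt must stay small)"
        )
    return mom, rec_steps, mags, e_dip, e_zee, snaps


def sd_integrate(
    ensemble: NanoparticleEnsemble,
    field: FieldProtocol,
    params: SDParams,
    n_steps: int,
    record_every: int | None = None,
    wca: WCAParams | None = None,
) -> Trajectory:
    """Integrate the stochastic LLG equations at fixed positions.

    The input ensemble is not modified; the evolved copy is available as
    ``trajectory.final_ensemble``. |m_i| is conserved by construction
    (per-step renormalization). Deterministic for a given seed.
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    if record_every is None:
        record_every = max(1, n_steps // 200)
    bext = field.series(params.dt, n_steps)
    mom, rec_steps, mags, e_dip, e_zee, snaps = _run_llg(
        ensemble, bext, params, record_every
    )
    out = ensemble.copy()
    out.moments = mom
    e_wca = total_energy(out, params=wca).wca
    energies = [
        EnergyBreakdown(dipolar=float(d), wca=e_wca, zeeman=float(z))
        for d, z in zip(e_dip, e_zee)
    ]
    return Trajectory(
        times=rec_steps * params.dt,
        moments=snaps,
        energies=energies,
        magnetization=mags,
        final_ensemble=out,
    )


def relax(
    ensemble: NanoparticleEnsemble,
    params: SDParams | None = None,
    tol: float = 1e-24,
    B_ext=None,
    window: int = 1000,
    max_windows: int = 200,
) -> RelaxResult:
    """Damped T=0 integration until the energy change per window < ``tol``.

    Returns the relaxed ensemble and its energy breakdown; if the budget
    of ``max_windows * window`` steps is exhausted first, the best state
    is returned flagged ``converged=False``.
    """
    if tol <= 0:
        raise DomainError("tol must be positive")
    params = params or SDParams()
    if params.alpha <= 0:
        raise DomainError("relaxation requires alpha > 0")
    work = ensemble.with_(temperature=0.0)
    fieldp = ConstantField(tuple(np.asarray(B_ext, dtype=float))) \
        if B_ext is not None else ZERO_FIELD
    bext = fieldp.series(params.dt, window)

    e_prev = None
    steps = 0
    converged = False
    for _ in range(max_windows):
        mom, _, _, e_dip, e_zee, _ = _run_llg(work, bext, params,
                                              record_every=window)
        work.moments = mom
        steps += window
        e_now = float(e_dip[-1] + e_zee[-1])
        if e_prev is not None and abs(e_now - e_prev) < tol:
            converged = True
            break
        e_prev = e_now
    energy = total_energy(work, B_ext=B_ext)
    return RelaxResult(ensemble=work, energy=energy, converged=converged,
                       n_steps=steps)


def demagnetize(
    ensemble: NanoparticleEnsemble,
    protocol: DemagProtocol,
    params: SDParams | None = None,
    tol: float = 1e-24,
) -> RelaxResult:
    """Apply the rotating damped-field protocol, then a final relaxation.

    A zero-amplitude protocol degenerates exactly to :func:`relax`.
    """
    params = params or SDParams()
    if protocol.B0 == 0:
        return relax(ensemble, params, tol=tol)
    n_steps = max(1, int(round(protocol.duration / params.dt)))
    bext = protocol.series(params.dt, n_steps)
    work = ensemble.with_(temperature=0.0)
    mom, _, _, _, _, _ = _run_llg(work, bext, params,
                                  record_every=max(1, n_steps // 4))
    work.moments = mom
    return relax(work, params, tol=tol)


def magnetization_curve(
    ensemble: NanoparticleEnsemble,
    sweep: FieldSweep,
    params: SDParams | None = None,
    steps_per_field: int = 2000,
    equil_windows: int = 8,
    equil_tol: float = 1e-24,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-static M(B) loop along the sweep axis.

    At each field value the moments are integrated in windows of
    ``steps_per_field`` T=0 steps until the energy plateaus (or the
    window budget is exhausted), then the reduced magnetization component
    along the axis is recorded. State carries over between field values,
    so hysteresis is captured.
    """
    params = params or SDParams()
    axis = sweep.unit_axis
    work = ensemble.with_(temperature=0.0)
    B_values = sweep.field_values()
    m_values = np.empty_like(B_values)
    msum = work.moment_magnitudes.sum()
    for k, B in enumerate(B_values):
        bvec = tuple(B * axis)
        bext = ConstantField(bvec).series(params.dt, steps_per_field)
        e_prev = None
        for _ in range(equil_windows):
            mom, _, _, e_dip, e_zee, _ = _run_llg(
                work, bext, params, record_every=steps_per_field
            )
            work.moments = mom
            e_now = float(e_dip[-1] + e_zee[-1])
            if e_prev is not None and abs(e_now - e_prev) < equil_tol:
                break
            e_prev = e_now
        m_values[k] = float(work.moments.sum(axis=0) @ axis) / msum
    return B_values, m_values
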