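"""1:1 Langmuir surface binding: rate law, isotherm, well-mixed sensorgrams.

The surface rate law is

    dn/dt = ka c (1 - n/nA) - kd n / nA

with ``ka`` (m/s) the association rate, ``kd`` (mol m^-2 s^-1) the
dissociation rate in surface-flux units, ``nA`` (mol/m^2) the acceptor
density and ``c`` (mol/m^3) the solution concentration at the surface.
The equilibrium dissociation constant KD (mol/m^3) ties them together
via ka = kd / KD. The conventional first-order off-rate in 1/s is the
derived quantity k_off = kd/nA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError

# Published reference values for the PhoB/DNA system driving the defaults.
DEFAULT_NA = 2.56e-8  # mol/m^2
DEFAULT_KD_RATE = 1.5e-8  # mol m^-2 s^-1
DEFAULT_KD_EQ = 21e-3  # mol/m^3


def association_from_equilibrium(kd: float, KD: float) -> float:
    """ka = kd / KD (m/s)."""
    if KD <= 0:
        raise DomainError("KD must be positive")
    if kd < 0:
        raise DomainError("kd must be non-negative")
    return kd / KD


@dataclass(frozen=True)
class BindingParams:
    """Rate constants of the 1:1 surface reaction.

    Any one of ``ka``/``kd``/``KD`` may be omitted and is derived from
    the other two; if all three are given they must satisfy
    ka = kd/KD to 1e-9 relative.
    """

    ka: float | None = None
    kd: float = DEFAULT_KD_RATE
    KD: float | None = DEFAULT_KD_EQ
    nA: float = DEFAULT_NA

    def __post_init__(self) -> None:
        ka, kd, KD = self.ka, self.kd, self.KD
        if kd < 0 or self.nA < 0:
            raise DomainError("rates must be non-negative")
        if ka is None and KD is not None:
            ka = association_from_equilibrium(kd, KD)
            object.__setattr__(self, "ka", ka)
        elif KD is None and ka is not None:
            if ka > 0:
                object.__setattr__(self, "KD", kd / ka)
        if self.ka is None:
            raise DomainError("need ka, or kd and KD, to fix the rate law")
        if self.ka < 0:
            raise DomainError("ka must be non-negative")
        if self.KD is not None and self.ka > 0:
            if abs(self.ka - self.kd / self.KD) > 1e-9 * self.ka:
                raise DomainError("inconsistent ka, kd, KD (ka != kd/KD)")

    @property
    def k_off(self) -> float:
        """First-order off rate kd/nA (1/s)."""
        return self.kd / self.nA

    @classmethod
    def reference(cls) -> "BindingParams":
        """The published PhoB/DNA parameter set."""
        return cls()


def surface_rate(c, n, p: BindingParams):
    """dn/dt (mol m^-2 s^-1) of the 1:1 rate law."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    if np.any(n < 0) or np.any(n > p.nA * (1 + 1e-12)):
        raise DomainError("coverage must lie in [0, nA]")
    out = p.ka * c * (1.0 - n / p.nA) - p.kd * n / p.nA
    return float(out) if out.ndim == 0 else out


def equilibrium_coverage(c, p: BindingParams):
    """One-site isotherm n_eq = nA c / (c + KD) (mol/m^2)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise DomainError("concentration must be non-negative")
    if p.KD is None:
        raise DomainError("KD is required for the equilibrium isotherm")
    out = p.nA * c / (c + p.KD)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class InjectionSchedule:
    """Inlet concentration program: smooth ramp up, hold, smooth ramp down."""

    c_in: float
    ramp_up: float = 0.5
    hold: float = 20.0
    ramp_down: float = 0.5

    def __post_init__(self) -> None:
        if min(self.c_in, self.ramp_up, self.hold, self.ramp_down) < 0:
            raise DomainError("schedule values must be non-negative")

    @property
    def t_end(self) -> float:
        """Time at which the inlet concentration returns to zero."""
        return self.ramp_up + self.hold + self.ramp_down

    def concentration(self, t):
        """Inlet concentration at time(s) ``t`` (cosine smoothstep ramps)."""
        t = np.asarray(t, dtype=float)
        c = np.zeros_like(t)
        if self.ramp_up > 0:
            mask = (t >= 0) & (t < self.ramp_up)
            c[mask] = 0.5 * self.c_in * (1 - np.cos(np.pi * t[mask]
                                                    / self.ramp_up))
        t1 = self.ramp_up
        t2 = t1 + self.hold
        c[(t >= t1) & (t < t2)] = self.c_in
        if self.ramp_down > 0:
            mask = (t >= t2) & (t < t2 + self.ramp_down)
            c[mask] = 0.5 * self.c_in * (
                1 + np.cos(np.pi * (t[mask] - t2) / self.ramp_down)
            )
        return float(c) if c.ndim == 0 else c


@dataclass
class Sensorgram:
    """Surface-coverage time series n(t) with optional outlet concentration."""

    t: np.ndarray
    n: np.ndarray
    c_outlet: np.ndarray | None = None
    meta: dict = field(default_factory=dict)
    balance: "object | None" = None  # MassBalance from the flow-cell solver

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.c_outlet is not None:
            self.c_outlet = np.asarray(self.c_outlet, dtype=float)
            if self.c_outlet.shape != self.t.shape:
                raise DomainError("c_outlet length must match t")
        if self.t.shape != self.n.shape:
            raise DomainError("t and n must have the same length")

    def to_csv(self, path: "str | Path") -> None:
        cols = {"t": self.t, "n_mean": self.n}
        cols["c_outlet"] = (self.c_outlet if self.c_outlet is not None
                            else np.full_like(self.t, np.nan))
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: "str | Path") -> "Sensorgram":
        df = pd.read_csv(path, float_precision="round_trip")
        c_out = df["c_outlet"].to_numpy() if "c_outlet" in df else None
        return cls(t=df["t"].to_numpy(), n=df["n_mean"].to_numpy(),
                   c_outlet=c_out)


def _exact_update(n: float, c: float, p: BindingParams, dt: float) -> float:
    """Exact solution of the (linear in n) rate law over dt at constant c."""
    lam = (p.ka * c + p.kd) / p.nA
    if lam == 0.0:
        return n
    n_inf = p.ka * c / lam
    return n_inf + (n - n_inf) * np.exp(-lam * dt)


def wellmixed_sensorgram(
    schedule: InjectionSchedule,
    p: BindingParams,
    dt: float = 1e-3,
    t_total: float | None = None,
    n0: float = 0.0,
) -> Sensorgram:
    """Transport-free sensorgram: the surface sees the inlet program directly.

    Each dt sub-interval uses the exact exponential update at the
    midpoint concentration, so piecewise-constant inlet programs incur
    no truncation error at all.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    if t_total is None:
        t_total = schedule.t_end + 10.0
    n_steps = int(np.ceil(t_total / dt))
    t = np.empty(n_steps + 1)
    n = np.empty(n_steps + 1)
    t[0], n[0] = 0.0, n0
    cur = n0
    for k in range(n_steps):
        c_mid = float(schedule.concentration((k + 0.5) * dt))
        cur = _exact_update(cur, c_mid, p, dt)
        t[k + 1] = (k + 1) * dt
        n[k + 1] = cur
    return Sensorgram(t=t, n=n, meta={"model": "well-mixed",
                                      "c_in": schedule.c_in})
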