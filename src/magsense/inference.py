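"""Rate-constant recovery from sensorgrams.

kd comes from a log-linear least-squares fit of the dissociation phase
(dn/dt = -(kd/nA) n once the near-wall concentration has washed out, so
log n decays with slope -kd/nA); ka follows from ka = kd/KD; KD comes
from a one-site isotherm fit of peak coverages against inlet
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .binding import Sensorgram, association_from_equilibrium
from .errors import DomainError, NoDecayError, NonIdentifiableError


@dataclass
class RateEstimate:
    """Fitted dissociation rate with derived quantities and diagnostics."""

    kd_est: float  # mol m^-2 s^-1
    fit_window: tuple[float, float]
    r_squared: float
    ka_est: float | None = None  # m/s
    KD_est: float | None = None  # mol/m^3

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise DomainError("r_squared must lie in [0, 1]")
        if self.kd_est < 0:
            raise DomainError("estimates must be non-negative")


@dataclass
class IsothermFit:
    """One-site binding-model fit n = n_max c / (c + KD)."""

    KD_est: float
    n_max_est: float
    residual_norm: float


def default_dissociation_window(
    sensorgram: Sensorgram,
    t_injection_end: float | None = None,
    settle: float = 1.0,
    floor_frac: float = 1e-3,
) -> tuple[float, float]:
    """Default fit window: 1 s after injection end (transport washout)
    until n drops below ``floor_frac`` of its peak or the record ends."""
    t, n = sensorgram.t, sensorgram.n
    if t_injection_end is None:
        t_injection_end = sensorgram.meta.get(
            "t_injection_end", float(t[int(np.argmax(n))])
        )
    start = t_injection_end + settle
    peak = float(n.max(initial=0.0))
    below = np.where((t > start) & (n < floor_frac * peak))[0]
    end = float(t[below[0]]) if below.size else float(t[-1])
    return (start, end)


def fit_dissociation_rate(
    sensorgram: Sensorgram,
    nA: float,
    window: tuple[float, float] | None = None,
) -> RateEstimate:
    """Least-squares line on log n(t) over the window; kd = -slope * nA."""
    if nA <= 0:
        raise DomainError("nA must be positive")
    if window is None:
        window = default_dissociation_window(sensorgram)
    t0, t1 = window
    mask = (sensorgram.t >= t0) & (sensorgram.t <= t1)
    t = sensorgram.t[mask]
    n = sensorgram.n[mask]
    if t.size < 3:
        raise NoDecayError("fewer than 3 samples in the fit window")
    if np.any(n <= 0):
        raise NoDecayError("non-positive coverage inside the fit window")
    logn = np.log(n)
    if np.ptp(logn) < 1e-12:
        raise NoDecayError("no decay detected (constant signal)")
    res = stats.linregress(t, logn)
    if res.slope >= 0:
        raise NoDecayError("no decay detected")
    return RateEstimate(
        kd_est=-res.slope * nA,
        fit_window=(float(t0), float(t1)),
        r_squared=float(res.rvalue**2),
    )


def derive_ka(kd_est: float, KD: float) -> float:
    """ka = kd_est / KD (m/s)."""
    return association_from_equilibrium(kd_est, KD)


def fit_equilibrium_KD(points) -> IsothermFit:
    """Nonlinear least squares of the one-site isotherm on (c_in, n_peak).

    Initialization: n_max0 = max(n_peak), KD0 = median(c_in);
    Levenberg-style damped least squares (bounded trust region), best of
    a small p0 grid by residual.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise DomainError("points must be (m, 2): columns c_in, n_peak")
    c, n = pts[:, 0], pts[:, 1]
    if np.unique(c).size < 3:
        raise NonIdentifiableError("need >= 3 distinct concentrations")
    if np.any(n < 0) or np.any(c < 0):
        raise DomainError("concentrations and coverages must be >= 0")
    if np.ptp(n) == 0:
        raise NonIdentifiableError("all coverages equal; KD not identifiable")

    # fit on normalized variables so the optimizer sees O(1) numbers
    c_scale = float(np.median(c[c > 0])) if np.any(c > 0) else 1.0
    n_scale = float(n.max())
    cs, nn = c / c_scale, n / n_scale

    def model(cc, n_max, KD):
        return n_max * cc / (cc + KD)

    best = None
    for kd0_scale in (0.5, 1.0, 2.0):
        p0 = (1.0, kd0_scale)
        try:
            popt, _ = optimize.curve_fit(
                model, cs, nn, p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10_000,
            )
        except RuntimeError:
            continue
        resid = float(np.linalg.norm(model(cs, *popt) - nn)) * n_scale
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise NonIdentifiableError("isotherm fit did not converge")
    (n_max_n, KD_n), resid = best
    return IsothermFit(KD_est=float(KD_n * c_scale),
                       n_max_est=float(n_max_n * n_scale),
                       residual_norm=resid)
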