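"""Physical constants shared by all simulation modules.

All quantities are in SI units. ``mu0`` is pinned to its defined value;
``gamma`` (the gyromagnetic ratio used by the spin integrator) is
configurable because it is a material/model choice, not a constant of
nature at the macrospin level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError

#: Vacuum permeability (T m / A).
MU0 = 4.0e-7 * math.pi

#: Boltzmann constant (J / K).
KB = 1.380649e-23

#: Electron gyromagnetic ratio magnitude (rad / (s T)), default for macrospins.
GAMMA_E = 1.76e11


@dataclass(frozen=True)
class PhysicalConstants:
    """Bundle of physical constants used by energy and dynamics kernels.

    Parameters
    ----------
    mu0 : float
        Vacuum permeability (T m / A). Must equal the defined value.
    kB : float
        Boltzmann constant (J / K).
    gamma : float
        Gyromagnetic ratio (rad s^-1 T^-1) used for moment precession.
    """

    mu0: float = MU0
    kB: float = KB
    gamma: float = GAMMA_E

    def __post_init__(self) -> None:
        if not (self.mu0 > 0 and self.kB > 0 and self.gamma > 0):
            raise DomainError("all physical constants must be strictly positive")
        if abs(self.mu0 - MU0) > 1e-12 * MU0:
            raise DomainError(
                f"mu0 is fixed to its defined value {MU0!r}; got {self.mu0!r}"
            )
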