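"""Map magnetization to giant-magnetoresistance characteristic curves.

The granular GMR model used here is GMR(M) = A * (1 - (M/Ms)^2) with the
effect amplitude ``A`` in percent (default 20%, matched to experiment).
``M/Ms`` is the reduced total magnetization component along the applied
field axis, i.e. the quantity a field sweep measures; a magnitude-based
reading is available via ``use_magnitude`` in :func:`gmr_curve` callers
that build their own reduced series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError

#: Default GMR effect amplitude (%), matched to experimental data.
DEFAULT_AMPLITUDE = 20.0


def gmr_from_m(m_reduced, amplitude: float = DEFAULT_AMPLITUDE):
    """GMR (%) from reduced magnetization: ``amplitude * (1 - m^2)``."""
    m = np.asarray(m_reduced, dtype=float)
    if amplitude < 0:
        raise DomainError("amplitude must be >= 0")
    if np.any(np.abs(m) > 1.0 + 1e-12):
        raise DomainError("|m_reduced| must be <= 1")
    m = np.clip(m, -1.0, 1.0)
    out = amplitude * (1.0 - m * m)
    return float(out) if out.ndim == 0 else out


@dataclass
class GMRCurve:
    """GMR characteristic: field series, reduced M, GMR (%) and amplitude."""

    B: np.ndarray
    m_reduced: np.ndarray
    gmr: np.ndarray
    amplitude: float

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=float)
        self.m_reduced = np.asarray(self.m_reduced, dtype=float)
        self.gmr = np.asarray(self.gmr, dtype=float)
        if not (len(self.B) == len(self.m_reduced) == len(self.gmr)):
            raise DomainError("curve series lengths differ")


def gmr_curve(
    B,
    m_reduced,
    amplitude: float = DEFAULT_AMPLITUDE,
) -> GMRCurve:
    """Elementwise GMR of a magnetization curve, preserving field order."""
    B = np.asarray(B, dtype=float)
    m = np.asarray(m_reduced, dtype=float)
    if B.shape != m.shape:
        raise DomainError("B and m_reduced must have the same shape")
    return GMRCurve(B=B, m_reduced=m, gmr=gmr_from_m(m, amplitude),
                    amplitude=amplitude)
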