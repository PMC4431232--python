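"""Nanoparticle ensemble data structures, generators and table import.

An ensemble is a set of single-domain spherical nanoparticles, each
carrying an effective magnetic moment of magnitude ``Ms * pi * d^3 / 6``
(saturation magnetization times particle volume). Positions and moments
are stored as ``(n, 3)`` SI arrays; translational motion may be confined
to a plane (``motion_dim == 2``) while moments always rotate in 3D.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .constants import PhysicalConstants
from .errors import DomainError, ParseError, PlacementError

#: Default saturation magnetization (A/m): bulk cobalt. The carbon shell of
#: core/shell particles is treated as magnetically inert.
MS_COBALT = 1.446e6

_MOMENT_RTOL = 1e-12


def moment_magnitude(diameter: float, Ms: float) -> float:
    """Effective moment magnitude (A m^2) of a single-domain sphere.

    Parameters
    ----------
    diameter : float
        Particle diameter (m), >= 0.
    Ms : float
        Saturation magnetization (A/m), >= 0.

    Returns
    -------
    float
        ``Ms * (pi / 6) * diameter**3``.
    """
    diameter = np.asarray(diameter, dtype=float)
    Ms = np.asarray(Ms, dtype=float)
    if np.any(diameter < 0) or np.any(Ms < 0):
        raise DomainError("diameter and Ms must be non-negative")
    out = Ms * (math.pi / 6.0) * diameter**3
    return float(out) if out.ndim == 0 else out


@dataclass
class Nanoparticle:
    """A single spherical nanoparticle (view onto ensemble rows)."""

    position: np.ndarray  # (3,) m
    diameter: float  # m
    moment: np.ndarray  # (3,) A m^2

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.moment = np.asarray(self.moment, dtype=float).reshape(3)
        if self.diameter <= 0:
            raise DomainError("particle diameter must be positive")


@dataclass
class NanoparticleEnsemble:
    """Positions, diameters and moments of an interacting particle set.

    Attributes
    ----------
    positions, moments : (n, 3) float arrays, SI units.
    diameters : (n,) float array (m).
    box : (3,) extents (m); particles live in ``[0, box[k]]`` per axis.
    boundary : 'reflective' or 'periodic' (translational boundary mode).
    Ms : saturation magnetization (A/m) shared by all particles.
    temperature : heat-bath temperature (K) for stochastic dynamics.
    motion_dim : 2 (planar translation, default) or 3.
    """

    positions: np.ndarray
    diameters: np.ndarray
    moments: np.ndarray
    box: np.ndarray
    Ms: float = MS_COBALT
    temperature: float = 0.0
    motion_dim: int = 2
    boundary: str = "reflective"
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=float))
        self.diameters = np.atleast_1d(np.asarray(self.diameters, dtype=float))
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        n = self.positions.shape[0]
        if self.positions.shape != (n, 3) or self.moments.shape != (n, 3):
            raise DomainError("positions and moments must have shape (n, 3)")
        if self.diameters.shape != (n,):
            raise DomainError("diameters must have shape (n,)")
        if np.any(self.diameters <= 0):
            raise DomainError("all diameters must be positive")
        if np.any(self.box <= 0):
            raise DomainError("box extents must be positive")
        if self.temperature < 0:
            raise DomainError("temperature must be non-negative")
        if self.motion_dim not in (2, 3):
            raise DomainError("motion_dim must be 2 or 3")
        if self.boundary not in ("reflective", "periodic"):
            raise DomainError("boundary must be 'reflective' or 'periodic'")
        expected = moment_magnitude(self.diameters, self.Ms)
        got = np.linalg.norm(self.moments, axis=1)
        scale = np.maximum(np.abs(expected), 1e-300)
        if np.any(np.abs(got - expected) > _MOMENT_RTOL * scale + 1e-300):
            raise DomainError(
                "moment magnitudes must equal Ms*pi*d^3/6 (1e-12 relative)"
            )

    # -- convenience -----------------------------------------------------

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def moment_magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.moments, axis=1)

    @property
    def particles(self) -> list[Nanoparticle]:
        return [
            Nanoparticle(self.positions[i].copy(), float(self.diameters[i]),
                         self.moments[i].copy())
            for i in range(self.n)
        ]

    def copy(self) -> "NanoparticleEnsemble":
        return replace(
            self,
            positions=self.positions.copy(),
            diameters=self.diameters.copy(),
            moments=self.moments.copy(),
            box=self.box.copy(),
        )

    def with_(self, **kwargs) -> "NanoparticleEnsemble":
        return replace(self.copy(), **kwargs)

    def min_pair_distance(self) -> float:
        if self.n < 2:
            return math.inf
        return float(pdist(self.positions).min())

    def nearest_neighbor_distances(self) -> np.ndarray:
        if self.n < 2:
            return np.full(self.n, np.inf)
        d = np.linalg.norm(
            self.positions[:, None, :] - self.positions[None, :, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    def reduced_magnetization(self) -> np.ndarray:
        """Net moment divided by the saturation value sum(|m_i|)."""
        total = self.moment_magnitudes.sum()
        if total == 0:
            return np.zeros(3)
        return self.moments.sum(axis=0) / total


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_random_ensemble(
    n: int,
    box: Sequence[float],
    diameter: float = 20e-9,
    Ms: float = MS_COBALT,
    seed: int | None = None,
    motion_dim: int = 2,
    temperature: float = 0.0,
    max_attempts: int = 50_000,
) -> NanoparticleEnsemble:
    """Place ``n`` non-overlapping monodisperse particles uniformly at random.

    ``box`` may have two entries (planar sample; the out-of-plane extent is
    set to one diameter) or three. Positions keep whole spheres inside the
    box; moments get uniformly random orientations. Deterministic per seed.

    Raises
    ------
    PlacementError
        If fewer than ``n`` particles could be placed within the retry
        budget (reports the achieved count).
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if diameter <= 0:
        raise DomainError("diameter must be positive")
    box = np.asarray(box, dtype=float)
    if box.size == 2:
        box = np.array([box[0], box[1], diameter])
    if box.size != 3:
        raise DomainError("box must have 2 or 3 extents")

    rng = np.random.default_rng(seed)
    radius = diameter / 2.0
    lo = np.full(3, radius)
    hi = box - radius
    if motion_dim == 2:
        lo[2] = hi[2] = box[2] / 2.0
    if np.any(hi < lo):
        raise DomainError("box too small for the requested diameter")

    positions = np.empty((n, 3))
    placed = 0
    attempts = 0
    while placed < n:
        if attempts >= max_attempts:
            raise PlacementError(
                f"placed only {placed}/{n} particles after {max_attempts} attempts"
            )
        attempts += 1
        trial = lo + rng.random(3) * (hi - lo)
        if placed:
            d2 = np.sum((positions[:placed] - trial) ** 2, axis=1)
            if d2.min() < diameter**2:
                continue
        positions[placed] = trial
        placed += 1

    mag = moment_magnitude(diameter, Ms)
    moments = mag * _random_unit_vectors(rng, n)
    return NanoparticleEnsemble(
        positions=positions,
        diameters=np.full(n, float(diameter)),
        moments=moments,
        box=box,
        Ms=Ms,
        temperature=temperature,
        motion_dim=motion_dim,
    )


def load_positions(
    table: "str | Path | pd.DataFrame | Iterable[Sequence[float]]",
    Ms: float = MS_COBALT,
    seed: int | None = None,
    box: Sequence[float] | None = None,
    motion_dim: int = 3,
) -> NanoparticleEnsemble:
    """Build an ensemble from a particle table (e.g. a 3D reconstruction).

    Accepts a CSV path with header ``x,y,z,diameter`` (meters), a
    DataFrame with those columns, or an iterable of 4-tuples. Moments are
    initialized with random orientations (per ``seed``) and magnitudes
    from :func:`moment_magnitude`. Overlapping records produce a warning,
    not an error — imaged particles may touch.
    """
    if isinstance(table, (str, Path)):
        df = pd.read_csv(table, float_precision="round_trip")
    elif isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.DataFrame(list(table), columns=["x", "y", "z", "diameter"])

    required = ["x", "y", "z", "diameter"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"particle table missing columns: {missing}")
    if len(df) == 0:
        raise ParseError("no particles in table")

    vals = df[required].to_numpy()
    bad = np.where(~np.isfinite(vals).all(axis=1) | (vals[:, 3] <= 0))[0]
    if bad.size:
        raise ParseError(f"malformed particle record at row {int(bad[0])}")

    positions = vals[:, :3].astype(float)
    diameters = vals[:, 3].astype(float)

    contact = 0.5 * (diameters[:, None] + diameters[None, :])
    if len(df) > 1:
        dist = np.linalg.norm(
            positions[:, None, :] - positions[None, :, :], axis=-1
        )
        iu = np.triu_indices(len(df), k=1)
        if np.any(dist[iu] < 0.95 * contact[iu]):
            warnings.warn("particle table contains overlapping records",
                          stacklevel=2)

    if box is None:
        span = positions.max(axis=0) + diameters.max()
        box = np.maximum(span, diameters.max())
    rng = np.random.default_rng(seed)
    moments = moment_magnitude(diameters, Ms)[:, None] * _random_unit_vectors(
        rng, len(df)
    )
    return NanoparticleEnsemble(
        positions=positions,
        diameters=diameters,
        moments=moments,
        box=np.asarray(box, dtype=float),
        Ms=Ms,
        motion_dim=motion_dim,
    )


def write_positions(ensemble: NanoparticleEnsemble, path: "str | Path") -> None:
    """Write the ``x,y,z,diameter`` particle table (SI units, CSV)."""
    df = pd.DataFrame(
        {
            "x": ensemble.positions[:, 0],
            "y": ensemble.positions[:, 1],
            "z": ensemble.positions[:, 2],
            "diameter": ensemble.diameters,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
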