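"""Writers/readers for trajectories, curves and run metadata.

All floats are written with 17 significant digits so CSV round-trips are
bit-faithful. Snapshot format is extended XYZ: ``x y z mx my mz d`` per
particle, SI units, with the time and box in the comment line.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import NanoparticleEnsemble
from .errors import ParseError
from .spin_dynamics import Trajectory

FLOAT_FMT = "%.17g"


def write_xyz_frame(fh, positions, moments, diameters, comment: str) -> None:
    fh.write(f"{len(positions)}\n")
    fh.write(comment.replace("\n", " ") + "\n")
    for p, m, d in zip(positions, moments, diameters):
        fh.write(
            " ".join(FLOAT_FMT % v for v in (*p, *m, d)) + "\n"
        )


def write_trajectory_xyz(traj: Trajectory, path: "str | Path") -> None:
    """All recorded snapshots as concatenated extended-XYZ frames."""
    ens = traj.final_ensemble
    diameters = ens.diameters if ens is not None else np.zeros(
        traj.moments.shape[1])
    with open(path, "w") as fh:
        for k, t in enumerate(traj.times):
            pos = (traj.positions[k] if traj.positions is not None
                   else (ens.positions if ens is not None
                         else np.zeros_like(traj.moments[k])))
            write_xyz_frame(fh, pos, traj.moments[k], diameters,
                            comment=f"t={FLOAT_FMT % t}")


def write_ensemble_xyz(ens: NanoparticleEnsemble, path: "str | Path",
                       comment: str = "") -> None:
    with open(path, "w") as fh:
        write_xyz_frame(fh, ens.positions, ens.moments, ens.diameters,
                        comment or "magsense snapshot")


def read_xyz_frames(path: "str | Path"):
    """Parse extended-XYZ frames -> list of (positions, moments, diameters)."""
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        try:
            count = int(lines[i])
        except ValueError as exc:
            raise ParseError(f"bad frame header at line {i + 1}") from exc
        rows = lines[i + 2: i + 2 + count]
        if len(rows) < count:
            raise ParseError("truncated XYZ frame")
        data = np.array([[float(v) for v in r.split()] for r in rows])
        if data.shape[1] != 7:
            raise ParseError("expected 7 columns: x y z mx my mz d")
        frames.append((data[:, :3], data[:, 3:6], data[:, 6]))
        i += 2 + count
    return frames


def write_trajectory_csv(traj: Trajectory, path: "str | Path") -> None:
    """Per-sample energy breakdown and magnetization."""
    df = pd.DataFrame(
        {
            "t": traj.times,
            "E_dipolar": [e.dipolar for e in traj.energies],
            "E_wca": [e.wca for e in traj.energies],
            "E_zeeman": [e.zeeman for e in traj.energies],
            "Mx": traj.magnetization[:, 0],
            "My": traj.magnetization[:, 1],
            "Mz": traj.magnetization[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_gmr_csv(curve, path: "str | Path") -> None:
    pd.DataFrame(
        {"B": curve.B, "m_reduced": curve.m_reduced,
         "gmr_percent": curve.gmr}
    ).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_gmr_csv(path: "str | Path"):
    df = pd.read_csv(path, float_precision="round_trip")
    return df["B"].to_numpy(), df["m_reduced"].to_numpy(), \
        df["gmr_percent"].to_numpy()


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_metadata(path: "str | Path", config: dict, seed: int | None,
                   extras: dict | None = None) -> None:
    """Run-metadata JSON: config hash, seed, library versions."""
    from . import __version__

    meta = {
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {"magsense": __version__, "numpy": np.__version__},
    }
    if extras:
        meta.update(extras)
    Path(path).write_text(json.dumps(meta, indent=2, default=float) + "\n")
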