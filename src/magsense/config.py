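"""Run-configuration parsing and validation.

Configs are YAML key-value files with one block per subsystem; every
physical quantity is plain SI. Unknown keys are rejected (they are
almost always typos of real keys), missing keys take documented
defaults, and derivable quantities (ka from kd and KD) are filled in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

# section -> {key: default}; None means "no default, optional"
SCHEMA: dict[str, dict] = {
    "ensemble": {
        "n": 192,
        "box": [350e-9, 350e-9],
        "diameter": 20e-9,
        "Ms": 1.446e6,
        "motion_dim": 2,
        "temperature": 0.0,
        "positions_csv": None,
    },
    "wca": {"epsilon": None, "sigma": None},
    "sd": {"alpha": 0.1, "dt": 1e-13, "gamma": 1.76e11},
    "md": {"dt": 1e-10, "drag": None, "temperature": 298.0, "eta": 1e-3},
    "schedule": {"total_steps": 200_000, "sd_every": 10_000,
                 "sd_budget": 20_000},
    "demag": {"B0": 0.05, "n_oscillations": 30, "azimuthal_turns": 7,
              "polar_turns": 3, "duration": 1e-7,
              "damping_shape": "linear"},
    "sweep": {"B_max": 0.05, "n_steps": 21, "axis": [1.0, 0.0, 0.0],
              "mode": "loop", "steps_per_field": 2000},
    "gmr": {"amplitude": 20.0},
    "flowcell": {
        "length": 2400e-6, "width": 500e-6, "height": 20e-6,
        "nx": 120, "nz": 30, "grading": 1.15,
        "D": 1e-10, "eta": 1e-3, "u_mean": 3.3e-2,
        "dt": None, "t_total": None, "record_dt": 0.01,
    },
    "injection": {"c_in": 20e-3, "ramp_up": 0.5, "hold": 20.0,
                  "ramp_down": 0.5},
    "binding": {"ka": None, "kd": 1.5e-8, "KD": 21e-3, "nA": 2.56e-8},
    "inference": {"window": None, "nA": 2.56e-8},
    "run": {"seed": 0, "relax_tol": 1e-24},
}

_POSITIVE = {
    ("ensemble", "n"), ("ensemble", "diameter"), ("ensemble", "Ms"),
    ("sd", "dt"), ("sd", "gamma"), ("md", "dt"),
    ("schedule", "total_steps"), ("schedule", "sd_every"),
    ("flowcell", "length"), ("flowcell", "width"), ("flowcell", "height"),
    ("flowcell", "D"), ("flowcell", "eta"),
    ("binding", "nA"),
}


@dataclass
class RunConfig:
    """Validated configuration; sections behave like attribute dicts."""

    sections: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> dict:
        return self.sections[name]

    def get(self, section: str, key: str):
        return self.sections[section][key]

    def as_dict(self) -> dict:
        return {k: dict(v) for k, v in self.sections.items()}


def _validate(raw: dict) -> dict:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    out: dict[str, dict] = {}
    for section, value in raw.items():
        if section not in SCHEMA:
            raise ConfigError(f"unknown config section '{section}'")
        if not isinstance(value, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        for key in value:
            if key not in SCHEMA[section]:
                raise ConfigError(
                    f"unknown key '{key}' in section '{section}'"
                )
    for section, defaults in SCHEMA.items():
        merged = dict(defaults)
        merged.update(raw.get(section, {}))
        out[section] = merged
    for section, key in _POSITIVE:
        v = out[section][key]
        if v is not None and not (isinstance(v, (int, float)) and v > 0):
            raise ConfigError(f"'{section}.{key}' must be positive, got {v!r}")
    b = out["binding"]
    if b["ka"] is None and b["kd"] is not None and b["KD"]:
        b["ka"] = b["kd"] / b["KD"]
    return out


def read_config(path: "str | Path") -> RunConfig:
    """Parse and validate a YAML run configuration."""
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse config: {exc}") from exc
    return RunConfig(sections=_validate(raw))


def default_config() -> RunConfig:
    return RunConfig(sections=_validate({}))


def write_config(config: RunConfig, path: "str | Path") -> None:
    Path(path).write_text(
        yaml.safe_dump(config.as_dict(), sort_keys=True)
    )
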