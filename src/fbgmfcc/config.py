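"""Run configuration: structured-text (INI) parsing with strict validation.

A config file has sections [system], [backend], [mm], [dynamics],
[restraints], [output]; unknown sections or keys are rejected before any
computation starts, so a typo cannot silently change a run.
"""

from __future__ import annotations

import configparser
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

_SCHEMA: dict[str, dict[str, type]] = {
    "system": {
        "source": str,  # builder | pdb
        "sequence": str,
        "n_cap": str,
        "c_cap": str,
        "geometry": str,
        "pdb_path": str,
        "n_waters": int,
        "solvent_seed": int,
    },
    "backend": {
        "type": str,  # mock
        "cap_transparent": bool,
        "parallel_width": int,
    },
    "mm": {
        "bond_k": float,
        "angle_k": float,
    },
    "dynamics": {
        "ensemble": str,  # nve | langevin | heating
        "dt": float,
        "steps": int,
        "temperature": float,
        "gamma": float,
        "seed": int,
        "balance_mode": str,  # paper | chain_rule | none
        "initial_temperature": float,
        "heating_schedule": str,  # "duration_fs:targetT,..."
        "include_twobody": bool,
    },
    "restraints": {
        "backbone_k": float,
        "boundary_k": float,
        "boundary_radius": float,
    },
    "output": {
        "trajectory": str,
        "energy_log": str,
        "checkpoint": str,
        "stride": int,
    },
}

_DEFAULTS = {
    "system": {"source": "builder", "sequence": "AAAAAAAAA", "n_cap": "ACE",
               "c_cap": "NME", "geometry": "extended", "pdb_path": "",
               "n_waters": 0, "solvent_seed": 0},
    "backend": {"type": "mock", "cap_transparent": False, "parallel_width": 1},
    "mm": {"bond_k": 300.0, "angle_k": 50.0},
    "dynamics": {"ensemble": "nve", "dt": 1.0, "steps": 100,
                 "temperature": 300.0, "gamma": 2.0, "seed": 1,
                 "balance_mode": "paper", "initial_temperature": 300.0,
                 "heating_schedule": "", "include_twobody": True},
    "restraints": {"backbone_k": 0.0, "boundary_k": 0.0,
                   "boundary_radius": 0.0},
    "output": {"trajectory": "", "energy_log": "", "checkpoint": "",
               "stride": 10},
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    sections: dict[str, dict] = field(default_factory=dict)
    source_text: str = ""

    def __getitem__(self, section: str) -> dict:
        return self.sections[section]

    @property
    def digest(self) -> str:
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:12]

    def validate(self) -> None:
        sys_cfg = self.sections["system"]
        if sys_cfg["source"] not in ("builder", "pdb"):
            raise ConfigError(f"system.source must be builder|pdb, "
                              f"got {sys_cfg['source']!r}")
        if sys_cfg["source"] == "pdb" and not sys_cfg["pdb_path"]:
            raise ConfigError("system.source=pdb requires system.pdb_path")
        dyn = self.sections["dynamics"]
        if dyn["ensemble"] not in ("nve", "langevin", "heating"):
            raise ConfigError(f"unknown ensemble {dyn['ensemble']!r}")
        if dyn["balance_mode"] not in ("paper", "chain_rule", "none"):
            raise ConfigError(f"unknown balance_mode {dyn['balance_mode']!r}")
        if dyn["dt"] <= 0:
            raise ConfigError("dynamics.dt must be > 0")
        if dyn["steps"] < 0:
            raise ConfigError("dynamics.steps must be >= 0")
        if self.sections["backend"]["type"] != "mock":
            raise ConfigError("only the 'mock' backend is configurable from "
                              "file; external engines are driven via the API")
        if dyn["ensemble"] == "heating" and not dyn["heating_schedule"]:
            raise ConfigError("heating ensemble requires heating_schedule")

    def heating_schedule(self) -> list[tuple[float, float]]:
        out = []
        text = self.sections["dynamics"]["heating_schedule"]
        for part in text.split(","):
            if not part.strip():
                continue
            dur, _, target = part.partition(":")
            out.append((float(dur), float(target)))
        return out


def _coerce(value: str, typ: type, where: str):
    if typ is bool:
        v = value.strip().lower()
        if v in ("true", "yes", "1", "on"):
            return True
        if v in ("false", "no", "0", "off"):
            return False
        raise ConfigError(f"{where}: expected boolean, got {value!r}")
    try:
        return typ(value)
    except ValueError:
        raise ConfigError(f"{where}: expected {typ.__name__}, "
                          f"got {value!r}") from None


def load_config(path_or_text) -> RunConfig:
    """Parse and fully validate a run configuration."""
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        text = path_or_text
    else:
        text = Path(path_or_text).read_text()
    parser = configparser.ConfigParser(interpolation=None)
    parser.optionxform = str
    try:
        parser.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"unparseable config: {exc}") from None

    sections = {name: dict(vals) for name, vals in _DEFAULTS.items()}
    for sec in parser.sections():
        if sec not in _SCHEMA:
            raise ConfigError(f"unknown section [{sec}]")
        for key, raw in parser[sec].items():
            if key not in _SCHEMA[sec]:
                raise ConfigError(f"unknown key {key!r} in section [{sec}]")
            sections[sec][key] = _coerce(raw, _SCHEMA[sec][key],
                                         f"[{sec}] {key}")
    cfg = RunConfig(sections=sections, source_text=text)
    cfg.validate()
    return cfg
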