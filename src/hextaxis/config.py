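"""Configuration serialization: YAML/JSON round-trip and dotted overrides.

A config document mirrors :class:`~hextaxis.engine.SimulationConfig`; an
empty document reproduces the default model exactly (all printed reaction
probabilities and energy parameters).  Ligand specs are written with
receptor-type names as multiplier keys::

    energy: {g0: -600.0, ej: -700.0}
    ligands:
      - {name: MeAsp, kd_active: 1.2e-05, kd_inactive: 1.7e-06,
         multipliers: {Tar: 1.0}}
    schedule:
      - [30000, MeAsp, 4.0e-06]

Dotted-path overrides (``reactions.chey_chez=0``) address any scalar key.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .engine import LigandSchedule, SimulationConfig
from .receptor_field import TAR, TSR, EnergyParams, LigandSpec
from .soluble_agents import ReactionTable

__all__ = ["config_to_dict", "config_from_dict", "load_config",
           "save_config", "apply_overrides", "ConfigError"]

_RTYPE_BY_NAME = {"Tar": TAR, "Tsr": TSR}
_NAME_BY_RTYPE = {v: k for k, v in _RTYPE_BY_NAME.items()}


class ConfigError(ValueError):
    """Malformed configuration; the message names the offending key."""


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["energy"] = dataclasses.asdict(config.energy)
    d["reactions"] = dataclasses.asdict(config.reactions)
    d["ligands"] = [
        {"name": s.name, "kd_active": s.kd_active,
         "kd_inactive": s.kd_inactive,
         "multipliers": {_NAME_BY_RTYPE[rt]: mult
                         for rt, mult in s.multipliers.items()}}
        for s in config.ligands]
    d["schedule"] = [list(c) for c in config.schedule.changes]
    return d


def _build(cls, data: dict, context: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    bad = set(data) - valid
    if bad:
        raise ConfigError(f"unknown key {context}.{sorted(bad)[0]}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data or {})
    kw: dict = {}
    if "energy" in data:
        kw["energy"] = _build(EnergyParams, data.pop("energy"), "energy")
    if "reactions" in data:
        kw["reactions"] = _build(ReactionTable, data.pop("reactions"),
                                 "reactions")
    if "ligands" in data:
        specs = []
        for entry in data.pop("ligands"):
            entry = dict(entry)
            mult = entry.pop("multipliers", {})
            try:
                entry["multipliers"] = {_RTYPE_BY_NAME[k]: float(v)
                                        for k, v in mult.items()}
            except KeyError as exc:
                raise ConfigError(
                    f"ligands.multipliers: unknown receptor type {exc}")
            specs.append(_build(LigandSpec, entry, "ligands"))
        kw["ligands"] = specs
    if "schedule" in data:
        raw = data.pop("schedule")
        try:
            changes = [(int(it), str(sp), float(c)) for it, sp, c in raw]
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid schedule entry: {exc}") from exc
        kw["schedule"] = LigandSchedule(changes)
    kw.update(data)
    return _build(SimulationConfig, kw, "config")


def load_config(path) -> SimulationConfig:
    """Read a YAML (or JSON: YAML is a superset) config document."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    p = Path(path)
    d = config_to_dict(config)
    if p.suffix == ".json":
        p.write_text(json.dumps(d, indent=2))
    else:
        p.write_text(yaml.safe_dump(d, sort_keys=False))


def apply_overrides(config: SimulationConfig,
                    overrides: list[str]) -> SimulationConfig:
    """Apply ``key=value`` / ``section.key=value`` overrides to a config."""
    data = config_to_dict(config)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} is not key=value")
        key, _, raw = item.partition("=")
        value = yaml.safe_load(raw)
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            if not isinstance(node.get(part), dict):
                raise ConfigError(f"unknown config section {part!r}")
            node = node[part]
        if parts[-1] not in node:
            raise ConfigError(f"unknown config key {key!r}")
        node[parts[-1]] = value
    return config_from_dict(data)
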