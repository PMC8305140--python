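"""Configuration loading, validation and serialization.

Configurations are plain nested dataclasses (:class:`SimulationConfig`
with nested geometry, fate and force parameter blocks).  Files may be
JSON or TOML; keys mirror the dataclass fields, unknown keys are
rejected with the full list of offending names, and omitted keys fall
back to the defaults.  Round-tripping a config through
:func:`save_config`/:func:`load_config` is lossless.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .fate import FateParams
from .mechanics import ForceParams
from .runtime import GeometryParams, SimulationConfig

__all__ = ["load_config", "save_config", "config_to_dict", "config_from_dict"]

_NESTED = {
    "geometry": GeometryParams,
    "fate": FateParams,
    "forces": ForceParams,
}


class ConfigError(ValueError):
    """Invalid configuration file."""


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Nested plain-dict representation of a configuration."""
    return dataclasses.asdict(cfg)


def _build(cls, data: dict, path: str) -> object:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - names)
    if unknown:
        raise ConfigError(
            f"unknown configuration key(s) under '{path}': {unknown}")
    kwargs = {}
    for key, value in data.items():
        sub = _NESTED.get(key)
        if sub is not None and cls is SimulationConfig:
            if not isinstance(value, dict):
                raise ConfigError(f"'{path}{key}' must be a table/object")
            kwargs[key] = _build(sub, value, f"{path}{key}.")
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration under '{path}': {exc}") from exc


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated SimulationConfig from a nested dict."""
    return _build(SimulationConfig, data, "")


def load_config(path: str | Path) -> SimulationConfig:
    """Load a JSON or TOML configuration file.

    An empty file yields the full default configuration.  Validation
    failures list every offending key.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return SimulationConfig()
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a table/object")
    return config_from_dict(data)


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as JSON (lossless round-trip)."""
    Path(path).write_text(json.dumps(config_to_dict(cfg), indent=2) + "\n")
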