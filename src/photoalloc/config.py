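"""YAML configuration: constants, species, environments, temperature.

A configuration file is a single YAML document with up to four sections.
Anything omitted falls back to the shipped defaults (Table-of-constants
values, the four archetype species, the evolutionary and growth
environment presets and the default temperature responses); provenance of
every constant (default vs user) is recorded for reporting.  Unknown keys
are rejected rather than silently ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml

from .errors import ConfigError, ValidationError
from .params import (
    ArrheniusEntry,
    Environment,
    SpeciesParams,
    StoichiometryConstants,
    TEMPERATURE_QUANTITIES,
    default_environments,
    default_species,
    default_temperature_params,
)

_SECTIONS = {"constants", "species", "environments", "temperature"}

_SPECIES_KEYS = {
    "ptype",
    "beta",
    "k_ccat",
    "xi",
    "K_p",
    "g_s",
    "bounds",
    "ca_over_ci",
    "n_Rubisco",
    "n_fit",
}
_SPECIES_REQUIRED = ("ptype", "beta", "k_ccat", "xi", "K_p", "g_s")
_ENV_KEYS = {"I", "T", "C_m", "O", "N_t", "C_a"}
_TEMP_KEYS = {"k25", "E", "H", "S"}


@dataclass(frozen=True)
class Config:
    constants: StoichiometryConstants
    species: dict
    environments: dict
    temperature: dict
    provenance: dict


def _check_keys(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _parse_species(name: str, raw: dict) -> SpeciesParams:
    _check_keys(raw, _SPECIES_KEYS, f"species {name!r}")
    missing = [k for k in _SPECIES_REQUIRED if k not in raw]
    if missing:
        raise ConfigError(
            f"species {name!r} is missing required fields: {missing}"
        )
    kwargs = {k: v for k, v in raw.items() if k != "bounds"}
    bounds = raw.get("bounds", {})
    if bounds:
        kwargs["allocation_bounds"] = {
            k: (float(v[0]), float(v[1])) for k, v in bounds.items()
        }
    try:
        return SpeciesParams(label=name, **kwargs)
    except ValidationError as exc:
        raise ConfigError(f"species {name!r}: {exc}") from exc


def _parse_environment(name: str, raw: dict) -> Environment:
    _check_keys(raw, _ENV_KEYS, f"environment {name!r}")
    try:
        return Environment(**raw)
    except (ValidationError, TypeError) as exc:
        raise ConfigError(f"environment {name!r}: {exc}") from exc


def _parse_temperature(raw: dict) -> dict:
    entries = default_temperature_params()
    _check_keys(raw, set(TEMPERATURE_QUANTITIES), "temperature section")
    for name, spec in raw.items():
        _check_keys(spec, _TEMP_KEYS, f"temperature entry {name!r}")
        merged = {"k25": 1.0, "E": 0.0, "H": math.inf, "S": 0.0}
        merged.update(spec)
        if isinstance(merged["H"], str):
            if merged["H"] not in ("inf", ".inf", "Infinity"):
                raise ConfigError(f"temperature entry {name!r}: bad H value")
            merged["H"] = math.inf
        try:
            entries[name] = ArrheniusEntry(**merged)
        except ValidationError as exc:
            raise ConfigError(f"temperature entry {name!r}: {exc}") from exc
    return entries


def load_config(path: str | Path | None = None) -> Config:
    """Load a YAML configuration, merged over the shipped defaults.

    ``path=None`` or an empty file yields the pure defaults: Table-of-
    constants values, the four archetype species and the evolutionary plus
    growth environment presets.
    """
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration must be a YAML mapping")
    _check_keys(raw, _SECTIONS, "configuration")

    const_raw = raw.get("constants", {}) or {}
    valid_const = {f.name for f in fields(StoichiometryConstants)}
    _check_keys(const_raw, valid_const, "constants section")
    try:
        constants = StoichiometryConstants(**const_raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
    provenance = {
        name: ("user" if name in const_raw else "default")
        for name in valid_const
    }

    species = default_species()
    for name, spec in (raw.get("species", {}) or {}).items():
        species[name] = _parse_species(name, spec)

    environments = default_environments()
    for name, spec in (raw.get("environments", {}) or {}).items():
        environments[name] = _parse_environment(name, spec)

    temperature = _parse_temperature(raw.get("temperature", {}) or {})
    return Config(
        constants=constants,
        species=species,
        environments=environments,
        temperature=temperature,
        provenance=provenance,
    )


def save_config(config: Config, path: str | Path) -> None:
    """Serialize a configuration so that ``load_config`` reproduces it."""
    doc = {
        "constants": {
            f.name: getattr(config.constants, f.name)
            for f in fields(StoichiometryConstants)
        },
        "species": {
            name: {
                "ptype": sp.ptype,
                "beta": sp.beta,
                "k_ccat": sp.k_ccat,
                "xi": sp.xi,
                "K_p": sp.K_p,
                "g_s": sp.g_s,
                "ca_over_ci": sp.ca_over_ci,
                "bounds": {
                    k: [v[0], v[1]] for k, v in sp.allocation_bounds.items()
                },
                **({"n_Rubisco": sp.n_Rubisco} if sp.n_Rubisco is not None else {}),
                **({"n_fit": sp.n_fit} if sp.n_fit is not None else {}),
            }
            for name, sp in config.species.items()
        },
        "environments": {
            name: {
                "I": env.I,
                "T": env.T,
                "O": env.O,
                "N_t": env.N_t,
                **({"C_m": env.C_m} if env.C_m is not None else {}),
                **({"C_a": env.C_a} if env.C_a is not None else {}),
            }
            for name, env in config.environments.items()
        },
        "temperature": {
            name: {
                "k25": entry.k25,
                "E": entry.E,
                "H": "inf" if math.isinf(entry.H) else entry.H,
                "S": entry.S,
            }
            for name, entry in config.temperature.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
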