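"""Configuration files and experiment presets.

Simulations are described by a YAML (or JSON) mapping; every key is
optional and defaults to the standard study conditions (0.0144 s timestep,
50,000 steps, the [-2, 2] x [-2, 2] mm domain, the measured swimming
constants, the calibrated cascade parameter set).  Unknown keys are
rejected by name so typos cannot silently fall back to defaults.

Named presets reproduce the package's main experiments:

* ``shallow_gradient`` / ``intermediate_gradient`` / ``steep_gradient`` —
  100 cells spanning eight protein-scaling values beta in a single MeAsp
  bump of steepness d = 10 / 1 / 0.1;
* ``two_ligand_competition`` — 50 cells between a MeAsp bump at (-1, 0)
  and a serine bump at (+1, 0).
"""

from __future__ import annotations

import dataclasses
from typing import Any, Dict, Mapping, Optional

import yaml

from .cascade import CascadeParams, ReceptorSpec
from .engine import SimulationConfig
from .fields import (ConstantFieldSpec, ExponentialFieldSpec,
                     TwoLigandFieldSpec, two_ligand_field)
from .kinematics import KinematicSpec
from .motor import MotorSpec

__all__ = ["ConfigError", "load_config", "config_to_dict", "PRESETS"]

BETA_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)

PRESETS: Dict[str, Dict[str, Any]] = {
    "shallow_gradient": {
        "n_cells": 100, "beta_values": list(BETA_LADDER),
        "field": {"type": "exponential", "l0_mM": 0.1, "d": 10.0},
    },
    "intermediate_gradient": {
        "n_cells": 100, "beta_values": list(BETA_LADDER),
        "field": {"type": "exponential", "l0_mM": 0.1, "d": 1.0},
    },
    "steep_gradient": {
        "n_cells": 100, "beta_values": list(BETA_LADDER),
        "field": {"type": "exponential", "l0_mM": 0.1, "d": 0.1},
    },
    "two_ligand_competition": {
        "n_cells": 50,
        "field": {"type": "two_ligand", "omega": 1.0, "upsilon": 0.0025},
    },
}


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


def _check_keys(mapping: Mapping[str, Any], allowed, context: str) -> None:
    for key in mapping:
        if key not in allowed:
            raise ConfigError(f"unknown key {key!r} in {context}")


def _build_field(spec: Mapping[str, Any]):
    kind = spec.get("type", "exponential")
    if kind == "exponential":
        _check_keys(spec, {"type", "l0_mM", "d", "center", "scaling",
                           "species"}, "field")
        return ExponentialFieldSpec(
            l0=float(spec.get("l0_mM", 0.1)), d=float(spec.get("d", 1.0)),
            center=tuple(spec.get("center", (0.0, 0.0))),
            scaling=float(spec.get("scaling", 1.0)),
            species=spec.get("species", "MeAsp"))
    if kind == "constant":
        _check_keys(spec, {"type", "level_mM", "species"}, "field")
        return ConstantFieldSpec(level=float(spec.get("level_mM", 0.1)),
                                 species=spec.get("species", "MeAsp"))
    if kind == "two_ligand":
        _check_keys(spec, {"type", "omega", "upsilon", "l_a0", "l_s0",
                           "x_a", "x_s", "d"}, "field")
        return two_ligand_field(
            omega=float(spec.get("omega", 1.0)),
            upsilon=float(spec.get("upsilon", 0.0025)),
            l_a0=float(spec.get("l_a0", 0.1)),
            l_s0=float(spec.get("l_s0", 0.1)),
            x_a=float(spec.get("x_a", 1.0)),
            x_s=float(spec.get("x_s", -1.0)),
            d=float(spec.get("d", 1.0)))
    raise ConfigError(f"unknown field type {kind!r}")


def _build_dataclass(cls, spec: Mapping[str, Any], context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(spec, names, context)
    kwargs = dict(spec)
    if cls is KinematicSpec and "domain" in kwargs:
        kwargs["domain"] = tuple(tuple(pair) for pair in kwargs["domain"])
    return cls(**kwargs)


def _build_cascade(spec: Mapping[str, Any]) -> CascadeParams:
    names = {f.name for f in dataclasses.fields(CascadeParams)}
    _check_keys(spec, names, "cascade")
    kwargs = dict(spec)
    if "receptor" in kwargs:
        kwargs["receptor"] = _build_dataclass(ReceptorSpec, kwargs["receptor"],
                                              "cascade.receptor")
    return CascadeParams(**kwargs)


_TOP_KEYS = {"preset", "n_cells", "n_steps", "dt", "master_seed",
             "record_stride", "init_adaptation", "paired_init",
             "beta_values", "field", "motor", "kinematics", "cascade"}


def load_config(path_or_mapping) -> SimulationConfig:
    """Build a fully validated :class:`SimulationConfig`.

    Accepts a file path (YAML/JSON) or an already-parsed mapping.  An empty
    file yields the all-defaults configuration; a ``preset`` key merges the
    named preset underneath any explicitly given keys.
    """
    if isinstance(path_or_mapping, Mapping):
        raw: Dict[str, Any] = dict(path_or_mapping)
    else:
        with open(path_or_mapping) as fh:
            loaded = yaml.safe_load(fh)
        raw = {} if loaded is None else dict(loaded)
    _check_keys(raw, _TOP_KEYS, "config")

    preset = raw.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
        merged = dict(PRESETS[preset])
        merged.update(raw)
        raw = merged

    kwargs: Dict[str, Any] = {}
    for key in ("n_cells", "n_steps", "master_seed", "record_stride"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "dt" in raw:
        kwargs["dt"] = float(raw["dt"])
    if "init_adaptation" in raw:
        kwargs["init_adaptation"] = raw["init_adaptation"]
    if "paired_init" in raw:
        kwargs["paired_init"] = bool(raw["paired_init"])
    if "beta_values" in raw:
        kwargs["beta_values"] = tuple(float(b) for b in raw["beta_values"])
    if "field" in raw:
        kwargs["field"] = _build_field(raw["field"])
    if "motor" in raw:
        kwargs["motor"] = _build_dataclass(MotorSpec, raw["motor"], "motor")
    if "kinematics" in raw:
        kwargs["kinematics"] = _build_dataclass(KinematicSpec,
                                                raw["kinematics"], "kinematics")
    if "cascade" in raw:
        kwargs["cascade"] = _build_cascade(raw["cascade"])
    try:
        return SimulationConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc


def config_to_dict(config: SimulationConfig) -> Dict[str, Any]:
    """Round-trippable plain-dict echo of a config (for manifests)."""

    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [encode(v) for v in obj]
        return obj

    out = encode(config)
    out["field"] = {"class": type(config.field).__name__, **out["field"]}
    return out
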