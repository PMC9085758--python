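"""Run configuration: schema validation and unit normalization.

Configs are YAML.  Every kinetic value may be a bare number (already in
the internal unit system: um, s, uM and their compounds) or a mapping
``{value: .., unit: .., provenance: ..}``; units are converted at load and
provenance `placeholder` entries are collected so a run can log which
constants are physiological placeholders rather than measured values.

A seed is mandatory whenever the chosen model contains stochastic
modules (endocytotic pit formation, Brownian vesicle motion, chance
state changes).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from mesocell.integrator import ControllerConfig
from mesocell.models import (CompartmentParams, EndocytosisModelParams,
                             FullModelParams, PhosphoParams)

__all__ = ["RunConfig", "ConfigurationError", "load_config", "convert_unit",
           "config_hash", "MODEL_PARAMS", "STOCHASTIC_MODELS"]


class ConfigurationError(ValueError):
    """Schema violation; message lists every failing field."""


# multiplicative factors into the internal system (um / s / uM)
_UNIT_FACTORS = {
    None: 1.0, "": 1.0,
    # concentration
    "uM": 1.0, "nM": 1e-3, "mM": 1e3, "M": 1e6,
    # time
    "s": 1.0, "ms": 1e-3, "min": 60.0, "h": 3600.0,
    # length
    "um": 1.0, "nm": 1e-3, "mm": 1e3,
    # rates
    "1/s": 1.0, "s^-1": 1.0, "1/min": 1.0 / 60.0,
    "uM/s": 1.0, "nM/s": 1e-3, "uM/min": 1.0 / 60.0,
    "1/(uM*s)": 1.0, "uM^-1 s^-1": 1.0, "1/(nM*s)": 1e3, "1/(mM*s)": 1e-3,
    "um^2/s": 1.0, "um/s": 1.0, "nm/s": 1e-3,
    "1/(s*um^2)": 1.0, "uM*um": 1.0,
}

MODEL_PARAMS = {
    "phospho": PhosphoParams,
    "compartment": CompartmentParams,
    "endocytosis": EndocytosisModelParams,
    "full_activation": FullModelParams,
    "full_recycling": FullModelParams,
}

STOCHASTIC_MODELS = {"endocytosis", "full_activation", "full_recycling"}


def convert_unit(value: float, unit: str | None) -> float:
    if unit not in _UNIT_FACTORS:
        raise ConfigurationError(f"unknown unit {unit!r}")
    return float(value) * _UNIT_FACTORS[unit]


@dataclass
class RunConfig:
    """Fully resolved run configuration (internal units)."""

    model: str
    params: object
    duration: float = 300.0
    seed: int | None = None
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    out_dir: str = "out"
    observe_every: float = 1.0
    placeholders: list[str] = field(default_factory=list)
    raw: dict = field(default_factory=dict)


def _resolve_value(name: str, raw, errors: list[str],
                   placeholders: list[str]):
    if isinstance(raw, dict):
        if "value" not in raw:
            errors.append(f"{name}: mapping without 'value'")
            return None
        if raw.get("provenance") == "placeholder":
            placeholders.append(name)
        try:
            return convert_unit(raw["value"], raw.get("unit"))
        except ConfigurationError as e:
            errors.append(f"{name}: {e}")
            return None
    return raw


def _build_params(cls, entries: dict, errors: list[str],
                  placeholders: list[str], prefix: str = "params."):
    names = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, raw in (entries or {}).items():
        if key not in names:
            errors.append(f"{prefix}{key}: unknown field for {cls.__name__}")
            continue
        if dataclasses.is_dataclass(names[key].type) or key == "phospho":
            kwargs[key] = _build_params(PhosphoParams, raw, errors,
                                        placeholders, prefix=f"{prefix}{key}.")
            continue
        val = _resolve_value(prefix + key, raw, errors, placeholders)
        if val is not None:
            if isinstance(getattr(cls, "__dataclass_fields__")[key].default,
                          tuple) and isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse, validate, and unit-normalize a model configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    errors: list[str] = []
    placeholders: list[str] = []

    model = raw.get("model")
    if model not in MODEL_PARAMS:
        errors.append(
            f"model: must be one of {sorted(MODEL_PARAMS)} (got {model!r})")
        raise ConfigurationError("; ".join(errors))

    params = _build_params(MODEL_PARAMS[model], raw.get("params", {}),
                           errors, placeholders)
    if model == "full_recycling":
        params = dataclasses.replace(params, recycling=True)

    ctrl_entries = raw.get("controller", {}) or {}
    ctrl_names = {f.name for f in fields(ControllerConfig)}
    bad = set(ctrl_entries) - ctrl_names
    errors.extend(f"controller.{k}: unknown field" for k in sorted(bad))
    controller = ControllerConfig(
        **{k: v for k, v in ctrl_entries.items() if k in ctrl_names})

    seed = raw.get("seed")
    if model in STOCHASTIC_MODELS and seed is None:
        errors.append("seed: required (model has stochastic modules)")
    if seed is not None and hasattr(params, "seed"):
        params = dataclasses.replace(params, seed=int(seed))

    duration = _resolve_value("duration", raw.get("duration", 300.0),
                              errors, placeholders)
    observe_every = _resolve_value(
        "observe_every", raw.get("observe_every", 1.0), errors, placeholders)

    if errors:
        raise ConfigurationError("; ".join(errors))
    return RunConfig(model=model, params=params, duration=float(duration),
                     seed=None if seed is None else int(seed),
                     controller=controller,
                     out_dir=str(raw.get("out_dir", "out")),
                     observe_every=float(observe_every),
                     placeholders=placeholders, raw=raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the raw configuration for the run manifest."""
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
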