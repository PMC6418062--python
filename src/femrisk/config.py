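"""Configuration handling: embedded defaults with YAML/JSON overrides.

The default configuration carries the fixed model constants and the
truncation limits of the six stochastic fall parameters.  A user file (YAML
or JSON) is deep-merged over the defaults; unknown keys are rejected as a
typo guard, and each (a, b) pair is validated.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .domain import FixedConstants, FallStochasticModel

__all__ = ["DEFAULT_CONFIG", "load_config", "config_to_objects", "config_hash"]

DEFAULT_CONFIG: dict = {
    "constants": {"c": 0.554, "dt": 0.09, "n_fall": 0.65, "g": 9.81, "k": 0.5},
    "fall_model": {
        "theta_i": {"a": 0.0, "b": 30.0},
        "theta_f": {"a": 60.0, "b": 120.0},
        "v_i": {"a": 0.0, "b": 1.40},
        "a_i": {"a": 0.0, "b": 5.10},
        "eta_P": {"a": 0.500, "b": 0.800},
        "eta_I": {"a": -2.55, "b": 0.914},
    },
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ValueError(f"unknown configuration key: {here!r}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ValueError(f"configuration key {here!r} must be a mapping")
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = float(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a configuration mapping: embedded defaults, file overrides.

    ``path=None`` or an empty file yields the pure defaults.
    """
    override: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"configuration file {path} must contain a mapping")
            override = loaded
    cfg = _merge(DEFAULT_CONFIG, override)
    for name, spec in cfg["fall_model"].items():
        if not spec["a"] < spec["b"]:
            raise ValueError(f"fall_model.{name}: require a < b, got a={spec['a']}, b={spec['b']}")
    return cfg


def config_to_objects(cfg: dict) -> tuple[FixedConstants, FallStochasticModel]:
    """Materialise a configuration mapping into typed model objects."""
    constants = FixedConstants(**cfg["constants"])
    fall_model = FallStochasticModel.from_dict(cfg["fall_model"])
    return constants, fall_model


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping (for run manifests)."""
    blob = json.dumps(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
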