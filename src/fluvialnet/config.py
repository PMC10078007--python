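"""Run configuration: defaults, YAML loading, flag overrides.

Flat dotted keys (``boat.avg_speed_kmh``) mirror the module parameters they
feed. Unknown keys are rejected so typos fail loudly rather than silently
falling back to defaults.
"""
from __future__ import annotations

import hashlib
import json
from typing import Any

import yaml

from .attributes import DEFAULT_FLOW_REGIME_MAP, DEFAULT_STREAM_SPEED_TABLE

DEFAULTS: dict[str, Any] = {
    "boat.avg_speed_kmh": 18.52,
    "boat.max_speed_kmh": 37.0,
    "boat.min_effective_speed_kmh": 1.0,
    "stream_speed_table": dict(DEFAULT_STREAM_SPEED_TABLE),
    "flow_regime_map": None,  # None = built-in map
    "min_discharge_cms": 0.0,
    "upstream_mode": "floor",  # or "block"
    "apply_stream_speed": True,
    "river_fclass": "waterway_river",
    "junction_tolerance_m": 1.0,
    "connector_tolerance_m": 500.0,
    "walk_speed_kmh": 5.0,
    "default_road_speed_kmh": 40.0,
    "max_snap_m": 2000.0,
    "buffer_m": 250.0,
}


class ConfigError(ValueError):
    pass


def _flatten(d: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict) and key not in ("stream_speed_table", "flow_regime_map"):
            out.update(_flatten(v, f"{key}."))
        else:
            out[key] = v
    return out


def load_config(path: str | None = None, overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge defaults <- YAML file <- explicit overrides; reject unknown keys."""
    cfg = dict(DEFAULTS)
    for source, values in (("config file", _load_yaml(path)), ("flags", overrides or {})):
        for key, value in values.items():
            if value is None:
                continue
            if key not in DEFAULTS:
                raise ConfigError(f"unknown config key {key!r} (from {source})")
            cfg[key] = value
    if cfg["upstream_mode"] not in ("floor", "block"):
        raise ConfigError(f"upstream_mode must be 'floor' or 'block', got {cfg['upstream_mode']!r}")
    table = cfg["stream_speed_table"]
    cfg["stream_speed_table"] = {int(k): float(v) for k, v in table.items()}
    return cfg


def _load_yaml(path: str | None) -> dict[str, Any]:
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return _flatten(data)


def config_hash(cfg: dict[str, Any]) -> str:
    """Stable digest of a configuration, for run reports."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
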