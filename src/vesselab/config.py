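"""Run configuration: defaults, YAML loading, strict key validation.

A :class:`RunConfig` is a nested dict with every default materialized, so
a dumped config is a complete record of an analysis run.  Unknown keys
are rejected by name to catch misspellings early.
"""

from __future__ import annotations

import copy
from collections.abc import Mapping
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULTS", "load_config", "dump_config"]

CONFIG_VERSION = 1

DEFAULTS: dict = {
    "version": CONFIG_VERSION,
    "seed": 0,
    "gaussian": {
        # metadata only: the fixed transform matrix is used regardless
        "lambda0": 520.0,
        "sigma_lambda": 55.0,
    },
    "normalized": {"epsilon": 1e-6},
    "niblack": {"k": -0.2, "window_radius": 15},
    "sigmoid": {"gain": 10.0, "midpoint": "otsu"},
    "bilateral": {"sigma_s": 3.0, "sigma_r": 0.1, "window_radius": 7},
    "detail": {"n_iters": 2, "gain": 1.0},
    "quant": {"n_bins": 8, "kappa_q": None},  # None -> 8 / Delta_q
    "abstraction": {"use_large_scale": True, "base_gamma": 0.3},
    "gpac": {
        "block_size": 4,
        "curvature_weight": 0.5,
        "max_iters": 300,
        "tol": 0.001,  # fraction of image pixels
        "init_mode": "threshold_seed",
        "seed": 0,
    },
    "regions": {
        "dilation_radius": 5,
        "min_area": 50,
        "min_hole": 16,
        "white_fraction_cuts": [0.05, 0.35, 0.65, 0.95],
        "sar_band": [0.2, 0.9],
        "air_max": 0.2,
    },
    "fcm": {"n_classes": 3, "fuzzifier": 2.0, "stain_color": [0.45, 0.30, 0.20]},
}


class RunConfig(dict):
    """Nested configuration dict with attribute-free, key-checked access."""

    def dump(self) -> str:
        return yaml.safe_dump(dict(self), sort_keys=True)


def _merge(defaults: Mapping, override: Mapping, path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in override.items():
        full = f"{path}.{key}" if path else str(key)
        if key not in out:
            raise KeyError(f"unknown config key: {full!r}")
        if isinstance(out[key], Mapping):
            if not isinstance(value, Mapping):
                raise TypeError(f"config key {full!r} expects a mapping")
            out[key] = _merge(out[key], value, full)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: Mapping | None = None) -> RunConfig:
    """Load a YAML config file, merge onto defaults, validate keys.

    With ``path=None`` the full default configuration is returned.
    ``overrides`` (a nested mapping) is applied last; unknown keys at any
    level raise ``KeyError`` naming the offending key.
    """
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, Mapping):
            raise TypeError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, data)
    if overrides:
        cfg = _merge(cfg, overrides)
    return RunConfig(cfg)


def dump_config(cfg: RunConfig) -> str:
    """YAML text of the full effective configuration."""
    return cfg.dump()
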