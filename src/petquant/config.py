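"""Layered YAML configuration for the command-line pipeline."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "logan": {
        "window_min": 30.0,
        "window_max": 60.0,
        "k2prime": 0.16,
    },
    "idaif": {
        "t_late": 40.0,
        "n_starts": 5,
        "seed": 0,
        "smoothing": None,
        "duration_weighted": False,
        "parent_fraction": {
            "plateau": 0.05,
            "decay": 0.15,
            "blood_plasma_ratio": 1.0,
            "direction": "plasma_to_blood",
        },
    },
    "roi": {
        "fwhm_mm": 8.0,
        "percentile": 99.9,
        "keep_components": 1,
        "cc_a": 16.0,
        "cc_b": 100.0,
        "smoothing_mode": "constant",
        "truncate": 6.0,
    },
    "kinetic": {
        "n_starts": 3,
        "seed": 0,
        "duration_weighted": False,
    },
    "forward": {
        "dt_internal": 0.05,
    },
}


def merge_config(base: dict, override: dict) -> dict:
    """Recursive dict merge; override wins, sub-dicts merge key-wise."""
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overlaid with a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError("config file must contain a YAML mapping")
    return merge_config(DEFAULTS, user)
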