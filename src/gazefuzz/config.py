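"""YAML pipeline configuration with strict key validation."""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "merge_config", "dump_config"]

#: Every tunable of the pipeline, with its default. Unknown keys are rejected.
DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "fps": 30.0,
    "window": 10,
    "binarize": {"threshold": "auto"},
    "clean": {"open_radius": 2, "median_size": 3},
    "cht": {"pupil_radius_range": [10, 40], "glint_radius_range": [2, 10], "vote_floor": 8.0},
    "chanvese": {"mu": 0.25, "lambda_in": 1.0, "lambda_out": 1.0, "max_iter": 200},
    "mask": {"pupil_scale": 1.5, "glint_scale": 2.0},
    "glint": {"rel_threshold": 0.9},
    "feature1": {"stillness_threshold": 5.0, "templates": None},
    "gabor": {
        "sigma_x": 2.0,
        "sigma_y": 2.0,
        "radial_freq": 0.25,
        "n_orientations": 4,
        "n_scales": 4,
        "roi_half": 50,
    },
    "fuzzy": {
        "mode": "MIN",
        "method": "COG",
        "threshold": 0.6,
        "membership": None,  # None -> entropy-fit from labeled training features
        "grid_step": 0.01,
    },
}


def merge_config(overrides: Mapping[str, Any] | None, defaults: Mapping[str, Any] | None = None) -> dict:
    """Deep-merge user overrides onto the defaults, rejecting unknown keys."""
    base = copy.deepcopy(dict(defaults if defaults is not None else DEFAULT_CONFIG))
    if not overrides:
        return base
    for key, value in overrides.items():
        if key not in base:
            raise KeyError(f"unknown config key: {key!r}")
        if isinstance(base[key], dict) and isinstance(value, Mapping):
            base[key] = merge_config(value, base[key])
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config file and validate it against the defaults."""
    if path is None:
        return merge_config(None)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return merge_config(data)


def dump_config(config: Mapping[str, Any], path: str | Path) -> None:
    """Echo the effective configuration next to the outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
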