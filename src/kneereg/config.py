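"""Default algorithm parameters and YAML config loading.

Config files override the defaults key by key; command-line flags override
the config file. Every key below is documented in docs/methods.md.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "geometry": {
        "angle_a": 45.0,
        "angle_b": 135.0,
        "source_distance": 1000.0,  # mm, source to isocenter
        "detector_offset": 200.0,  # mm, isocenter to detector
        "pixel_spacing": 0.2,  # mm / pixel
        "image_size": [512, 512],
    },
    "preprocess": {
        "canny": {"low": 0.1, "high": 0.2, "sigma": 1.4},
        "median": {"size": 3},
        "nlm": {"patch": 7, "search": 21, "h": None},  # h=None: 0.8 * est. sigma
        "slic": {"K": 200, "m": 0.3, "iters": 10},
    },
    "similarity": {"rho": 0.005, "beta": 10.0},
    "optimizer": {
        "pop_size": 20,
        "iterations": 800,
        "seed": None,
        "bounds_rot_deg": 15.0,
        "bounds_trans_mm": 15.0,
        "radius": 256,
        "restart": 0.1,
        "stagnation": None,
    },
    "synthetic": {
        "size_mm": 50.0,
        "noise_sigma": 0.05,
        "n_clutter": 6,
        "rot_perturb_deg": 10.0,
        "trans_perturb_mm": 10.0,
    },
}


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    out = copy.deepcopy(base)
    if not override:
        return out
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = merge_config(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, overridden by a YAML file, overridden by ``overrides``."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = merge_config(cfg, doc)
    return merge_config(cfg, overrides)
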