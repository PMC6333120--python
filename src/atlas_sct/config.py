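"""Pipeline parameter tree: defaults, file loading, and overrides.

Configs are plain nested dicts (YAML or JSON on disk).  Command-line flags
override file values which override the defaults below.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .fusion import GREParams
from .mr_preprocessing import StandardScale
from .registration import RegistrationParams

__all__ = [
    "default_config",
    "load_config",
    "merge_config",
    "scale_from_config",
    "reg_params_from_config",
    "gre_params_from_config",
]

_DEFAULTS: dict = {
    "seed": 0,
    "alpha": 0.5,
    "scale": {"s_dark": 100.0, "s_valley": 500.0, "s_bright": 1000.0,
              "s_max": 1200.0},
    "hist_bins": 256,
    "smooth_window": 5,
    "bias": {"basis_order": 2, "k": 3, "n_iter": 20},
    "fcm": {"fuzzifier": 2.0, "tol": 1e-4, "max_iter": 200},
    # iteration schedule is coarsest-first and deliberately lighter than the
    # single-level default of RegistrationParams to keep batch runs tractable
    "registration": {
        "grid_spacing_mm": 40.0,
        "pyramid_levels": 3,
        "iterations_per_level": [60, 30, 15],
        "regularization_weight": 0.01,
    },
    "gre": {"patch_radius_vox": 2, "entropy_bins": 32, "epsilon": 1e-6,
            "search_radius_mm": 2.0},
    "crop_slices": 0,
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def merge_config(base: dict, override: dict | None) -> dict:
    """Recursive dict merge; ``override`` wins on leaves."""
    out = copy.deepcopy(base)
    for key, val in (override or {}).items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None) -> dict:
    """Defaults merged with a YAML/JSON config file (if given)."""
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise IOError(f"config file not found: {path}")
    text = path.read_text()
    loaded = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if loaded is None:
        loaded = {}
    if not isinstance(loaded, dict):
        raise ValueError(f"config root must be a mapping: {path}")
    return merge_config(cfg, loaded)


def scale_from_config(cfg: dict) -> StandardScale:
    return StandardScale(**cfg["scale"])


def reg_params_from_config(cfg: dict) -> RegistrationParams:
    r = cfg["registration"]
    iters = r["iterations_per_level"]
    if isinstance(iters, list):
        iters = tuple(iters)
    return RegistrationParams(
        grid_spacing_mm=float(r["grid_spacing_mm"]),
        pyramid_levels=int(r["pyramid_levels"]),
        iterations_per_level=iters,
        regularization_weight=float(r["regularization_weight"]),
    )


def gre_params_from_config(cfg: dict, body_mask=None) -> GREParams:
    g = cfg["gre"]
    return GREParams(
        patch_radius_vox=int(g["patch_radius_vox"]),
        entropy_bins=int(g["entropy_bins"]),
        epsilon=float(g["epsilon"]),
        search_radius_mm=float(g["search_radius_mm"]),
        body_mask=body_mask,
    )
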