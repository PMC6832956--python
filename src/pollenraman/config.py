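"""Run configuration: a single nested YAML file with embedded defaults.

``default_config`` returns the full default tree; ``load_config`` deep-merges
a user file over it, so configs only need to state what they change.  Every
command echoes the effective config into its output directory for
reproducibility.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "paths": {
        "output_dir": "pollenraman_run",
        "images_dir": None,
        "spectra_table": None,
        "manifest": None,
    },
    "simulate": {
        "n_per_class": 150,
        "axis_min": 600.0,
        "axis_max": 3100.0,
        "n_channels": 1200,
        "scatter_sd": 0.1,
        "noise_sd": 0.02,
        "spike_rate": 0.05,
        "n_fov_images": 4,
        "fov": {
            "image_shape": [480, 640],
            "n_particles": 5,
            "radius_range": [12.0, 25.0],
            "min_separation": 80.0,
            "noise_sd": 2.0,
        },
    },
    "localization": {
        "pixel_size_um": 1.0,
        "min_diameter_um": 10.0,
        "max_diameter_um": 100.0,
        "fill_iterations": 3,
        "dilate_iterations": 1,
        "frame_pitch_um": [640.0, 480.0],
        "stage_scale_um_per_px": 1.0,
        "stage_offset_um": [0.0, 0.0],
    },
    "preprocess": {
        "spike_width_threshold": 3,
        "spike_deviation_threshold": 8.0,
        "emsc_b_floor": 1.0e-6,
    },
    "regions": {
        "fingerprint": [758.0, 1800.0],
        "high_wavenumber": [2800.0, 3045.0],
    },
    "chemometrics": {
        "hca": {"exponent": 5.0, "linkage": "average", "n_clusters": 4},
        "n_components": 9,
        "n_train_scores": 100,
        "n_folds": 10,
        "kernel_scale": None,
        "tsne_perplexity": 30.0,
    },
}


def default_config() -> dict[str, Any]:
    return copy.deepcopy(DEFAULT_CONFIG)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return _deep_merge(DEFAULT_CONFIG, user)


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
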