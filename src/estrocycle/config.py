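"""YAML configuration with package-wide defaults.

A single YAML file with sections ``data``, ``preprocess``, ``train``,
``cyclefit`` and ``evaluate`` can override any default below; absent keys
fall back to the defaults.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path

import yaml

logger = logging.getLogger("estrocycle")

DEFAULT_CONFIG: dict = {
    "data": {
        "min_pixels": 300,
        "min_cells": 10,
        "synthetic": {
            "image_size": 448,
            "n_per_stage": 200,
            "stains": ["HE", "Shorr"],
            "clumping_strength": 0.7,
            "noise_sd": 0.01,
        },
    },
    "preprocess": {
        "luminance_target": 0.8,
        "luminance_bins": 64,
        "fractions": [0.8, 0.1, 0.1],
        "strata_keys": ["stain", "species", "lab", "magnification"],
        "quadrisect_after_split": True,
        "augment": {
            "reflect": "both",
            "reflect_prob": 0.5,
            "rotation_range": 30.0,
            "scale_range": [0.9, 1.1],
            "translate_range": 0.1,
        },
    },
    "train": {
        "backbone": "smallcnn",
        "n_stages": 4,
        "initial_lr": 1e-5,
        "minibatch": 80,
        "optimizer": "rmsprop",
        "squared_gradient_decay": 0.99,
        "epochs": 3,
        "shuffle_every_epoch": True,
        "lr_drop": 0.1,
        "epochs_drop": 1,
        "lr_floor": 0.0,
    },
    "cyclefit": {
        "period_days": 4.8,
        "stage_fractions": {
            "diestrus": 0.35,
            "proestrus": 0.15,
            "estrus": 0.30,
            "metestrus": 0.20,
        },
        "phase_increment": 0.1,
        "deviation_threshold": 1.0,
        "ci_threshold": 0.30,
        "waveform": "interp",
        "pseudopregnancy_factor": 1.5,
        "anestrus_leukocyte_threshold": 0.9,
        "anestrus_min_days": 2,
    },
    "evaluate": {
        "bootstrap_iterations": 5000,
        "kfold_groups": 6,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config merged over :data:`DEFAULT_CONFIG`."""
    if path is None:
        return copy.deepcopy(DEFAULT_CONFIG)
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a YAML mapping")
    return _deep_merge(DEFAULT_CONFIG, raw)


def setup_logging(logfile: str | Path | None = None, level: int = logging.INFO) -> logging.Logger:
    """Attach a timestamped handler to the package logger."""
    log = logging.getLogger("estrocycle")
    log.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    handler: logging.Handler
    handler = logging.FileHandler(logfile) if logfile else logging.StreamHandler()
    handler.setFormatter(fmt)
    log.addHandler(handler)
    return log
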