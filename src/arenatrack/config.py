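"""Run configuration: one YAML file mirroring every tunable default.

Every run writes its *resolved* configuration (defaults merged with the
user file) beside the outputs, so an experiment is reproducible from its
output directory alone.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .tracker import TrackerConfig

__all__ = ["default_config", "load_config", "save_config", "tracker_config"]


def default_config() -> dict:
    cfg = {"tracker": asdict(TrackerConfig())}
    cfg["assays"] = {
        "ymaze": {"center_radius_fraction": 0.25},
        "optomotor": {
            "duration_s": 2.0,
            "min_iti_s": 2.0,
            "refresh_hz": 60.0,
            "min_edge_distance": None,
            "speed_threshold": 1.0,
        },
        "speed_contingent": {
            "threshold_mm_s": 6.8,
            "period_s": 480.0,
            "n_periods": 8,
        },
    }
    return cfg


def _deep_update(base: dict, extra: dict) -> dict:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None) -> dict:
    """Defaults, overridden by the YAML file at ``path`` when given."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    return cfg


def save_config(cfg: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def tracker_config(cfg: dict) -> TrackerConfig:
    return TrackerConfig(**cfg.get("tracker", {}))
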