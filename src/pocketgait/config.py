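"""Flat, namespaced run configuration shared by the CLI and the pipeline."""

from __future__ import annotations

import yaml

from .errors import ValidationError

#: Every known configuration key with its default.
DEFAULTS = {
    "orientation.method": "tilt_complementary",
    "orientation.gain": 0.02,
    "gravity_mps2": 9.80665,
    "accel_in_g": False,
    "events.lp_cutoff_hz": 3.0,
    "events.min_period_s": 0.4,
    "events.prominence_k": 1.0,
    "events.stride_gate_s": [0.5, 2.5],
    "pendulum.hp_cutoff_hz": 0.11,
    "pendulum.hp_order": 4,
    "adjustment.anchor_m": 0.2,
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a flat YAML file, then from overrides.

    Unknown keys are rejected so typos do not silently fall back to defaults.
    """
    cfg = dict(DEFAULTS)
    for source, label in ((path, "config file"), (overrides, "override")):
        if source is None:
            continue
        if isinstance(source, dict):
            items = source
        else:
            with open(source) as fh:
                items = yaml.safe_load(fh) or {}
            if not isinstance(items, dict):
                raise ValidationError(f"{label} {source} is not a flat key-value mapping")
        unknown = set(items) - set(DEFAULTS)
        if unknown:
            raise ValidationError(f"unknown {label} key(s): {', '.join(sorted(unknown))}")
        cfg.update(items)
    return cfg


def estimate_gait_kwargs(cfg: dict) -> dict:
    """Translate a flat config into :func:`pocketgait.pendulum.estimate_gait` arguments."""
    return {
        "orientation_method": cfg["orientation.method"],
        "orientation_gain": cfg["orientation.gain"],
        "gravity": cfg["gravity_mps2"],
        "lp_cutoff": cfg["events.lp_cutoff_hz"],
        "min_period": cfg["events.min_period_s"],
        "prominence_k": cfg["events.prominence_k"],
        "stride_gate": tuple(cfg["events.stride_gate_s"]),
        "hp_cutoff": cfg["pendulum.hp_cutoff_hz"],
        "hp_order": cfg["pendulum.hp_order"],
    }
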