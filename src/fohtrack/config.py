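"""YAML configuration for probe/imaging parameters and tracker options."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .geometry import ProbeGeometry
from .localise import TrackerOptions

__all__ = ["ConfigError", "load_config", "save_config", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """Raised for unreadable or inconsistent configuration files."""


DEFAULT_CONFIG: dict = {
    "rho_mm": 68.0,
    "fov_deg": 55.0,
    "n_lines": 128,
    "sound_speed_mps": 1540.0,
    "imaging_depth_mm": 300.0,
    "sample_rate_hz": 1.0e7,
    "focal_depth_mm": 15.0,
    "trigger_to_transmit_delay_s": 1.0e-5,
}


def load_config(path: str | Path | None) -> tuple[ProbeGeometry, dict]:
    """Load probe/imaging configuration; returns (geometry, full dict).

    Unknown keys are preserved in the returned dict (e.g. tracker options).
    Missing keys fall back to the package defaults.
    """
    merged = dict(DEFAULT_CONFIG)
    if path is not None:
        try:
            with open(path) as f:
                user = yaml.safe_load(f) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read configuration {path}: {exc}") from exc
        if not isinstance(user, dict):
            raise ConfigError(f"configuration {path} must be a mapping")
        merged.update(user)
    try:
        geometry = ProbeGeometry(
            radius_of_curvature_mm=float(merged["rho_mm"]),
            field_of_view_deg=float(merged["fov_deg"]),
            n_scan_lines=int(merged["n_lines"]),
            sound_speed_mps=float(merged["sound_speed_mps"]),
            imaging_depth_mm=float(merged["imaging_depth_mm"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid probe configuration: {exc}") from exc
    return geometry, merged


def tracker_options_from(config: dict) -> TrackerOptions:
    defaults = TrackerOptions()
    return TrackerOptions(
        threshold_db=float(config.get("threshold_db", defaults.threshold_db)),
        snr_gate_db=float(config.get("snr_gate_db", defaults.snr_gate_db)),
        dynamic_range_db=float(config.get("dynamic_range_db", defaults.dynamic_range_db)),
        toa_gate_pulse_lengths=float(
            config.get("toa_gate_pulse_lengths", defaults.toa_gate_pulse_lengths)
        ),
        spread_variant=str(config.get("spread_variant", defaults.spread_variant)),
    )


def save_config(path: str | Path, config: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config, f, sort_keys=True)
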