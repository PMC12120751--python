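"""Configuration: defaults for every numeric setting, TOML/YAML overrides."""

from __future__ import annotations

import copy
import tomllib
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["DEFAULTS", "load_config", "merge_config"]

DEFAULTS: dict = {
    "grid": {
        "stimulation_frequency": 2.4,
        "f_max": 97.6,
        "step_above": 1.2,
        "n_below": 6,
        "step_below": 0.2,
        "sub_stim_centers": None,
        "fwhm_base": 0.3,
        "fwhm_log10_slope": 1.0,
    },
    "ged": {
        "gamma_S": 1e-6,
        "gamma_R_fraction": 0.01,
        "n_keep": 10,
        "method": "ged",
    },
    "cfc": {
        "n_bins": 36,
        "edge_guard_s": 1.0,
        "modulator_frequency": 2.4,
        "modulator_component": 1,
        "carrier_component": 1,
    },
    "stats": {
        "q": 0.05,
        "tail": "two",
        "n_perm": 1000,
        "alpha_cluster_forming": 0.05,
        "seed": 0,
    },
    "simulate": {
        "n_voxels": 200,
        "duration_s": 120.0,
        "sampling_rate": 250.0,
        "aperiodic_exponent": 1.0,
        "background_rms": 1.0,
        "white_noise_rms": 0.5,
        "seed": 0,
        "n_subjects": 2,
        "pl_add_network_frequency": 2.4,
        "pl_add_network_amplitude": 2.0,
    },
    "pipeline": {
        "stages": [],
        "out": "freqness_out",
        "seed": 0,
    },
}


def merge_config(overrides: dict, base: dict | None = None) -> dict:
    """Deep-merge user overrides onto the defaults, rejecting unknown keys."""
    config = copy.deepcopy(base if base is not None else DEFAULTS)
    for section, values in overrides.items():
        if section not in config:
            raise ConfigurationError(f"unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigurationError(f"section {section!r} must be a table/mapping")
        for key, value in values.items():
            if key not in config[section]:
                raise ConfigurationError(f"unknown key {section}.{key}")
            config[section][key] = value
    return config


def load_config(path: str | Path | None) -> dict:
    """Load a TOML or YAML config file and merge it onto the defaults."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as handle:
            overrides = tomllib.load(handle)
    elif path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as handle:
            overrides = yaml.safe_load(handle) or {}
    else:
        raise ConfigurationError(f"config must be .toml or .yaml, got {path.suffix!r}")
    return merge_config(overrides)
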