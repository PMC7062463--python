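"""Run configuration: sectioned key-value settings with strict validation.

A run config is a YAML file with the sections below; missing keys take
the documented defaults, unknown sections or keys are rejected, and the
fully resolved configuration is echoed (logged) for reproducibility.
"""

from __future__ import annotations

import copy
import logging

import yaml

__all__ = ["DEFAULTS", "run_config"]

log = logging.getLogger("stclust")

DEFAULTS: dict = {
    "data": {
        "container": None,          # path to recording HDF5
        "cell": None,               # cell id within /spikes
        "n_lags": 15,               # STA depth (125 ms at 120 Hz)
        "rf_threshold": 2.5,        # RF mask threshold, multiples of sigma
    },
    "fit": {
        "n_subunits": 5,
        "max_iter": 100,
        "tol": 1e-6,
        "seed": 0,
        "init": "sta-noise",
    },
    "reg": {
        "kind": "none",             # none | l1 | lnl1
        "lam": 0.0,
        "eps": 0.01,
        "connectivity": 4,
    },
    "select": {
        "n_min": 1,
        "n_max": 12,
        "lam_grid": [0.0],
        "repeats": 3,
        "test_frac": 0.1,
        "val_frac": 0.1,
    },
    "sim": {
        "preset": "rgc64",          # rgc64 | toy3 | toy5
        "minutes": 24.0,
        "pixel_size": 6.0,
        "contrast": 0.48,
        "seed": 0,
    },
    "null": {
        "contrast": 0.48,
        "mode": "spatial",          # spatial | spectral
        "tol": 1e-9,
        "max_iter": 500,
    },
}

_VALIDATORS = {
    ("fit", "n_subunits"): lambda v: v >= 1,
    ("fit", "max_iter"): lambda v: v >= 1,
    ("fit", "tol"): lambda v: v > 0,
    ("reg", "lam"): lambda v: v >= 0,
    ("reg", "eps"): lambda v: v > 0,
    ("reg", "kind"): lambda v: v in ("none", "l1", "lnl1"),
    ("reg", "connectivity"): lambda v: v in (4, 8),
    ("sim", "contrast"): lambda v: 0 < v <= 1,
    ("null", "mode"): lambda v: v in ("spatial", "spectral"),
}


def run_config(path=None, overrides: dict | None = None) -> dict:
    """Load, validate and resolve a run configuration.

    ``path`` may be None (pure defaults).  ``overrides`` is a nested
    dict merged last (CLI flags).  Unknown sections/keys raise;
    validated values that fail their constraint raise with the
    offending key named.  The resolved config is logged verbatim.
    """
    cfg = copy.deepcopy(DEFAULTS)
    layers = []
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        layers.append(loaded)
    if overrides:
        layers.append(overrides)
    for layer in layers:
        if not isinstance(layer, dict):
            raise ValueError("config must be a mapping of sections")
        for section, values in layer.items():
            if section not in cfg:
                raise ValueError(f"unknown config section {section!r}")
            if not isinstance(values, dict):
                raise ValueError(f"section {section!r} must be a mapping")
            for key, val in values.items():
                if key not in cfg[section]:
                    raise ValueError(f"unknown key {section}.{key}")
                default = cfg[section][key]
                if default is not None and val is not None and not isinstance(
                        val, type(default)) and not (
                        isinstance(default, float) and isinstance(val, int)):
                    raise ValueError(
                        f"{section}.{key}: expected {type(default).__name__}, "
                        f"got {type(val).__name__}")
                cfg[section][key] = val
    for (section, key), check in _VALIDATORS.items():
        val = cfg[section][key]
        if val is not None and not check(val):
            raise ValueError(f"invalid value for {section}.{key}: {val!r}")
    log.info("resolved config: %s", yaml.safe_dump(cfg, sort_keys=True))
    return cfg
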