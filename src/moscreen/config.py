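"""Run configuration: defaults, YAML loading, and strict key validation.

A run is described by a small YAML file with named sections mirroring the
library inputs, the screen parameters, the objective transforms and the
synthetic-benchmark generator. Every field has a documented default;
unknown keys are rejected with a suggestion, and the fully resolved
configuration is echoed into the output directory before any computation
so a run directory is self-describing.
"""

from __future__ import annotations

import copy
import difflib
import os
from typing import Any, Mapping

import yaml

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "moscreen_run",
    "library": {
        "smiles": None,        # .smi path
        "embeddings": None,    # matrix path (.npy / delimited text)
        "properties": None,    # CSV with id column + property columns
        "id_column": "id",
        "fingerprint_radius": 2,
        "fingerprint_bits": 2048,
    },
    "screen": {
        "budget_fraction": 0.06,
        "init_fraction_of_budget": 0.25,
        "n_clusters": 20,
        "batch_size": None,
        "kernel_family": "rbf",
        "zeta": 0.01,
        "log_space": True,
        "gp_max_iter": 200,
        "pool_chunk": None,
    },
    "objectives": [
        {"name": "affinity", "transform": {"kind": "negate"},
         "desirable": [None, -8.0]},
        {"name": "logp",
         "transform": {"kind": "gaussian_peak", "center": 2.5, "width": 1.0},
         "desirable": [0.0, 5.0]},
        {"name": "sas", "transform": {"kind": "negate"},
         "desirable": [None, 2.0]},
    ],
    "benchmark": {
        "n_molecules": 5000,
        "d": 32,
        "n_objectives": 3,
        "n_blobs": 20,
    },
}


class ConfigError(ValueError):
    """Raised for unknown keys or invalid configuration values."""


def _check_keys(given: Mapping[str, Any], allowed: Mapping[str, Any],
                path: str = "") -> None:
    for key in given:
        if key not in allowed:
            loc = f"{path}{key}"
            hint = difflib.get_close_matches(key, list(allowed), n=1)
            msg = f"unknown config key {loc!r}"
            if hint:
                msg += f"; did you mean {hint[0]!r}?"
            raise ConfigError(msg)


def _merge(base: dict, override: Mapping[str, Any], path: str = "") -> dict:
    _check_keys(override, base, path)
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(base[key], dict) and isinstance(val, Mapping):
            out[key] = _merge(base[key], val, path=f"{path}{key}.")
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | os.PathLike | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Merge defaults <- YAML file <- programmatic overrides, strictly."""
    resolved = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a mapping")
        resolved = _merge(resolved, user)
    if overrides:
        resolved = _merge(resolved, overrides)
    return resolved


def echo_config(config: Mapping[str, Any], out_dir: str | os.PathLike) -> str:
    """Write the fully resolved config into the run directory."""
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(os.fspath(out_dir), "resolved_config.yaml")
    with open(path, "w") as fh:
        yaml.safe_dump(dict(config), fh, sort_keys=False)
    return path
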