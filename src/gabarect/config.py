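"""Declarative configuration and run manifests.

A run is described by a plain YAML mapping with three top-level groups —
``sim`` (solver settings), ``model`` (which preset cell and channel options),
and ``protocol`` (per-protocol parameters).  Unknown keys are rejected with
the offending path so typos fail loudly.  Every command writes a manifest
recording the seed, scheme, dt, package version, a hash of the resolved
configuration, and the produced files, so any output can be regenerated
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__

__all__ = ["ConfigError", "DEFAULTS", "load_config", "resolve", "RunManifest"]


class ConfigError(ValueError):
    pass


DEFAULTS: dict = {
    "sim": {
        "dt": 0.025,
        "t_stop": 300.0,
        "v_init": -70.0,
        "scheme": "backward_euler",
        "settle": 500.0,
    },
    "model": {
        "preset": "branch",            # "branch" or "fullcell"
        "morph_seed": 0,
        "with_hcn": True,
        "with_k": True,
        "tonic_density": 0.0,
        "e_gaba": -70.0,
        "swc": None,                   # optional SWC path overriding the preset
    },
    "protocol": {
        "step_pA": 25.0,
        "holds_mV": None,              # None = -94..+26 by 12
        "tail_ms": 30.0,
        "n_inputs": [1, 3, 5, 7],
        "gaba_variant": "nonlinear",
        "nmda_on": True,
        "n_active": [15, 45, 75, 105, 135, 165],
        "gaba_mode": "nonlinear",
        "repeats": 5,
        "round_index": 3,
        "variant": "control",
        "synapse": "gabaA_nonlinear_unit",
        "weight_nS": None,
        "noise_sigma": 0.02,
    },
}


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, here)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None) -> dict:
    """Resolved configuration: defaults overlaid with the YAML file, if any."""
    if path is None:
        return json.loads(json.dumps(DEFAULTS))
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError("top-level config must be a mapping")
    return _merge(DEFAULTS, user)


def resolve(cfg: dict, overrides: list[str] | None = None) -> dict:
    """Apply ``key.path=value`` command-line overrides (YAML-parsed values)."""
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigError(f"override must look like sim.dt=0.0125: {ov!r}")
        key, _, raw = ov.partition("=")
        node: dict = {}
        leaf = node
        parts = key.split(".")
        for part in parts[:-1]:
            leaf[part] = {}
            leaf = leaf[part]
        leaf[parts[-1]] = yaml.safe_load(raw)
        cfg = _merge(cfg, node)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    subcommand: str
    seed: int
    config_hash: str
    dt: float
    scheme: str
    version: str = __version__
    outputs: list[str] = field(default_factory=list)

    def write(self, directory: str | Path) -> Path:
        path = Path(directory) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
        return path
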