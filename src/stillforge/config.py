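"""Validated hierarchical run configuration (YAML).

Every stochastic step derives its generator from the single top-level
seed; unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .cells import UnitCell
from .postrefine import PostRefinementConfig
from .synthdata import SimConfig

__all__ = ["RunConfig", "load_config", "config_fingerprint"]


@dataclass
class RunConfig:
    """Top-level configuration for the end-to-end pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    postrefine: PostRefinementConfig = field(default_factory=PostRefinementConfig)
    cluster_cut_height: float = 5.0
    misindex_search_radius: float = 4.0
    frames_path: str | None = None  # process an existing frame set instead of simulating
    out_dir: str = "stillforge_out"
    seed: int = 0

    def __post_init__(self) -> None:
        # one seed to rule every stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.postrefine = dataclasses.replace(self.postrefine, split_seed=self.seed)


def _build(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown config key(s) under {path or 'root'}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        if name == "cell" and isinstance(value, (list, tuple)):
            kwargs[name] = UnitCell(*value)
        elif dataclasses.is_dataclass(_resolve(ftype)) and isinstance(value, dict):
            kwargs[name] = _build(_resolve(ftype), value, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _resolve(ftype):
    mapping = {"SimConfig": SimConfig, "PostRefinementConfig": PostRefinementConfig}
    if isinstance(ftype, str):
        return mapping.get(ftype, str)
    return ftype


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return _build(RunConfig, data, "")


def config_fingerprint(config: RunConfig) -> str:
    """Stable hash of the full configuration, for provenance records."""

    def encode(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: encode(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, UnitCell):
            return [float(v) for v in obj.parameters()]
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    blob = json.dumps(encode(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
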