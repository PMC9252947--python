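"""Run configuration: one YAML file drives the end-to-end pipeline.

All randomness flows from the single global ``seed`` through named
substreams (phantom, model init, training shuffle/dropout, MC sampling),
so every artifact is reconstructible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .bnn_model import ModelConfig, TrainConfig
from .phantom import LesionSpec, PhantomConfig, RegionParams

_SUBSTREAMS = {
    "phantom": 0,
    "init": 1,
    "train": 2,
    "init_baseline": 3,
    "train_baseline": 4,
    "mc": 5,
}


def substream_seed(seed: int, name: str) -> int:
    """Deterministic named sub-seed of the global seed (below 2**31)."""
    return int(
        np.random.SeedSequence([seed, _SUBSTREAMS[name]]).generate_state(1)[0]
        % (2**31)
    )


@dataclasses.dataclass
class AnomalyConfig:
    """Operational constants of the detection stage."""

    z_threshold: float = 3.0
    radius_mm: float = 5.0
    connectivity: int = 26
    variance_floor: float = 1e-6
    mc_samples: int = 1

    def __post_init__(self) -> None:
        if self.z_threshold <= 0 or self.radius_mm <= 0:
            raise ValueError("z_threshold and radius_mm must be positive")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


@dataclasses.dataclass
class EvalConfig:
    suv_thresholds: tuple[float, ...] = (1.0, 2.0)
    abs_error_thresholds: tuple[float, ...] = (0.5, 1.0)
    fp_rates: tuple[float, ...] = (1.0, 3.0, 10.0)


@dataclasses.dataclass
class RunConfig:
    phantom: PhantomConfig = dataclasses.field(default_factory=PhantomConfig)
    model: ModelConfig = dataclasses.field(default_factory=ModelConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    anomaly: AnomalyConfig = dataclasses.field(default_factory=AnomalyConfig)
    eval: EvalConfig = dataclasses.field(default_factory=EvalConfig)
    out_dir: str = "petnorm_run"
    resample_mm: float = 3.0
    seed: int = 0


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def _tup(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    phantom = d.get("phantom", {})
    if isinstance(phantom, dict):
        p = dict(phantom)
        if "regions" in p:
            p["regions"] = tuple(RegionParams(**r) for r in p["regions"])
        if "lesions" in p:
            p["lesions"] = tuple(LesionSpec(**l) for l in p["lesions"])
        for key in ("shape", "spacing"):
            if key in p:
                p[key] = _tup(p[key])
        phantom = PhantomConfig(**p)
    model = d.get("model", {})
    if isinstance(model, dict):
        m = dict(model)
        for key in ("logvar_clamp", "input_norm"):
            if key in m:
                m[key] = _tup(m[key])
        model = ModelConfig(**m)
    train = d.get("train", {})
    if isinstance(train, dict):
        train = TrainConfig(**train)
    anomaly = d.get("anomaly", {})
    if isinstance(anomaly, dict):
        anomaly = AnomalyConfig(**anomaly)
    ev = d.get("eval", {})
    if isinstance(ev, dict):
        e = {k: _tup(v) for k, v in ev.items()}
        ev = EvalConfig(**e)
    return RunConfig(
        phantom=phantom,
        model=model,
        train=train,
        anomaly=anomaly,
        eval=ev,
        out_dir=d.get("out_dir", "petnorm_run"),
        resample_mm=float(d.get("resample_mm", 3.0)),
        seed=int(d.get("seed", 0)),
    )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def apply_override(cfg: RunConfig, dotted_key: str, value: str) -> RunConfig:
    """Apply a ``section.field=value`` override, YAML-parsing the value."""
    d = config_to_dict(cfg)
    parts = dotted_key.split(".")
    node = d
    for part in parts[:-1]:
        if part not in node or not isinstance(node[part], dict):
            raise KeyError(f"unknown config section {dotted_key!r}")
        node = node[part]
    if parts[-1] not in node:
        raise KeyError(f"unknown config field {dotted_key!r}")
    node[parts[-1]] = yaml.safe_load(value)
    return config_from_dict(d)
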