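"""Run configuration: one YAML/JSON file, one master seed, strict keys.

Sub-seeds for each pipeline stage are derived from the master seed by a
fixed counter scheme (stage offsets), so a single integer reproduces the
whole run.  Unknown keys anywhere in the file are rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .embedding import SgnsParams
from .model import ModelConfig
from .network import FeatureConfig
from .synthetic import SynthParams

__all__ = ["RunConfig", "ConfigError", "parse_config", "STAGE_SEED_OFFSETS"]

# Fixed fan-out of the master seed to stages.
STAGE_SEED_OFFSETS = {
    "simulate": 0,
    "embed": 1,
    "featurize": 2,
    "train": 3,
    "crossval": 4,
}


class ConfigError(ValueError):
    pass


@dataclass
class EvalSettings:
    k: int = 10
    tau: float = 0.5
    top_n: int = 10


@dataclass
class RunConfig:
    data_dir: str = "data"
    out_dir: str = "out"
    seed: int = 7
    synth: SynthParams = field(default_factory=SynthParams)
    sgns: SgnsParams = field(default_factory=SgnsParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvalSettings = field(default_factory=EvalSettings)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{path}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "synth", "sgns", "features", "model", "evaluation"):
            sub_cls = {"synth": SynthParams, "sgns": SgnsParams,
                       "features": FeatureConfig, "model": ModelConfig,
                       "evaluation": EvalSettings}[f.name]
            kwargs[key] = _build(sub_cls, value, f"{path}.{key}")
        else:
            tname = f.type if isinstance(f.type, str) else getattr(
                f.type, "__name__", str(f.type))
            expected = {"int": int, "float": float, "str": str}.get(tname)
            if f.name in ("proc_hidden", "cls_hidden", "modalities"):
                kwargs[key] = tuple(value)
                continue
            if expected is int and isinstance(value, bool):
                raise ConfigError(f"{path}.{key}: expected int, got bool")
            if expected is int and not isinstance(value, int):
                raise ConfigError(f"{path}.{key}: expected int, got {value!r}")
            if expected is float and not isinstance(value, (int, float)):
                raise ConfigError(f"{path}.{key}: expected number, got {value!r}")
            if expected is str and not isinstance(value, str):
                raise ConfigError(f"{path}.{key}: expected string, got {value!r}")
            kwargs[key] = value
    return cls(**kwargs)


def parse_config(path: str | Path | None) -> RunConfig:
    """Parse YAML or JSON into a RunConfig; an empty file means defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text(encoding="utf-8")
    if not text.strip():
        return RunConfig()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return RunConfig()
    return _build(RunConfig, data, "config")


def effective_config_json(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError
    return json.dumps(cfg, default=enc, indent=1, sort_keys=True)
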