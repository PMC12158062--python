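"""Run configuration: defaults, YAML files, and ``key=value`` overrides.

Precedence is CLI overrides > config file > defaults.  Defaults resolve
to the reference setup (300-s windows; Adam, lr 1e-4, discount 0.95,
replay 50,000).  Every command serializes the resolved config and its
hash into the output directory so a run is reconstructable from its
artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Union

import yaml
from pydantic import BaseModel, Field

from .agent import TrainingConfig

__all__ = [
    "GeneratorConfig",
    "TrainConfig",
    "EvalConfig",
    "RunConfig",
    "load_config",
    "config_hash",
]


class GeneratorConfig(BaseModel):
    n_sessions: int = 17
    segment_duration_s: int = 300
    hr_rest: float = 65.0
    hr_slope: float = 9.0
    noise_sd: float = 2.0
    ar_coef: float = 0.9
    tau: float = 30.0


class TrainConfig(BaseModel):
    learning_rate: float = 1e-4
    gamma: float = 0.95
    replay_capacity: int = 50_000
    epochs: int = 35
    batch_size: int = 64
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_frac: float = 0.5
    target_sync_interval: int = 1_000
    warmup_transitions: int = 1_000
    update_every: int = 4
    window_length_s: int = 300
    train_stride_s: int = 30

    def to_training_config(self, seed: int) -> TrainingConfig:
        return TrainingConfig(seed=seed, **self.model_dump())


class EvalConfig(BaseModel):
    clamp_keytel_negative: bool = True
    fill_missing_hr: bool = True


class RunConfig(BaseModel):
    seed: int = 0
    log_level: str = "INFO"
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    training: TrainConfig = Field(default_factory=TrainConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)


def _coerce(value: str):
    try:
        return json.loads(value)
    except json.JSONDecodeError:
        return value


def load_config(
    path: Union[str, Path, None] = None,
    overrides: tuple[str, ...] = (),
    seed: Optional[int] = None,
) -> RunConfig:
    """Resolve a :class:`RunConfig` from file + dotted-key overrides.

    Overrides look like ``training.epochs=10``; values parse as JSON
    when possible, else as strings.  An explicit ``seed`` wins over both.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded:
            data = loaded
    for item in overrides:
        key, sep, value = item.partition("=")
        if not sep:
            raise ValueError(f"override {item!r} is not of the form key=value")
        node = data
        *parents, leaf = key.strip().split(".")
        for part in parents:
            node = node.setdefault(part, {})
        node[leaf] = _coerce(value.strip())
    if seed is not None:
        data["seed"] = seed
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the fully resolved configuration."""
    canonical = json.dumps(config.model_dump(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
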