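"""Schema-validated run configuration for the end-to-end pipeline.

YAML -> pydantic models with unknown keys rejected.  Every artifact the
pipeline writes records the configuration hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dataset import CLASS_NAMES

__all__ = ["RunConfig", "load_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorSection(_Strict):
    image_size: int = 256
    counts: dict[str, int] = Field(
        default_factory=lambda: {n: 20 for n in CLASS_NAMES})
    stem_probability: float = 0.0


class PreprocessSection(_Strict):
    gaussian_kernel: int = 11
    block_size: int = 51
    offset: float = 5.0
    canny_low: float = 50.0
    canny_high: float = 150.0


class DatasetSection(_Strict):
    ratio: float = 0.8
    overrides: dict[str, list[int]] = Field(default_factory=dict)
    augment_train: bool = True
    augment_test: bool = True


class ModelSection(_Strict):
    fc_units: int = 1024
    pool_grid: list[int] = Field(default_factory=lambda: [1, 1])
    width_multiplier: float = 1.0


class LossSection(_Strict):
    name: str = "wsoftmax"
    gamma: float = 1.0
    guard: bool = True


class SWASection(_Strict):
    enabled: bool = True
    start_epoch: int = 1
    cycle_steps: int | None = None
    alpha1: float = 0.1
    alpha2: float = 0.05
    n_cycles: int = 10


class TrainingSection(_Strict):
    batch_size: int = 32
    base_lr: float = 0.1
    weight_decay: float = 1.0e-4
    momentum: float = 0.9
    epochs: int = 100
    train_resolution: int | None = None   # optional downscale before the net


class RunConfig(_Strict):
    seed: int = 0
    generator: GeneratorSection = Field(default_factory=GeneratorSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    dataset: DatasetSection = Field(default_factory=DatasetSection)
    model: ModelSection = Field(default_factory=ModelSection)
    loss: LossSection = Field(default_factory=LossSection)
    swa: SWASection = Field(default_factory=SWASection)
    training: TrainingSection = Field(default_factory=TrainingSection)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
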