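"""Experiment configuration: a versioned, fully serializable schema.

A saved config re-runs to identical results (all randomness is derived from
the seeds it carries). Loaded from YAML; validation errors report field
paths via pydantic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

SCHEMA_VERSION = 1


class CohortConfig(BaseModel):
    n_participants: int = Field(14, ge=1)
    n_days: int = Field(6, ge=2)
    seed: int = 0
    truncate_one: bool = True


class PreprocessingConfig(BaseModel):
    split_fraction: float = Field(0.1666, gt=0.0, lt=0.5)


class ModelConfig(BaseModel):
    cell: str = "rnn"
    dilated: bool = False
    integrations: list[str] = ["none", "cat"]
    static_subset: str = "six"  # 'six' or 'all'
    grid_layers: list[int] = [3]
    grid_units: list[int] = [16]
    quantile_head: bool = False

    @field_validator("cell")
    @classmethod
    def _cell(cls, v: str) -> str:
        if v not in ("rnn", "gru", "lstm"):
            raise ValueError("cell must be rnn, gru or lstm")
        return v

    @field_validator("integrations")
    @classmethod
    def _integrations(cls, v: list[str]) -> list[str]:
        bad = [x for x in v if x not in ("none", "init", "cat", "both")]
        if bad:
            raise ValueError(f"unknown integration strategies: {bad}")
        return v

    @field_validator("static_subset")
    @classmethod
    def _subset(cls, v: str) -> str:
        if v not in ("six", "all"):
            raise ValueError("static_subset must be 'six' or 'all'")
        return v


class TrainingConfig(BaseModel):
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = Field(256, ge=1)
    epochs: int = Field(25, ge=0)
    n_seeds: int = Field(3, ge=1)
    base_seed: int = 0


class ProtocolConfig(BaseModel):
    horizons_min: list[int] = [30, 60, 120]
    windows: list[str] = ["full_day", "night"]

    @field_validator("horizons_min")
    @classmethod
    def _h(cls, v: list[int]) -> list[int]:
        bad = [x for x in v if x not in (30, 60, 120)]
        if bad:
            raise ValueError(f"horizons must be 30/60/120 min, got {bad}")
        return v

    @field_validator("windows")
    @classmethod
    def _w(cls, v: list[str]) -> list[str]:
        bad = [x for x in v if x not in ("full_day", "night")]
        if bad:
            raise ValueError(f"unknown windows: {bad}")
        return v


class ExperimentConfig(BaseModel):
    """Top-level experiment description.

    The default sizes (one small grid point, 25 epochs) are a fast profile
    for laptop/CI runs; the full study grid is the ``paper_profile``.
    """

    schema_version: int = SCHEMA_VERSION
    cohort: CohortConfig = CohortConfig()
    preprocessing: PreprocessingConfig = PreprocessingConfig()
    model: ModelConfig = ModelConfig()
    training: TrainingConfig = TrainingConfig()
    protocols: ProtocolConfig = ProtocolConfig()
    output_dir: str = "glucast_run"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def paper_profile() -> ExperimentConfig:
    """The full hyperparameter grid of the study: depth {3,5} x width
    {16,32}, 200 epochs, three seeds."""
    cfg = ExperimentConfig()
    cfg.model.grid_layers = [3, 5]
    cfg.model.grid_units = [16, 32]
    cfg.training.epochs = 200
    return cfg


__all__ = [
    "SCHEMA_VERSION",
    "CohortConfig",
    "PreprocessingConfig",
    "ModelConfig",
    "TrainingConfig",
    "ProtocolConfig",
    "ExperimentConfig",
    "paper_profile",
]
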