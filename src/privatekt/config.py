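"""Run configuration: validated schema, YAML loading, derived quantities.

The schema is versioned and fail-loud: unknown keys are rejected so a
typo in an experiment file cannot silently fall back to a default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .ldp import beta_for_budget

__all__ = ["DataConfig", "PartitionConfig", "RunConfig", "SuiteConfig", "load_config", "load_suite"]

SCHEMA_VERSION = 1


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DataConfig(_StrictModel):
    """Synthetic-task shape: a class-conditional Gaussian mixture."""

    n_samples: int = Field(default=2000, ge=2)
    n_classes: int = Field(default=10, ge=2)
    n_features: int = Field(default=8, ge=1)
    separation: float = Field(default=3.0, ge=0)
    pool_fraction: float = Field(default=0.2, gt=0, lt=1)
    n_test: int = Field(default=2000, ge=1)


class PartitionConfig(_StrictModel):
    scheme: Literal["iid", "class_noniid", "size_noniid", "mixed_noniid"] = "class_noniid"
    alpha: float = Field(default=0.5, gt=0)
    sigma: float = Field(default=1.0, ge=0)


class RunConfig(_StrictModel):
    """Everything one simulated run needs; the single source of truth.

    ``epsilon`` is the total per-round privacy budget (nats) and ``k`` the
    number of knowledge-transfer samples answered per client per round; the
    keep probability beta is always derived from them, never set directly.
    """

    schema_version: int = SCHEMA_VERSION
    method: Literal["privatekt", "fedavg", "centrain"] = "privatekt"
    seed: int = 0
    rounds: int = Field(default=30, ge=1)
    n_clients: int = Field(default=10, ge=1)
    client_fraction: float = Field(default=1.0, gt=0, le=1)
    local_epochs: int = Field(default=5, ge=1)
    lr: float = Field(default=0.05, gt=0)
    hidden: int = Field(default=32, ge=0)

    epsilon: float = 5.0
    k: int = Field(default=2, ge=1)
    use_ldp: bool = True

    buffer_size: Optional[int] = Field(default=None, ge=1)
    selftrain_m: int = Field(default=5, ge=0)
    finetune_epochs: int = Field(default=20, ge=1)
    selftrain_epochs: int = Field(default=1, ge=1)
    use_buffer: bool = True
    use_importance_sampling: bool = True
    use_selftrain: bool = True

    fedavg_clip: float = Field(default=1.0)
    fedavg_epsilon: Optional[float] = None

    data: DataConfig = DataConfig()
    partition: PartitionConfig = PartitionConfig()

    @field_validator("epsilon")
    @classmethod
    def _epsilon_nonnegative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("epsilon must be >= 0")
        return v

    @field_validator("fedavg_clip")
    @classmethod
    def _clip_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("fedavg_clip must be > 0")
        return v

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"schema_version must be {SCHEMA_VERSION}")
        pool_size = int(self.data.pool_fraction * self.data.n_samples)
        if self.k > pool_size:
            raise ValueError(f"k={self.k} exceeds the public pool size {pool_size}")
        if self.selftrain_m > pool_size:
            raise ValueError(
                f"selftrain_m={self.selftrain_m} exceeds the public pool size {pool_size}"
            )
        return self

    @property
    def beta(self) -> float:
        return beta_for_budget(self.epsilon, self.k, self.data.n_classes)

    @property
    def buffer_capacity(self) -> int:
        # default: ten rounds' worth of records
        return self.buffer_size if self.buffer_size is not None else 10 * self.k


class SuiteConfig(_StrictModel):
    """A named set of run variants, each replicated with derived seeds."""

    name: str
    replications: int = Field(default=5, ge=1)
    seed: int = 0
    variants: dict[str, RunConfig]

    @model_validator(mode="after")
    def _nonempty(self) -> "SuiteConfig":
        if not self.variants:
            raise ValueError("suite must define at least one variant")
        return self


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return RunConfig.model_validate(raw)


def load_suite(path: str | Path) -> SuiteConfig:
    return SuiteConfig.model_validate(yaml.safe_load(Path(path).read_text()))
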