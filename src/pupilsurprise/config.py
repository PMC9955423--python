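"""Pipeline configuration: every knob with a default, unknown keys rejected."""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .synthetic import CohortConfig, PupilModel

__all__ = ["AnalysisConfig", "PathsConfig", "PipelineConfig", "load_config"]


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    family_size: int = Field(default=4, ge=1)
    critical_window: tuple[int, int] = (10, 19)
    odds_threshold: float = Field(default=10.0, gt=1.0)
    cell_sided: Literal["one", "two"] = "two"
    comparison_sided: Literal["one", "two"] = "one"
    norm_scope: Literal["condition", "pooled", "child"] = "condition"


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input_dir: str | None = None  # read existing tables instead of simulating
    output_dir: str = "results"


class PipelineConfig(BaseModel):
    """Full configuration of a simulate -> model -> analyze run."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    epsilon: float = Field(default=0.1, ge=0.0, lt=1.0)  # evidence noise
    eta: float = Field(default=0.1, ge=0.0, lt=1.0)  # response noise
    log_base: float = Field(default=math.e, gt=1.0)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    pupil_model: PupilModel = Field(default_factory=PupilModel)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)


def load_config(path: Path | str | None = None, **overrides) -> PipelineConfig:
    """Build a PipelineConfig from an optional YAML file plus overrides.

    Unknown keys are rejected with the offending key named (pydantic's
    extra="forbid" reporting).
    """
    data = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is not None:
            if not isinstance(raw, dict):
                raise ValueError(f"config file {path} must hold a mapping")
            data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
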