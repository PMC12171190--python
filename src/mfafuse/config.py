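"""Run configuration: schema, validation, defaults, provenance."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError

__all__ = ["RunConfig", "parse_config", "resolve_config", "write_provenance"]

SCHEMA_VERSION = 1


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSection(_Section):
    method: Literal["minmax", "zscore"] = "zscore"
    calibrate: bool = True


class EncoderSection(_Section):
    preset: Optional[Literal["paper"]] = None
    levels: int = Field(default=4, ge=1)
    base_channels: int = Field(default=8, ge=1)
    kernel_size: int = 3
    channel_growth: int = Field(default=2, ge=1)

    @field_validator("kernel_size")
    @classmethod
    def _odd(cls, v: int) -> int:
        if v % 2 == 0 or v < 1:
            raise ValueError(f"must be odd and positive, got {v}")
        return v


class AttentionSection(_Section):
    residual: bool = True


class DfrsSection(_Section):
    enabled: bool = True
    saliency_weighting: bool = True
    context_refinement: bool = True


class FusionSection(_Section):
    baseline: Literal["none", "laplacian"] = "none"
    laplacian_levels: int = Field(default=3, ge=1)


class TrainSection(_Section):
    lr: float = Field(default=1e-4, gt=0)
    warmup_epochs: int = Field(default=5, ge=0)
    max_epochs: int = Field(default=100, ge=1)
    early_stop_patience: int = Field(default=10, ge=1)
    batch_size: int = Field(default=16, ge=1)
    loss_dice: float = Field(default=0.5, ge=0)
    loss_ce: float = Field(default=0.5, ge=0)
    postprocess_min_size: int = Field(default=0, ge=0)


class EvalSection(_Section):
    threshold: float = Field(default=0.5, gt=0, lt=1)


class SimulateSection(_Section):
    height: int = Field(default=64, ge=16)
    width: int = Field(default=64, ge=16)
    n_modalities: int = Field(default=2, ge=1)
    structure: Literal["branching", "blob"] = "branching"
    contrast: float = Field(default=0.8, gt=0, le=1)
    noise_sigma: float = Field(default=0.05, ge=0)
    complementary: bool = True
    n_train: int = Field(default=8, ge=1)
    n_val: int = Field(default=2, ge=1)


class RunConfig(_Section):
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    preprocess: PreprocessSection = PreprocessSection()
    encoder: EncoderSection = EncoderSection()
    attention: AttentionSection = AttentionSection()
    dfrs: DfrsSection = DfrsSection()
    fusion: FusionSection = FusionSection()
    train: TrainSection = TrainSection()
    eval: EvalSection = EvalSection()
    simulate: SimulateSection = SimulateSection()


def _format_errors(exc: ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(part) for part in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def resolve_config(raw: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid configuration — {_format_errors(exc)}") from exc


def parse_config(path: Path | str | None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration; ``None`` gives
    the full default configuration."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration root must be a mapping, got {type(raw).__name__}")
    return resolve_config(raw)


def write_provenance(out_dir: Path | str, config: RunConfig, seed: int) -> None:
    """Record the fully-resolved config, seed, and package version beside
    a run's outputs so it can be reproduced bit-identically."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.model_dump(), sort_keys=True))
    (out / "provenance.json").write_text(
        json.dumps({"package": "mfafuse", "version": __version__, "seed": seed}, indent=2)
    )
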