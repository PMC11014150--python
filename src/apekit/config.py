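"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults equal the published constants of the method (6 s epochs, 187.5 /
500 mg trigger with a 5 s window, 120 min non-wear limit, 22.5 mg sedentary
gate, 150-350 mg / 8-13 steps / 1.6 steadiness walking criteria, 11.6 / 30 /
73.9 degree posture cut-points, 1436 min day-wear tolerance, 10 reference
settings, 4 valid days). The serialized config plus its hash goes into every
run report so results stay reproducible.
"""

from __future__ import annotations

import hashlib
import json
import pathlib

import pydantic
import yaml

from .errors import ConfigError


class TriggerConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    arm_threshold_mg: float = pydantic.Field(187.5, gt=0)
    confirm_threshold_mg: float = pydantic.Field(500.0, gt=0)
    confirm_window_s: float = pydantic.Field(5.0, gt=0)


class WalkingConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    mad_min_mg: float = pydantic.Field(150.0, gt=0)
    mad_max_mg: float = pydantic.Field(350.0, gt=0)
    steps_min: int = pydantic.Field(8, ge=0)
    steps_max: int = pydantic.Field(13, ge=0)
    steadiness_max: float = pydantic.Field(1.6, gt=0)


class CutpointConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    stand_sit: float = pydantic.Field(11.6, gt=0)
    sit_recline: float = pydantic.Field(30.0, gt=0)
    recline_lie: float = pydantic.Field(73.9, gt=0)


class StepConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    band_low_hz: float = pydantic.Field(0.5, gt=0)
    band_high_hz: float = pydantic.Field(3.0, gt=0)
    refractory_s: float = pydantic.Field(0.25, gt=0)
    prominence_mg: float = pydantic.Field(100.0, gt=0)


class ValidityConfig(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    min_wear_min: float = pydantic.Field(1436.0, gt=0, le=1440.0)
    min_reference_settings: int = pydantic.Field(10, ge=0)
    min_valid_days: int = pydantic.Field(4, ge=1)


class RunConfig(pydantic.BaseModel):
    """Complete pipeline configuration; defaults are the published values."""

    model_config = pydantic.ConfigDict(extra="forbid")

    epoch_s: float = pydantic.Field(6.0, gt=0)
    min_sample_fraction: float = pydantic.Field(0.9, gt=0, le=1.0)
    sb_gate_mg: float = pydantic.Field(22.5, gt=0)
    nonwear_limit_min: float = pydantic.Field(120.0, gt=0)
    backfill_reference: bool = False
    trigger: TriggerConfig = pydantic.Field(default_factory=TriggerConfig)
    walking: WalkingConfig = pydantic.Field(default_factory=WalkingConfig)
    cutpoints: CutpointConfig = pydantic.Field(default_factory=CutpointConfig)
    steps: StepConfig = pydantic.Field(default_factory=StepConfig)
    validity: ValidityConfig = pydantic.Field(default_factory=ValidityConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        try:
            return cls(**data)
        except pydantic.ValidationError as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
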