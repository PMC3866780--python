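"""Run configuration: schema-validated YAML/JSON, bundled study defaults.

Unknown keys are rejected (``extra="forbid"``) so a typo in a config file
fails loudly before any computation. The three study compounds and their
dose regimens ship as a bundled fixture (``data/compounds.yaml``).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .longrange import DoseRegimen
from .parameters import CompoundParameters, ReportedPeaks

__all__ = [
    "CompoundConfig",
    "RegimenConfig",
    "ShortRangeConfig",
    "LongRangeConfig",
    "RunConfig",
    "load_config",
    "default_config",
    "config_hash",
]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ReportedPeaksConfig(_StrictModel):
    cmax_pre: Optional[float] = None
    tmax_pre: Optional[float] = None
    cmax_refined: Optional[float] = None
    tmax_refined: Optional[float] = None


class CompoundConfig(_StrictModel):
    """One substance; units explicit in the field names."""

    name: str
    t_half_gi_min: float = Field(gt=0)
    t_half_plasma_min: float = Field(gt=0)
    dissolution_time_min: float = Field(gt=0)
    cmax_exp_ng_ml: float = Field(gt=0)
    cmax_exp_sd_ng_ml: float = Field(gt=0)
    tmax_exp_min: float = Field(gt=0)
    reported: ReportedPeaksConfig = Field(default_factory=ReportedPeaksConfig)

    def to_parameters(self) -> CompoundParameters:
        return CompoundParameters(
            name=self.name,
            t_half_gi=self.t_half_gi_min,
            t_half_plasma=self.t_half_plasma_min,
            dissolution_time=self.dissolution_time_min,
            cmax_exp=self.cmax_exp_ng_ml,
            cmax_exp_sd=self.cmax_exp_sd_ng_ml,
            tmax_exp=self.tmax_exp_min,
            reported=ReportedPeaks(**self.reported.model_dump()),
        )


class RegimenConfig(_StrictModel):
    dose_amount_ug_ml: float = Field(ge=0, default=0.49)
    period_h: float = Field(gt=0, default=24.0)
    pulse_shape: Literal["rectangular", "bolus"] = "rectangular"
    pulse_width_h: float = Field(gt=0, default=0.5)
    dissolution_scale: float = Field(gt=0, default=1.0)

    def to_regimen(self) -> DoseRegimen:
        return DoseRegimen(
            dose_amount=self.dose_amount_ug_ml,
            period=self.period_h,
            pulse_shape=self.pulse_shape,
            pulse_width=self.pulse_width_h,
            dissolution_scale=self.dissolution_scale,
        )


class ShortRangeConfig(_StrictModel):
    t_end_min: float = Field(gt=0, default=30.0)
    dt_min: float = Field(gt=0, default=0.01)


class LongRangeConfig(_StrictModel):
    horizon_periods: float = Field(ge=5, default=15.0)
    dt_h: float = Field(gt=0, default=0.01)
    burn_in_cycles: int = Field(ge=1, default=10)


class SyntheticConfig(_StrictModel):
    n_observations: int = Field(ge=4, default=25)
    t_min_min: float = Field(gt=0, default=0.1)
    t_max_min: float = Field(gt=0, default=30.0)
    noise_type: Literal["multiplicative_gaussian", "additive_gaussian"] = (
        "multiplicative_gaussian"
    )
    cv_or_sd: float = Field(ge=0, default=0.05)


class RunConfig(_StrictModel):
    """Full pipeline configuration."""

    compounds: list[CompoundConfig]
    regimens: dict[str, RegimenConfig] = Field(default_factory=dict)
    shortrange: ShortRangeConfig = Field(default_factory=ShortRangeConfig)
    longrange: LongRangeConfig = Field(default_factory=LongRangeConfig)
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    strategy: Literal["output_scale", "slow_elimination"] = "output_scale"
    seed: int = 0

    @model_validator(mode="after")
    def _regimen_names_known(self) -> "RunConfig":
        names = {c.name for c in self.compounds}
        unknown = set(self.regimens) - names
        if unknown:
            raise ValueError(f"regimens reference unknown compounds: {sorted(unknown)}")
        return self


def default_config() -> RunConfig:
    """The bundled study configuration (three compounds, their regimens)."""
    text = resources.files("cyclopk.data").joinpath("compounds.yaml").read_text()
    return _from_mapping(yaml.safe_load(text))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    raw = Path(path).read_text()
    data = yaml.safe_load(raw)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return _from_mapping(data)


def _from_mapping(data: dict) -> RunConfig:
    return RunConfig.model_validate(data)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalized config, for output provenance."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
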