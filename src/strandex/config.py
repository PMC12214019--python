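"""Validated experiment configuration (YAML -> pydantic models).

Concentrations are accepted in nM (the units the assays are quoted in)
and converted to molar internally; all rates are SI (M^-1 s^-1, s^-1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from .optics import ExcitationPattern, OpticsModel
from .presets import PRESETS

__all__ = ["OpticsConfig", "PatternConfig", "SimulateConfig", "load_simulate_config"]

NM_TO_M = 1e-9


class OpticsConfig(BaseModel):
    total_intensity: float = Field(1000.0, ge=0)
    leakage: float = Field(0.08, ge=0, lt=0.5)
    read_noise_sd: float = Field(15.0, ge=0)
    shot_noise: bool = True
    bleach_rate_donor: float = Field(0.0, ge=0)
    bleach_rate_acceptor: float = Field(0.0, ge=0)
    background_green: float = Field(0.0, ge=0)
    background_red: float = Field(0.0, ge=0)
    flow_background_step: float = Field(0.0, ge=0)

    def build(self) -> OpticsModel:
        return OpticsModel(**self.model_dump())


class PatternConfig(BaseModel):
    mode: Literal["continuous_green", "alex"] = "alex"
    frame_time: float = Field(0.050, gt=0)
    alex_green: int = Field(10, ge=1)
    alex_dark: int = Field(1, ge=0)
    alex_red: int = Field(10, ge=1)

    def build(self) -> ExcitationPattern:
        return ExcitationPattern(**self.model_dump())


class SimulateConfig(BaseModel):
    """One simulation run: a preset plus condition and optics overrides."""

    preset: str
    concentrations_nM: list[float] = Field(default_factory=list)
    n_molecules: int = Field(..., ge=1)
    seed: int = 0
    horizon_s: float = Field(3600.0, gt=0)
    flow_start_s: float = Field(0.0, ge=0)
    movie_times_s: Optional[list[float]] = None
    movie_duration_s: float = Field(2.0, gt=0)
    optics: OpticsConfig = OpticsConfig()
    pattern: PatternConfig = PatternConfig()

    @field_validator("preset")
    @classmethod
    def _known_preset(cls, v: str) -> str:
        if v not in PRESETS:
            raise ValueError(
                f"unknown preset {v!r}; available: {', '.join(sorted(PRESETS))}"
            )
        return v

    @field_validator("concentrations_nM")
    @classmethod
    def _nonnegative(cls, v: list[float]) -> list[float]:
        if any(c < 0 for c in v):
            raise ValueError("concentrations must be >= 0")
        return v

    @property
    def concentrations_M(self) -> list[float]:
        return [c * NM_TO_M for c in self.concentrations_nM]


def load_simulate_config(path) -> SimulateConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return SimulateConfig.model_validate(raw)
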