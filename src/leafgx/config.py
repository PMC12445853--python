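"""Run configuration: schema, named scenarios and YAML loading."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .constants import EnvironmentState, PhotoConstants, ValidationError

__all__ = ["EnvBlock", "RunConfig", "load_config", "NAMED_SCENARIOS"]

#: Reference growth environment of the bundled scenarios: temperate,
#: unstressed (25 degC, VPD 1 kPa, 400 ppm CO2, PPFD 800, sea level).
REFERENCE_ENV = dict(temp_c=25.0, vpd=1000.0, ca_ppm=400.0, ppfd=800.0,
                     patm=101325.0)

#: Named step-change scenarios: a doubling of ambient CO2 and of VPD.
NAMED_SCENARIOS = {
    "co2_doubling": (REFERENCE_ENV, {**REFERENCE_ENV, "ca_ppm": 800.0}),
    "vpd_doubling": (REFERENCE_ENV, {**REFERENCE_ENV, "vpd": 2000.0}),
}


class EnvBlock(BaseModel):
    """Environment block of a run configuration (VPD in Pa)."""

    model_config = ConfigDict(extra="forbid")

    temp_c: float
    vpd: float
    ca_ppm: float
    ppfd: float = 800.0
    patm: float = 101325.0

    def to_state(self) -> EnvironmentState:
        return EnvironmentState(**self.model_dump())


class RunConfig(BaseModel):
    """Validated scenario-run configuration."""

    model_config = ConfigDict(extra="forbid")

    scenario: Literal["co2_doubling", "vpd_doubling", "custom"]
    env0: Optional[EnvBlock] = None
    env1: Optional[EnvBlock] = None
    constants_overrides: dict[str, float | str] = Field(default_factory=dict)
    output_dir: str = "leafgx_output"
    seed: int = 0               # reserved; the engine is deterministic
    report_precision: int = 4

    @model_validator(mode="after")
    def _check_envs(self) -> "RunConfig":
        if self.scenario == "custom":
            if self.env0 is None or self.env1 is None:
                raise ValueError("custom scenario requires explicit env0 and env1")
        elif self.env0 is not None or self.env1 is not None:
            raise ValueError(
                f"named scenario {self.scenario!r} forbids env0/env1 blocks")
        return self

    def environments(self) -> tuple[EnvironmentState, EnvironmentState]:
        if self.scenario == "custom":
            return self.env0.to_state(), self.env1.to_state()
        e0, e1 = NAMED_SCENARIOS[self.scenario]
        return EnvironmentState(**e0), EnvironmentState(**e1)

    def constants(self) -> PhotoConstants:
        return PhotoConstants().with_overrides(self.constants_overrides)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a mapping")
    return RunConfig.model_validate(raw)
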