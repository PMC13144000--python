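"""Scenario configuration: loading, validation, defaults, serialization.

A scenario is a YAML (or JSON) document with an ``economic`` block holding
the calibration parameters, an optional ``cohort`` block for the burden
estimate, the list of ``risks`` for the calibration table, and optional
``dynamics`` / ``policy`` settings.  Unknown keys are rejected by name; a
bundled ``australia.yaml`` fixture carries the reference Australian
calibration so the package runs end to end with no external data.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .burden import CohortSpec
from .calibration import EconomicInputs

__all__ = [
    "ConfigError",
    "DynamicsSettings",
    "SweepSettings",
    "PolicySettings",
    "ScenarioConfig",
    "load_scenario",
    "dump_scenario",
    "bundled_scenario_path",
]

_REQUIRED_KEYS = ("economic", "risks")


class ConfigError(ValueError):
    """A scenario file failed to parse or validate."""


class DynamicsSettings(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    x0: float = Field(default=0.5, ge=0, le=1, description="initial cooperator share")
    horizon: float = Field(default=10.0, gt=0, description="simulated time span")
    n_points: int = Field(default=201, ge=2, description="time-grid resolution")


class SweepSettings(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    parameter: str
    start: float
    stop: float
    n: int = Field(default=101, ge=2)


class PolicySettings(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")

    subsidy: float = Field(default=0.0, ge=0, description="subsidy applied in dynamics, AUD")
    sweep: Optional[SweepSettings] = None


class ScenarioConfig(BaseModel):
    """Validated scenario with all defaults resolved."""

    model_config = ConfigDict(frozen=True, extra="forbid")

    economic: EconomicInputs
    risks: list[float] = Field(min_length=1, description="risk levels, one table row each")
    cohort: Optional[CohortSpec] = None
    dynamics: DynamicsSettings = DynamicsSettings()
    policy: PolicySettings = PolicySettings()
    conversion_rate: float = Field(default=0.71, gt=0, description="foreign currency per AUD")

    def model_post_init(self, __context) -> None:
        for r in self.risks:
            if not (0 <= r <= 1):
                raise ValueError(f"risks entries must lie in [0, 1], got {r!r}")


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Load and validate a YAML/JSON scenario file.

    Raises
    ------
    ConfigError
        On parse failure, missing/unknown keys, or invariant violations —
        always naming the offending key or value.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read scenario file {path}: {exc}") from exc
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"scenario file {path} is not valid YAML/JSON: {exc}") from exc
    if raw is None:
        raise ConfigError(
            f"scenario file {path} is empty; required keys: {', '.join(_REQUIRED_KEYS)}"
        )
    if not isinstance(raw, dict):
        raise ConfigError(f"scenario file {path} must be a mapping at top level")
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(
            f"invalid scenario {path}: {_format_validation_error(exc)}"
        ) from exc


def dump_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Serialize a scenario back to YAML (lossless round-trip)."""
    data = config.model_dump(exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def bundled_scenario_path() -> Path:
    """Path of the bundled Australian reference scenario."""
    return Path(importlib.resources.files("sungame").joinpath("data/australia.yaml"))
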