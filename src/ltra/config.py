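"""Schema-validated run configuration.

A scenario is a single flat YAML document.  Unknown keys are errors, not
warnings: a silently ignored typo in, say, ``savings_fraction`` would
corrupt a policy conclusion.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cost_model import AgeCostProfile, InflationModel, Intervention
from .errors import ConfigError
from .population import generate_profile
from .schemes import SchemeConfig

__all__ = ["SimulationConfig", "load_config", "config_hash"]


class ProfileSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shape: Literal["log_linear", "table"] = "log_linear"
    c0: float = 1720.0
    a0: int = 40
    beta: float = 0.02
    costs: dict[int, float] | None = None
    age_range: tuple[int, int] = (0, 100)

    def build(self) -> AgeCostProfile:
        if self.shape == "table":
            if not self.costs:
                raise ConfigError("table profile needs a costs mapping")
            return generate_profile("table", {"costs": self.costs}, self.age_range)
        return generate_profile(
            "log_linear", {"c0": self.c0, "a0": self.a0, "beta": self.beta}, self.age_range
        )


class SchemeSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kind: Literal["one_year", "long_term", "both"] = "both"
    horizons: list[tuple[int, int]] = Field(default_factory=lambda: [(70, 10), (80, 5)])
    terminal_horizon: int = 1
    payment_onset_lag: int = Field(default=2, ge=1)
    discount_rate: float = Field(default=0.0, gt=-1.0)

    def build(self, kind: str) -> SchemeConfig:
        return SchemeConfig(
            kind=kind,  # type: ignore[arg-type]
            horizon_rule=tuple((int(a), int(h)) for a, h in self.horizons),
            terminal_horizon=self.terminal_horizon,
            payment_onset_lag=self.payment_onset_lag,
            discount_rate=self.discount_rate,
        )

    @property
    def kinds(self) -> list[str]:
        return ["one_year", "long_term"] if self.kind == "both" else [self.kind]


class InterventionSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    year: int = Field(default=1, ge=1)
    cost_multiplier: float = Field(default=2.0, ge=0.0)
    savings_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    cost_onset_lag: int = Field(default=1, ge=1)
    payment_onset_lag: int = Field(default=2, ge=1)

    @model_validator(mode="after")
    def _lags(self) -> "InterventionSection":
        if self.payment_onset_lag < self.cost_onset_lag:
            raise ValueError("payment_onset_lag must be >= cost_onset_lag")
        return self

    def build(self) -> Intervention:
        return Intervention(
            year=self.year,
            cost_multiplier=self.cost_multiplier,
            savings_fraction=self.savings_fraction,
            cost_onset_lag=self.cost_onset_lag,
            payment_onset_lag=self.payment_onset_lag,
        )


class PopulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=1000, ge=1)
    age_range: tuple[int, int] = (25, 65)
    shock_sigma: float = Field(default=0.2, ge=0.0)
    switch_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    exit_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    eligible_rate: float = Field(default=0.3, ge=0.0, le=1.0)
    window: int = Field(default=10, ge=1)
    # multiplies group-B risk by exp(shift): nonzero makes prediction error
    # correlate with the observable group label (the selection alternative)
    group_risk_shift: float = 0.0


class SimulationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    profile: ProfileSection = Field(default_factory=ProfileSection)
    inflation: float = Field(default=0.03, gt=-1.0)
    scheme: SchemeSection = Field(default_factory=SchemeSection)
    intervention: InterventionSection = Field(default_factory=InterventionSection)
    population: PopulationSection = Field(default_factory=PopulationSection)
    seed: int = Field(default=0, ge=0)

    def inflation_model(self) -> InflationModel:
        return InflationModel(self.inflation)


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a YAML scenario file; raise ConfigError listing offenders."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        return SimulationConfig.model_validate(raw)
    except ValidationError as exc:
        keys = sorted({".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()})
        raise ConfigError(f"invalid config keys: {', '.join(keys)}\n{exc}") from exc


def config_hash(config: SimulationConfig) -> str:
    """Stable hash of the validated configuration, for run logs."""
    import hashlib

    blob = config.model_dump_json()
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
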