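"""Expected-cost dynamics for a single enrollee.

An enrollee's expected annual healthcare cost is driven by two multiplicative
forces: an age gradient (older enrollees cost more on average, read off an
:class:`AgeCostProfile`) and health-cost inflation (a constant annual rate,
:class:`InflationModel`; general price inflation is ignored so that payments
are comparable across years).  A health investment (:class:`Intervention`)
perturbs this path: it multiplies the intervention-year cost by ``kappa`` and
removes a fraction ``sigma`` of the *originally expected* cost in every year
from ``cost_onset_lag`` years after the intervention onward.

All money is in euros and kept at full floating precision; rounding to whole
euros happens only at report time (:mod:`ltra.reporting`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import AgeRangeError, ContractError, GrowthCalibrationError

__all__ = [
    "AgeCostProfile",
    "InflationModel",
    "CostTrajectory",
    "Intervention",
    "expected_cost",
    "baseline_trajectory",
    "apply_intervention",
    "annuity_sum",
    "calibrate_growth",
]


@dataclass(frozen=True)
class AgeCostProfile:
    """Base-year expected annual cost (euros) by integer age.

    Lookups outside ``valid_age_range`` raise :class:`AgeRangeError`; the
    profile never extrapolates silently.
    """

    base_year: int
    costs: Mapping[int, float]
    valid_age_range: tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.costs:
            raise ContractError("profile needs at least one age")
        ages = sorted(int(a) for a in self.costs)
        if self.valid_age_range is None:
            object.__setattr__(self, "valid_age_range", (ages[0], ages[-1]))
        lo, hi = self.valid_age_range
        for a in range(lo, hi + 1):
            if a not in self.costs:
                raise ContractError(f"profile has a gap at age {a}")
        for a, c in self.costs.items():
            if not np.isfinite(c) or c < 0:
                raise ContractError(f"cost at age {a} must be finite and >= 0, got {c}")

    def cost_at(self, age: int) -> float:
        lo, hi = self.valid_age_range
        if not (lo <= age <= hi):
            raise AgeRangeError(f"age {age} outside valid range [{lo}, {hi}]")
        return float(self.costs[age])

    @classmethod
    def from_csv(cls, path: str | Path, base_year: int = 0) -> "AgeCostProfile":
        """Read a two-column ``age,cost`` CSV with a header row."""
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["age", "cost"]:
            raise ContractError(f"expected columns age,cost; got {list(df.columns)}")
        return cls(base_year=base_year, costs={int(a): float(c) for a, c in zip(df["age"], df["cost"])})

    def to_csv(self, path: str | Path) -> None:
        lo, hi = self.valid_age_range
        pd.DataFrame(
            {"age": list(range(lo, hi + 1)), "cost": [self.costs[a] for a in range(lo, hi + 1)]}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class InflationModel:
    """Constant annual health-cost inflation rate (fraction per year)."""

    annual_rate: float = 0.03

    def __post_init__(self) -> None:
        if not self.annual_rate > -1:
            raise ContractError(f"inflation rate must exceed -1, got {self.annual_rate}")

    def factor(self, years: int) -> float:
        return (1.0 + self.annual_rate) ** years


TrajectoryLabel = Literal["baseline", "intervention", "reassessed"]


@dataclass(frozen=True)
class CostTrajectory:
    """Per-year expected expenditures for one enrollee over a horizon."""

    start_year: int
    values: tuple[float, ...]
    enrollee_age_at_start: int
    label: TrajectoryLabel = "baseline"

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ContractError("trajectory must cover at least one year")
        if any(v < 0 or not np.isfinite(v) for v in self.values):
            raise ContractError("trajectory values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def horizon(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def total(self) -> float:
        return float(np.sum(self.values))


@dataclass(frozen=True)
class Intervention:
    """A health investment in year ``year`` (1-based within the horizon).

    ``cost_multiplier`` (kappa) scales the intervention-year expenditure;
    ``savings_fraction`` (sigma) of the originally expected cost is saved in
    every year from ``cost_onset_lag`` years after the intervention onward.
    Under annual reassessment the scheme only reduces payments from
    ``payment_onset_lag`` years after the intervention.
    """

    year: int = 1
    cost_multiplier: float = 2.0
    savings_fraction: float = 0.3
    cost_onset_lag: int = 1
    payment_onset_lag: int = 2

    def __post_init__(self) -> None:
        if self.cost_multiplier < 0:
            raise ContractError("cost multiplier must be >= 0")
        if not 0.0 <= self.savings_fraction <= 1.0:
            raise ContractError("savings fraction must lie in [0, 1]")
        if not self.payment_onset_lag >= self.cost_onset_lag >= 1:
            raise ContractError("need payment_onset_lag >= cost_onset_lag >= 1")
        if self.year < 1:
            raise ContractError("intervention year is 1-based and must be >= 1")


def expected_cost(
    profile: AgeCostProfile,
    age: int,
    year_offset: int,
    inflation: InflationModel,
) -> float:
    """Expected cost ``year_offset`` years ahead for an enrollee aged ``age`` now.

    The enrollee ages along the profile while costs inflate:
    ``profile[age + offset] * (1 + pi) ** offset``.
    """
    if not float(year_offset).is_integer():
        raise ContractError(f"year offset must be an integer, got {year_offset}")
    year_offset = int(year_offset)
    return profile.cost_at(age + year_offset) * inflation.factor(year_offset)


def baseline_trajectory(
    profile: AgeCostProfile,
    start_age: int,
    horizon: int,
    inflation: InflationModel,
    start_year: int = 0,
) -> CostTrajectory:
    """Expected-cost path over ``horizon`` years with no intervention."""
    if horizon < 1:
        raise ContractError("horizon must be >= 1")
    values = tuple(expected_cost(profile, start_age, t, inflation) for t in range(horizon))
    return CostTrajectory(
        start_year=start_year,
        values=values,
        enrollee_age_at_start=start_age,
        label="baseline",
    )


def apply_intervention(baseline: CostTrajectory, iv: Intervention) -> CostTrajectory:
    """Expenditure path when the insurer finances the intervention.

    Year ``T`` costs ``kappa`` times the baseline; from ``T + cost_onset_lag``
    onward a fraction ``sigma`` of the baseline cost is saved; years strictly
    between are unchanged.  Savings apply to originally expected (baseline)
    costs, not to any realized post-shock path.
    """
    if baseline.label != "baseline":
        raise ContractError("intervention applies to a baseline trajectory")
    if iv.year > len(baseline):
        raise ContractError(f"intervention year {iv.year} outside horizon {len(baseline)}")
    t_iv = iv.year - 1  # 0-based index
    values = list(baseline.values)
    values[t_iv] = iv.cost_multiplier * baseline.values[t_iv]
    for t in range(t_iv + iv.cost_onset_lag, len(values)):
        values[t] = (1.0 - iv.savings_fraction) * baseline.values[t]
    return replace(baseline, values=tuple(values), label="intervention")


def annuity_sum(first_cost: float, growth: float, horizon: int) -> float:
    """Sum of a geometric annuity: sum_{t=0}^{H-1} first_cost * (1+g)^t."""
    if horizon < 1:
        raise ContractError("horizon must be >= 1")
    q = 1.0 + growth
    if q == 1.0:  # includes growth so small that 1+g rounds to 1
        return first_cost * horizon
    return first_cost * (q**horizon - 1.0) / (q - 1.0)


_G_LO, _G_HI = -0.99, 10.0


def calibrate_growth(first_cost: float, horizon_total: float, horizon: int) -> float:
    """Constant effective growth rate g whose H-year annuity hits a given total.

    Used to reconstruct a cost path consistent with a printed multi-year total
    when the underlying age-cost table is not available.  Solves
    ``annuity_sum(first_cost, g, H) == horizon_total`` by bracketed root
    finding to 1e-8 relative tolerance.
    """
    if horizon < 2:
        raise ContractError("calibration needs a horizon of at least 2 years")
    if not horizon_total > 0 or not first_cost > 0:
        raise ContractError("first cost and horizon total must be positive")

    def f(g: float) -> float:
        return annuity_sum(first_cost, g, horizon) - horizon_total

    f_lo, f_hi = f(_G_LO), f(_G_HI)
    if f_lo == 0.0:
        return _G_LO
    if f_lo * f_hi > 0:
        raise GrowthCalibrationError(
            f"total {horizon_total} not attainable with g in ({_G_LO}, {_G_HI}) "
            f"for first cost {first_cost} over {horizon} years"
        )
    g = brentq(f, _G_LO, _G_HI, xtol=1e-12, rtol=1e-10)
    return float(g)
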