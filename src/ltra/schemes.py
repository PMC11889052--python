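"""Payment engines for morbidity-based risk adjustment.

Two allocation mechanisms are implemented:

* **one-year** — the classical scheme: every year the insurer receives the
  enrollee's *reassessed* expected cost for that year.  Payments therefore
  track health improvements (with a reporting lag), which is exactly what
  removes the insurer's incentive to invest in enrollee health.
* **long-term** — the proposed scheme: at an assessment date the expected
  costs for the next ``H`` years are computed from then-current enrollee
  characteristics and frozen into an :class:`Assessment`.  The insurer then
  receives the scheduled amount each year regardless of subsequent health
  changes, so cost savings from successful interventions stay with it.

``H`` is age-dependent (default 10 years, 5 above age 70, 1 above age 80) to
avoid perverse incentives around end-of-life spending.  When an enrollee
switches insurer mid-horizon, a fresh assessment is issued for the receiving
insurer and the departing insurer settles the difference between the new and
the old expectations over the remaining years (:func:`switch_settlement`),
which makes switching financially neutral in expectation for both sides.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .cost_model import (
    AgeCostProfile,
    CostTrajectory,
    InflationModel,
    Intervention,
    expected_cost,
)
from .errors import ContractError

__all__ = [
    "SchemeConfig",
    "Assessment",
    "PaymentStream",
    "SettlementRecord",
    "EnrolleeHistory",
    "horizon_for_age",
    "reassessed_expectations",
    "one_year_payments",
    "long_term_assessment",
    "switch_settlement",
    "scheme_payment_stream",
]

SchemeKind = Literal["one_year", "long_term"]

#: Default age-dependent horizon rule: (age threshold, horizon for ages <= threshold).
#: Thresholds are exclusive upward ("older than 70"), so age 70 still gets 10 years.
DEFAULT_HORIZON_RULE: tuple[tuple[int, int], ...] = ((70, 10), (80, 5))


@dataclass(frozen=True)
class SchemeConfig:
    """Which allocation mechanism to run and its horizon/lag conventions."""

    kind: SchemeKind = "long_term"
    horizon_rule: tuple[tuple[int, int], ...] = DEFAULT_HORIZON_RULE
    terminal_horizon: int = 1  # horizon for ages above the last threshold
    payment_onset_lag: int = 2  # one-year kind: years after T at which payments fall
    discount_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("one_year", "long_term"):
            raise ContractError(f"unknown scheme kind {self.kind!r}")
        rule = tuple(sorted((int(a), int(h)) for a, h in self.horizon_rule))
        object.__setattr__(self, "horizon_rule", rule)
        horizons = [h for _, h in rule] + [self.terminal_horizon]
        if any(h < 1 for h in horizons):
            raise ContractError("every horizon must be >= 1")
        if any(h2 > h1 for h1, h2 in itertools.pairwise(horizons)):
            raise ContractError("horizons must be nonincreasing in age")


def horizon_for_age(config: SchemeConfig, age: int) -> int:
    """Assessment horizon for an enrollee of the given age (integer years).

    Thresholds are exclusive: age 70 maps to the 10-year horizon, 71 to 5.
    """
    if age < 0:
        raise ContractError("age must be >= 0")
    for threshold, horizon in config.horizon_rule:
        if age <= threshold:
            return horizon
    return config.terminal_horizon


@dataclass(frozen=True)
class Assessment:
    """A frozen schedule of annual allocations issued at an assessment date.

    Once issued the schedule is immutable: subsequent health changes do not
    alter the payments within the horizon.
    """

    assessment_year: int
    horizon: int
    scheduled_payments: tuple[float, ...]
    basis: dict = field(default_factory=dict, compare=False)
    assessment_id: str = ""

    def __post_init__(self) -> None:
        if len(self.scheduled_payments) != self.horizon:
            raise ContractError("schedule length must equal the horizon")


@dataclass(frozen=True)
class SettlementRecord:
    """Transfer settled when an enrollee leaves an insurer mid-horizon.

    ``transfer = sum(new_expected - old_scheduled)`` over the remaining
    years; positive means the departing insurer pays the scheme (the
    enrollee's risk went up while it was responsible), negative means the
    scheme pays the departing insurer.
    """

    switch_year: int
    remaining_years: int
    old_scheduled: tuple[float, ...]
    new_expected: tuple[float, ...]
    transfer: float


@dataclass(frozen=True)
class PaymentStream:
    """Per-year payments over a simulation window plus their provenance."""

    payments: tuple[float, ...]
    kind: SchemeKind
    provenance: tuple[str, ...] = ()
    settlements: tuple[SettlementRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.provenance and len(self.provenance) != len(self.payments):
            raise ContractError("one provenance entry per payment year")

    def __len__(self) -> int:
        return len(self.payments)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.payments, dtype=float)

    def total(self) -> float:
        return float(np.sum(self.payments))

    def settlement_total(self) -> float:
        """Net transfer paid by the insurer to the scheme (positive = paid)."""
        return float(sum(s.transfer for s in self.settlements))


def reassessed_expectations(baseline: CostTrajectory, iv: Intervention | None) -> CostTrajectory:
    """Expected-cost path as the scheme sees it under annual reassessment.

    The scheme learns about the intervention's effect with a lag: expected
    costs (hence one-year payments) fall only from ``payment_onset_lag``
    years after the intervention year.  The kappa premium is the insurer's
    own expense and never enters the payment basis.
    """
    if iv is None:
        return replace(baseline, label="reassessed")
    values = list(baseline.values)
    for t in range((iv.year - 1) + iv.payment_onset_lag, len(values)):
        values[t] = (1.0 - iv.savings_fraction) * baseline.values[t]
    return replace(baseline, values=tuple(values), label="reassessed")


def one_year_payments(expected_path: CostTrajectory, window: int) -> PaymentStream:
    """Classical scheme: payment each year equals that year's reassessed expected cost."""
    if window > len(expected_path):
        raise ContractError(f"window {window} exceeds trajectory length {len(expected_path)}")
    start = expected_path.start_year
    return PaymentStream(
        payments=tuple(expected_path.values[:window]),
        kind="one_year",
        provenance=tuple(f"reassess-y{start + t}" for t in range(window)),
    )


def long_term_assessment(
    baseline: CostTrajectory,
    assessment_year: int,
    config: SchemeConfig,
    assessment_id: str = "A0",
) -> Assessment:
    """Freeze the next H years of expected costs into a payment schedule.

    ``H`` follows the age-dependent horizon rule evaluated at the enrollee's
    age on the assessment date.
    """
    offset = assessment_year - baseline.start_year
    if offset < 0:
        raise ContractError("assessment predates the trajectory")
    age_at_assessment = baseline.enrollee_age_at_start + offset
    horizon = horizon_for_age(config, age_at_assessment)
    if offset + horizon > len(baseline):
        raise ContractError(
            f"horizon {horizon} from year {assessment_year} exceeds trajectory of length {len(baseline)}"
        )
    return Assessment(
        assessment_year=assessment_year,
        horizon=horizon,
        scheduled_payments=tuple(baseline.values[offset : offset + horizon]),
        basis={"age": age_at_assessment, "label": baseline.label},
        assessment_id=assessment_id,
    )


def switch_settlement(
    old: Assessment,
    new_expected_remaining: Sequence[float],
    switch_year: int,
) -> SettlementRecord:
    """Settle a mid-horizon insurer switch against the scheme.

    ``r = H - years elapsed`` years of the old schedule remain; the departing
    insurer pays (receives) the amount by which the fresh expectation exceeds
    (falls short of) the frozen schedule over those years.  The receiving
    insurer's new assessment is unaffected.
    """
    elapsed = switch_year - old.assessment_year
    if not 1 <= elapsed <= old.horizon:
        raise ContractError(
            f"switch year {switch_year} not within the horizon issued at {old.assessment_year}"
        )
    remaining = old.horizon - elapsed
    new_expected = tuple(float(v) for v in new_expected_remaining)
    if len(new_expected) != remaining:
        raise ContractError(
            f"need {remaining} remaining-year expectations, got {len(new_expected)}"
        )
    old_tail = old.scheduled_payments[elapsed:]
    transfer = float(sum(n - o for n, o in zip(new_expected, old_tail)))
    return SettlementRecord(
        switch_year=switch_year,
        remaining_years=remaining,
        old_scheduled=old_tail,
        new_expected=new_expected,
        transfer=transfer,
    )


@dataclass
class EnrolleeHistory:
    """Everything the payment engines need about one insurer-enrollee pair.

    ``risk_multipliers[y]`` is the morbidity multiplier *observable at an
    assessment made in year y* (the scheme's then-current information);
    expectations formed in year y scale the age/inflation baseline by it.
    Switches and exit are calendar events within the simulation window.
    """

    profile: AgeCostProfile
    inflation: InflationModel
    start_age: int
    window: int
    start_year: int = 0
    risk_multipliers: np.ndarray | None = None
    switch_years: frozenset[int] = frozenset()
    exit_year: int | None = None

    def __post_init__(self) -> None:
        if self.risk_multipliers is None:
            self.risk_multipliers = np.ones(self.window)
        self.risk_multipliers = np.asarray(self.risk_multipliers, dtype=float)
        if len(self.risk_multipliers) < self.window:
            raise ContractError("need one risk multiplier per simulated year")
        if np.any(self.risk_multipliers <= 0) or not np.all(np.isfinite(self.risk_multipliers)):
            raise ContractError("risk multipliers must be finite and positive")
        bad = [y for y in self.switch_years if not (self.start_year < y < self.start_year + self.window)]
        if bad:
            raise ContractError(f"switch years {bad} outside the simulation window")

    def forward_expectation(self, year: int, horizon: int) -> tuple[float, ...]:
        """H-year expected-cost vector as assessed in ``year``."""
        offset0 = year - self.start_year
        mult = float(self.risk_multipliers[offset0])
        return tuple(
            mult * expected_cost(self.profile, self.start_age, offset0 + t, self.inflation)
            for t in range(horizon)
        )

    def age_in(self, year: int) -> int:
        return self.start_age + (year - self.start_year)


def scheme_payment_stream(
    config: SchemeConfig,
    history: EnrolleeHistory,
    window: int | None = None,
) -> PaymentStream:
    """Compose assessments, reassessments and settlements over a window.

    Every simulated year gets exactly one payment.  Under the long-term kind
    a running schedule is honored to completion even across age thresholds;
    a fresh assessment is issued at horizon expiry or at a switch (after
    settling).  After an exit the remaining schedule is cancelled and settled
    at zero expected cost.
    """
    window = history.window if window is None else window
    if window > history.window:
        raise ContractError("window exceeds the history's coverage")

    if config.kind == "one_year":
        payments, provenance = [], []
        for t in range(window):
            year = history.start_year + t
            if history.exit_year is not None and year >= history.exit_year:
                payments.append(0.0)
                provenance.append("exited")
            else:
                payments.append(history.forward_expectation(year, 1)[0])
                provenance.append(f"reassess-y{year}")
        return PaymentStream(tuple(payments), "one_year", tuple(provenance))

    payments: list[float] = [0.0] * window
    provenance: list[str] = ["exited"] * window
    settlements: list[SettlementRecord] = []
    counter = itertools.count()

    year = history.start_year
    end = history.start_year + window
    current: Assessment | None = None
    while year < end:
        if history.exit_year is not None and year >= history.exit_year:
            break
        if current is None:
            horizon = horizon_for_age(config, history.age_in(year))
            current = Assessment(
                assessment_year=year,
                horizon=horizon,
                scheduled_payments=history.forward_expectation(year, horizon),
                basis={"age": history.age_in(year)},
                assessment_id=f"A{next(counter)}",
            )
        t = year - history.start_year
        payments[t] = current.scheduled_payments[year - current.assessment_year]
        provenance[t] = current.assessment_id
        year += 1
        ends_now = year - current.assessment_year >= current.horizon
        exits_now = history.exit_year is not None and year >= history.exit_year
        if exits_now:
            # death/exit: remaining scheduled payments are cancelled with no
            # cash settlement; the stream's provenance stays "exited"
            current = None
        elif year in history.switch_years and not ends_now:
            remaining = current.horizon - (year - current.assessment_year)
            new_expected = history.forward_expectation(year, remaining)
            settlements.append(switch_settlement(current, new_expected, year))
            current = None  # receiving insurer gets a fresh assessment next loop
        elif ends_now:
            current = None

    return PaymentStream(tuple(payments), "long_term", tuple(provenance), tuple(settlements))
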