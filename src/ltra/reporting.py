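"""Report assembly: euro rounding, worked-example streams, summaries, plots.

Everything monetary is carried at full float precision through the engines
and rounded to whole euros (half away from zero, the style of the printed
examples) only here.  The JSON summary layouts are pydantic models; their
JSON Schema is available via ``model_json_schema()`` and every summary the
package writes is validated by constructing the model.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .incentives import intervention_npv, ledger
from .population import ScenarioFixture
from .schemes import one_year_payments, reassessed_expectations

__all__ = [
    "round_euros",
    "ExampleSummary",
    "worked_example",
    "trajectories_to_frame",
    "plot_example",
]


def round_euros(x: float) -> int:
    """Round to whole euros, half away from zero (1.5 -> 2, -1.5 -> -2)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


class ExampleSummary(BaseModel):
    """Cumulative totals of the worked example under both schemes (whole euros)."""

    model_config = ConfigDict(extra="forbid")

    fixture: str
    horizon: int
    baseline_total: int
    intervention_cost_total: int
    payment_total_one_year: int
    payment_total_long_term: int
    surplus_one_year: int
    surplus_long_term: int
    npv_one_year: int
    npv_long_term: int


def trajectories_to_frame(baseline, intervention=None) -> pd.DataFrame:
    """Tidy export of cost trajectories: year, baseline_cost, intervention_cost."""
    n = len(baseline)
    data = {"year": np.arange(1, n + 1), "baseline_cost": baseline.as_array()}
    if intervention is not None:
        data["intervention_cost"] = intervention.as_array()
    return pd.DataFrame(data)


def worked_example(fixture: ScenarioFixture) -> tuple[pd.DataFrame, ExampleSummary]:
    """Run one enrollee through both schemes, with and without the intervention.

    Returns the per-year streams (baseline cost, post-intervention cost,
    one-year payments, long-term payments) and the euro-rounded summary.
    The one-year payments track the reassessed expected costs with the
    payment lag; the long-term payments are the frozen baseline schedule.
    """
    base = fixture.baseline()
    iv = fixture.calibrated_intervention()
    costs_iv = fixture.intervention_path()
    pay_oy = one_year_payments(reassessed_expectations(base, iv), fixture.horizon)
    pay_lt = base.as_array()  # frozen schedule equals the assessment-date expectations

    led_oy = ledger(pay_oy, costs_iv, scheme_kind="one_year", scenario_id=fixture.name)
    led_lt = ledger(pay_lt, costs_iv, scheme_kind="long_term", scenario_id=fixture.name)

    streams = trajectories_to_frame(base, costs_iv)
    streams["payment_one_year"] = pay_oy.as_array()
    streams["payment_long_term"] = pay_lt

    summary = ExampleSummary(
        fixture=fixture.name,
        horizon=fixture.horizon,
        baseline_total=round_euros(base.total()),
        intervention_cost_total=round_euros(costs_iv.total()),
        payment_total_one_year=round_euros(pay_oy.total()),
        payment_total_long_term=round_euros(float(pay_lt.sum())),
        surplus_one_year=round_euros(led_oy.cumulative_surplus),
        surplus_long_term=round_euros(led_lt.cumulative_surplus),
        npv_one_year=round_euros(intervention_npv(fixture.scheme("one_year"), base, iv)),
        npv_long_term=round_euros(intervention_npv(fixture.scheme("long_term"), base, iv)),
    )
    return streams, summary


def plot_example(streams: pd.DataFrame, path: str | Path) -> None:
    """Two-panel figure: annual reassessment vs frozen ten-year schedule."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    year = streams["year"]
    for ax, pay_col, title in (
        (axes[0], "payment_one_year", "One-year risk adjustment"),
        (axes[1], "payment_long_term", "Long-term risk adjustment"),
    ):
        ax.plot(year, streams["baseline_cost"], color="tab:green", label="expected cost, no intervention")
        ax.plot(year, streams["intervention_cost"], color="tab:blue", label="cost with intervention")
        ax.plot(year, streams[pay_col], "k:", label="payments to insurer")
        ax.set_title(title)
        ax.set_xlabel("year")
    axes[0].set_ylabel("euros")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
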