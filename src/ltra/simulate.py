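"""Population Monte-Carlo: run both payment schemes over a synthetic cohort.

Each enrollee carries a latent morbidity multiplier drawn with mean one.
The multiplier materializes after the first simulated year: realized costs
and any reassessment from year 1 onward scale the age/inflation baseline by
it, while an assessment made at entry still prices the enrollee at
multiplier one.  Under annual reassessment payments therefore track costs
exactly; under the frozen long-term schedule the gap between priced and
realized morbidity becomes insurer surplus (or loss), settled against the
scheme when the enrollee switches insurer mid-horizon.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig, config_hash
from .cost_model import baseline_trajectory, expected_cost
from .incentives import intervention_npv, selection_diagnostics
from .population import Enrollee, generate_population
from .schemes import EnrolleeHistory, SchemeConfig, horizon_for_age, scheme_payment_stream

__all__ = ["SimulationResult", "run_simulation", "write_outputs"]

_REVEAL_YEAR = 1  # morbidity observed from the second simulated year on


@dataclass
class SimulationResult:
    ledgers: pd.DataFrame
    npv: pd.DataFrame
    diagnostics: dict
    seed: int
    config_digest: str


def _history(enrollee: Enrollee, profile, inflation, window: int) -> EnrolleeHistory:
    mult = np.ones(window)
    mult[_REVEAL_YEAR:] = enrollee.risk_multiplier
    switches = frozenset({enrollee.switch_year} if enrollee.switch_year else set())
    return EnrolleeHistory(
        profile=profile,
        inflation=inflation,
        start_age=enrollee.age_at_entry,
        window=window,
        risk_multipliers=mult,
        switch_years=switches,
        exit_year=enrollee.exit_year,
    )


def _realized_costs(enrollee: Enrollee, profile, inflation, window: int) -> np.ndarray:
    costs = np.array(
        [expected_cost(profile, enrollee.age_at_entry, t, inflation) for t in range(window)]
    )
    costs[_REVEAL_YEAR:] *= enrollee.risk_multiplier
    if enrollee.exit_year is not None:
        costs[enrollee.exit_year:] = 0.0
    return costs


def run_simulation(config: SimulationConfig, seed: int | None = None) -> SimulationResult:
    """Run the configured cohort through the selected scheme(s)."""
    seed = config.seed if seed is None else seed
    profile = config.profile.build()
    inflation = config.inflation_model()
    pop_cfg = config.population
    window = pop_cfg.window

    enrollees = generate_population(
        n=pop_cfg.n,
        seed=seed,
        shock_sigma=pop_cfg.shock_sigma,
        switch_rate=pop_cfg.switch_rate,
        age_range=tuple(pop_cfg.age_range),
        window=window,
        eligible_rate=pop_cfg.eligible_rate,
        exit_rate=pop_cfg.exit_rate,
    )
    if pop_cfg.group_risk_shift != 0.0:
        factor = math.exp(pop_cfg.group_risk_shift)
        enrollees = [
            Enrollee(
                enrollee_id=e.enrollee_id,
                age_at_entry=e.age_at_entry,
                risk_multiplier=e.risk_multiplier * (factor if e.group == "B" else 1.0),
                group=e.group,
                switch_year=e.switch_year,
                exit_year=e.exit_year,
                intervention_eligible=e.intervention_eligible,
            )
            for e in enrollees
        ]

    kinds = config.scheme.kinds
    schemes = {k: config.scheme.build(k) for k in kinds}
    iv = config.intervention.build()

    rows, npv_rows = [], []
    for e in enrollees:
        hist = _history(e, profile, inflation, window)
        costs = _realized_costs(e, profile, inflation, window)
        for kind in kinds:
            stream = scheme_payment_stream(schemes[kind], hist)
            paid = stream.settlement_total()
            total_pay = stream.total()
            rows.append(
                {
                    "enrollee_id": e.enrollee_id,
                    "group": e.group,
                    "scheme": kind,
                    "age_at_entry": e.age_at_entry,
                    "total_payment": total_pay,
                    "settlement_paid": paid,
                    "total_cost": float(costs.sum()),
                    "surplus": total_pay - paid - float(costs.sum()),
                    "prediction_error": total_pay - float(costs.sum()),
                    "n_settlements": len(stream.settlements),
                    "switched": e.switch_year is not None,
                }
            )
        npv_row = {"enrollee_id": e.enrollee_id, "age_at_entry": e.age_at_entry}
        lt_cfg = schemes.get("long_term") or SchemeConfig(kind="long_term")
        horizon = horizon_for_age(lt_cfg, e.age_at_entry)
        base = baseline_trajectory(profile, e.age_at_entry, horizon, inflation)
        for kind in ("one_year", "long_term"):
            cfg = schemes.get(kind) or config.scheme.build(kind)
            npv_row[f"npv_{kind}"] = intervention_npv(cfg, base, iv)
        npv_rows.append(npv_row)

    ledgers = pd.DataFrame(rows)
    npv = pd.DataFrame(npv_rows)

    diagnostics: dict = {"seed": seed, "n": pop_cfg.n, "schemes": {}}
    for kind in kinds:
        sub = ledgers[ledgers["scheme"] == kind]
        entry = {
            "mean_surplus": float(sub["surplus"].mean()),
            "total_payments": float(sub["total_payment"].sum()),
            "total_settlements_paid": float(sub["settlement_paid"].sum()),
            "n_settlement_records": int(sub["n_settlements"].sum()),
        }
        group_sizes = sub.groupby("group").size()
        if len(group_sizes) >= 2 and (group_sizes >= 2).all():
            entry["selection"] = asdict(selection_diagnostics(sub))
        diagnostics["schemes"][kind] = entry

    return SimulationResult(
        ledgers=ledgers,
        npv=npv,
        diagnostics=diagnostics,
        seed=seed,
        config_digest=config_hash(config),
    )


def write_outputs(result: SimulationResult, outdir: str | Path, plots: bool = False) -> list[Path]:
    """Write ledgers CSV, NPV comparison CSV, diagnostics JSON and the run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    p = outdir / "ledgers.csv"
    result.ledgers.to_csv(p, index=False)
    written.append(p)
    p = outdir / "npv_comparison.csv"
    result.npv.to_csv(p, index=False)
    written.append(p)
    p = outdir / "diagnostics.json"
    p.write_text(json.dumps(result.diagnostics, indent=2, sort_keys=True) + "\n")
    written.append(p)
    p = outdir / "run.log"
    p.write_text(f"config_hash={result.config_digest}\nseed={result.seed}\n")
    written.append(p)
    return written
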