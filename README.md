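# ltra — long-term risk adjustment simulator

Morbidity-based risk adjustment pays each social health insurer the expected
annual healthcare cost of its enrollees, which removes the incentive to
cherry-pick low-risk individuals. But because the allocation is recomputed
every year, an insurer that invests in an enrollee's health sees its own
payments fall as soon as the enrollee's expected costs do: the savings are
clawed back by the scheme and prevention does not pay. `ltra` simulates this
mechanism and a long-term alternative in which expected costs are computed
once for an *H*-year horizon (default **H = 10**, reduced to 5 above age 70
and 1 above age 80) and frozen into an immutable payment schedule, so that
cost savings from successful interventions stay with the insurer.

The package is aimed at health economists and policy modellers who want to
explore the incentive properties of capitation payment designs without any
claims data: all inputs are scenario parameters and seeded synthetic
populations.

## Model

For an enrollee aged *a* at assessment, the expected cost *t* years ahead is

```
c_t = profile(a + t) · (1 + π)^t
```

with an age–cost profile and health-cost inflation π (default 3 %/year;
general inflation is ignored). A health investment in year *T* with cost
multiplier κ and savings fraction σ changes the expenditure path to

```
c'_T = κ · c_T,        c'_t = (1 − σ) · c_t   for t ≥ T + cost_onset_lag,
```

savings applying to *originally expected* costs. Under the **one-year
scheme** the payment in year *t* is the then-current reassessed expectation
(reduced from `T + payment_onset_lag` onward, default lag 2). Under the
**long-term scheme** payments follow the frozen schedule `(c_0, …, c_{H−1})`.
The insurer's ledger surplus is `Σ (payment_t − expenditure_t)`, and the
investment NPV is the cumulative surplus with the intervention minus
without it (invest iff NPV > 0). When an enrollee switches insurer after
*k* of *H* years, the departing insurer settles
`Σ_{t=k}^{H−1} (new expectation − old schedule)` with the scheme — positive
means it pays — which makes switching financially neutral in expectation.

## Worked example

The built-in `paper_example` scenario is a 40-year-old whose first-year
expected cost is 1,720 €, with 3 %/year cost inflation, a ten-year horizon
and an intervention in year 1 with κ = 2 and σ = 0.3 (costs fall from year
2, one-year payments from year 3). The cost path is calibrated so the
ten-year baseline total is 23,211 € and the post-intervention total is
19,132 € (see `docs/methods.md` for why the calibration is needed).

```bash
ltra example --fixture paper_example --out out/
```

prints

```json
{
  "fixture": "paper_example",
  "horizon": 10,
  "baseline_total": 23211,
  "intervention_cost_total": 19132,
  "payment_total_one_year": 17906,
  "payment_total_long_term": 23211,
  "surplus_one_year": -1226,
  "surplus_long_term": 4079,
  "npv_one_year": -1226,
  "npv_long_term": 4079
}
```

Reading: without any intervention both schemes are actuarially fair
(payments 23,211 € = costs 23,211 €, surplus 0). With the intervention, the
one-year scheme claws the savings back through reduced payments and the
insurer ends 1,226 € in the red — it will not invest. Under the ten-year
scheme the payments stay at 23,211 € while costs fall to 19,132 €, leaving
a surplus of 4,079 € (the printed inputs are euro-rounded, so 4,079–4,080):
the same intervention is now clearly worthwhile.

Population Monte-Carlo and scheme comparison run from a YAML scenario:

```bash
ltra simulate --config scenario.yaml --seed 7 --out out/
ltra compare  --config scenario.yaml --out out/
```

writing per-enrollee ledgers (CSV), selection diagnostics (JSON) and a
per-enrollee NPV comparison in which `npv_long_term >= npv_one_year` holds
row by row.

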