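# Methods

## Model and mechanism

The simulator works in discrete whole years (reports use "year 1" for the
intervention year; internally offsets are 0-based). An enrollee's expected
annual cost combines an age–cost profile with constant multiplicative
health-cost inflation: `c_t = profile(age + t) · (1 + π)^t`. Profiles map
integer ages to nonnegative euro amounts; any lookup outside the declared
age range is an error — the simulator never extrapolates, and population
runs are sized so no enrollee outlives the profile.

Two allocation mechanisms share this cost model:

* **One-year scheme.** Payments equal the enrollee's reassessed expected
  cost each year. After an intervention the scheme observes the improved
  health state with a lag: expenditures fall `cost_onset_lag` years after
  the intervention year (default 1) while payments fall only after
  `payment_onset_lag` years (default 2). The κ-premium is never part of
  the payment basis.
* **Long-term scheme.** At an assessment date the next *H* years of
  expected costs are frozen into an immutable schedule. *H* depends on age
  at assessment: 10 for age ≤ 70, 5 for 70 < age ≤ 80, 1 above 80
  (thresholds exclusive; "older than 70" does not include 70). A running
  schedule is honored to completion even if the enrollee crosses a
  threshold mid-horizon; the new horizon applies at the next assessment.
  At horizon expiry a fresh assessment is issued from then-current
  characteristics — the minimal consistent rolling rule.

**Switching.** When an enrollee leaves after *k* of *H* years, the receiving
insurer gets a fresh assessment and the departing insurer settles
`Σ (new expectation − old schedule)` over the remaining `H − k` years with
the scheme (positive = departing insurer pays). Because reassessed
expectations are unbiased in the simulation, the transfer has mean zero:
switching is financially neutral in expectation for both sides, which the
test suite checks at 10,000 simulated switches.

**Death/exit.** The remaining schedule is cancelled with no cash transfer
(payments stop, expected remaining costs are zero); the payment stream
flags the cancelled years. A literal cash settlement against a
zero-expectation path would pay the departing insurer the entire remaining
schedule as a lump sum, which would contradict cancellation.

**Investment rule.** The intervention NPV under a scheme is the cumulative
(optionally discounted; default rate 0, matching the undiscounted
comparisons the schemes are designed around) surplus with the intervention
minus without it. Ties resolve to "do not invest". For any κ ≥ 1, σ ≥ 0
with savings extending past the payment lag, `NPV(long_term) ≥
NPV(one_year)`, with equality at H = 1 and at the null intervention — the
property the whole design turns on.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| π | health-cost inflation, /year | 0.03 | standard stylized value of the worked example |
| H rule | horizon by age | 10 / 5 (>70) / 1 (>80) | end-of-life spending breaks the health→savings link |
| κ | intervention-year cost multiplier | 2.0 | worked example |
| σ | savings fraction of original costs | 0.3 | worked example |
| cost lag | years until costs fall | 1 | costs fall from year 2 |
| payment lag | years until one-year payments fall | 2 | payments fall from year 3 |
| σ_shock | lognormal morbidity-shock scale | 0.2 | moderate heterogeneity; mean fixed at 1 |
| switch rate | per-year switching hazard | 0.05 | order of magnitude of annual plan switching in social insurance |
| n, window | cohort size, simulated years | 1000, 10 | one full default horizon |

## Calibration of the worked example

The worked example's ten-year totals rest on an empirical German 2021
age–cost table that is not public. No constant-growth profile combined with
the stated κ = 2, σ = 0.3 and lags reproduces all printed totals
simultaneously: with the baseline total fixed at 23,211 €, a literal σ =
0.3 yields a post-intervention total of 18,483.7 €, not 19,132 €, and a
one-year payment total of ≈17,313 €, not 17,896 €. The package therefore
treats the printed totals as the binding anchors and calibrates two
effective parameters at fixture-build time:

* a constant effective growth rate *g* ≈ 0.0650 (combining ageing and
  inflation) such that the ten-year annuity on 1,720 € sums to 23,211 €,
  found by bracketed root finding (`scipy.optimize.brentq`, 1e-8 relative
  tolerance, bracket g ∈ (−0.99, 10));
* an effective savings fraction σ_eff ≈ 0.2698 (closed form) such that the
  post-intervention path sums to 19,132 €.

σ_eff < 0.3 absorbs the unknown curvature of the true age–cost profile.
The one-year payment total under this calibration is 17,906 € rather than
the printed 17,896 €; the 10 € gap is irreducible without the unpublished
table, so only the arithmetic identities among the printed totals
(23,211 − 19,132 ≈ 4,080 surplus; 17,896 − 19,132 = −1,236 loss) are treated
as checkable, and the reproduced headline quantities (surplus 4,079–4,080 €,
one-year NPV ≈ −1,226 €) agree with them to within the euro-rounding of the
printed inputs.

## Synthetic populations

`generate_population` draws, per enrollee, an entry age (uniform on 25–65
by default), a latent morbidity multiplier (lognormal with mean exactly 1
— positivity plus unbiasedness, which settlement neutrality requires), an
observable group label (fair coin), and geometric switch/exit times. Each
enrollee has a private random substream keyed by (master seed, enrollee
index), so enlarging a population never reshuffles existing enrollees, and
every generated object is a pure function of (parameters, seed).

In the population simulation the multiplier materializes after the first
year: realized costs and any later reassessment scale by it, while the
entry assessment prices the enrollee at multiplier 1. The one-year scheme
then reprices annually (payments track costs exactly — the actuarial
fairness identity), while the long-term scheme's frozen schedule turns the
priced-vs-realized morbidity gap into insurer surplus or loss, settled at
switches. An optional `group_risk_shift` scales one group's multiplier by
`exp(shift)`, making the prediction error correlate with the observable
label — the alternative hypothesis the selection diagnostics must detect.

What the generator does **not** emulate: real claims distributions (heavy
right tails, zero-inflation), serially correlated morbidity, non-geometric
switching behavior, strategic insurer responses, or correlation between
age and switching. Passing tests therefore demonstrate the mechanism's
internal logic — fairness, freezing, neutrality, dominance — not magnitudes
one would observe in administrative data.

## Selection diagnostics

Long-horizon cost prediction is noisier than one-year prediction, but
noise alone does not create selection incentives: only error correlated
with insurer-observable information does. The diagnostics take one row per
enrollee (observable group, realized profit, prediction error) and report
per-group mean profit (group means always aggregate to the overall mean),
their dispersion, and the correlation between the group code and the
error. Under independent errors group mean profits coincide up to Monte
Carlo noise (checked at n = 10,000 within 3 standard errors, fixed seeds);
a shifted group shows up as lower mean profit. These are diagnostics, not
inference — no multiplicity correction is applied.

## Numerical choices

* Money is full-precision float internally; reports round to whole euros,
  half away from zero.
* `calibrate_growth` requires H ≥ 2 and a positive total; a total not
  bracketed by g ∈ (−0.99, 10) raises a calibration error. Growth rates so
  small that 1 + g rounds to 1 fall back to the flat-annuity formula.
* Age thresholds compare integer age at the assessment date; "older than
  70" is strict.
* NPV ties (exactly 0) mean no investment.
* Unknown configuration keys are hard errors; every run log records the
  config hash and seed, making artifacts reproducible byte for byte.

## Problem sizes

Default study sizes: the worked example is a single 10-year enrollee;
fairness is checked over 100 random scenarios; settlement neutrality over
10,000 switches; the population runs use 10,000 enrollees for law-of-large-
numbers checks and 5,000 (window 10) in the acceptance script — sizes at
which the Monte-Carlo standard errors are small relative to the effects of
interest.

## Limitations

* No equilibrium modelling: average allocations across insurers are
  reported, but no claim is made about system-level cost dynamics.
* Risk sharing / high-risk pooling for extreme-cost patients is a named
  extension point (`SchemeConfig` can be subclassed around
  `scheme_payment_stream`), not implemented.
* Partial years, mid-year switching and premium competition are out of
  scope; the switch clock restarts at the receiving insurer's assessment.
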