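# Methods

## Model structure

`calfsim` is a deterministic, daily time-step, energy-allowable-growth
model. The state carried from day to day is minimal: body weight (BW),
cumulative starter NFC intake, and the weaned flag. Each day runs a fixed
pipeline — intake → digestion → requirements → gain — with BW and
cumulative NFC updated at day end (an explicit forward recurrence). The
ordering is a modelling convention: daily predictions do not prescribe a
within-day order, and end-of-day update is the simplest reproducible
choice.

**Stages.** Two equation sets exist: preweaning (milk plus solid feed) and
fully weaned. The weaned set — EBW factor 0.85 instead of 0.91, NEM
coefficient 97.0 instead of 76.9 kcal/kg^0.75, k_m from the dietary-ME
cubic instead of the 0.69 constant — takes over on the first day the milk
allowance is zero at or after the declared weaning age. Step-down plans
that reduce but do not eliminate milk before weaning age therefore remain
on preweaning coefficients, which matches how the stage definitions are
phrased ("fully transitioned to solid feed").

**Energy chain.** NEM and MEm are computed from EBW as in the README. Net
energy for gain is `(ME intake − MEm) · k_g`. The efficiency `k_g` of
converting ME above maintenance into retained energy is not pinned down by
the requirement equations themselves; we use 0.60, a conventional
published value for growing calves, and surface it as a first-class
`Scenario` field plus a logged default so the assumption is always
auditable. EBW gain is the exact algebraic inverse of the retention
relation `RE = gain^1.1 · EBW^0.205`; the forward form is kept in the API
as the inversion oracle (round-trip tested to 1e−9). BW gain is EBW gain
divided by the stage factor — the EBW↔BW mapping is the only bridge the
equation set provides.

**Negative energy balance.** The fractional-power inverse is undefined for
negative NE. We extend it odd-symmetrically:
`gain = −(|NE|/EBW^0.205)^(1/1.1)` for NE < 0, and flag the day
(`negative_balance`) in the record. This permits plausible BW loss under
restrictive plans without inventing a separate mobilization model; it is
the least-surprising smooth extension and is exercised by the starvation
tests.

**Liquid intake.** Offered litres are fully consumed up to 14 L/d, a
ceiling drawn from ad libitum feeding studies. The cap applies to
consumption (an allowance of 20 L records 14 L consumed and costed).
Litres convert to DM via `solids_per_litre`: for whole milk,
DM fraction × 1.03 kg/L density; for milk replacer, the declared mixing
rate (g powder/L). The conversion is a convention of this package — diet
composition is collected but no printed conversion exists.

**Starter intake.** The temperate (≤35 °C) and semitropical (>35 °C)
regressions are implemented exactly as printed, clamped at ≥0 g/d (the
temperate linear form goes negative for small calves in their first days —
a regression artifact, not biology). The switch at 35 °C is strict
(35.0 °C is temperate). `FPstarter`, time since first starter offer, is
measured in **weeks** by default: the declared unit is days, but at day
scale the quadratic term (13.496·FP²) alone reaches ~42 kg/d by day 56,
which no calf eats; at week scale the same coefficients produce intakes
squarely in the observed range. An `fp_unit="days"` switch preserves the
literal reading for anyone wanting it. Starter is first offered on day 3
of age by default (configurable); MEiLD in the regressions is the
current day's liquid ME intake.

**Digestibility maturation and starter ME.** The four digestibility
equations (dCP, dFat, dNDF, dNFC) are linear in ln(cumulative starter NFC
intake) with pelleted/texturized indicator and interaction terms (TMR is
the zero baseline). The logarithm's argument is clamped to [0.1, 15] kg:
the 15-kg ceiling enforces the documented plateau ("digestibility reaches
its maximum" at 15 kg cumulative NFC); the 0.1-kg floor keeps ln finite at
zero intake while leaving first-days digestibility deliberately poor, in
line with the limited fermentative capacity of the immature rumen. Each
digestibility is clamped to [0, 1] after evaluation. Starter ME density
uses the classical summative form
`DE = 4.2·(dNFC·NFC + dNDF·NDF) + 5.6·(dCP·CP) + 9.4·(dFat·Fat) − 0.3`,
`ME = 1.01·DE − 0.45` (Mcal/kg DM, clamped ≥0). These coefficients are a
stated convention of this package, chosen so the computation is
self-contained and testable. NFC is computed by difference,
1 − CP − NDF − fat − ash.

**k_m clamp.** The weaned-stage cubic is only validated over typical
starter energy densities (≈2.9–3.6 Mcal/kg DM). Outside (0, 1] the result
is clamped — upper bound 1.0, lower bound 1e−6 (an open interval cannot be
clamped to; the tiny floor keeps MEm finite) — with a `RuntimeWarning` so
extreme inputs never silently produce nonsense efficiencies.

**Economics and KPIs.** Daily cost = consumed litres × cost/L + starter
as-fed kg × cost/kg (DM intake divided by the starter DM fraction).
Currency is unit-agnostic. KPIs are emitted for two windows — until
weaning (days 1..weaning age, inclusive) and full horizon — because the
inclusive/exclusive convention is genuinely open; both are labelled.
`cost_per_kg_gain` is undefined (None) without positive gain, and
`age_at_15kg_nfc` is None if the trajectory never crosses 15 kg.

## Input validation

Scenario inputs are validated at parse time against the documented
acceptable ranges: initial BW 20–60 kg, temperature −30 to 50 °C, weaning
age 10–120 d, horizon ≤100 d, at most 4 scenarios per comparison. YAML
configuration errors report every violated field at once, with the ranges.

## Assessment module

Observed body weights from multi-study data are regressed on the
simulator's predictions:

    BW_obs = (β₀ + a_study) + β₁·BW_pred + e,
    a_study ~ N(0, σ²_study), e ~ N(0, σ²_res)

fitted by REML (statsmodels MixedLM). A treatment-within-study variance
component is fitted as an additional variance component and tested by a
likelihood-ratio test against the study-only model using the
boundary-corrected 0.5·χ²(0) + 0.5·χ²(1) mixture (the null puts the
variance on the boundary of its parameter space); the component is kept
only when significant at 0.05. Accuracy is judged by Wald tests of β₀ = 0
and β₁ = 1; precision by RMSE, R² and Lin's CCC; cluster similarity by
ICC = σ²_study/(σ²_study + σ²_res).

Conventions where definitions are genuinely open: R² is reported both as
the squared correlation of observed with predicted (marginal) and with the
conditional fitted values; CCC and RMSE are reported both raw and with the
estimated study intercepts (BLUPs) removed. Each observation is one row —
treatment-mean body weights carry no sampling weights.

Degenerate inputs: data in perfect within-study agreement with the
predictions (residual variance ≈ 0) make REML profile likelihoods
unstable, so the fit short-circuits to the exact answer (within-study
slope, intercepts by difference) rather than failing silently. Fewer than
2 studies or 10 pairs is rejected.

## Synthetic data generator

`generate_synthetic_studies` emulates the structure of a multi-study
literature evaluation: by default 27 studies × 3 treatments × 3 body-weight
ages (243 records), with scenario inputs drawn uniformly within
literature-derived ranges — initial BW 34.1–48.9 kg, weaning age 42–90 d,
liquid-diet ME 3.67–5.76 Mcal/kg DM, milk allowance 1–13.5 L/d,
temperature fixed at 20 °C (the customary default when studies do not
report it). The simulator's own trajectory is the truth; observed BW adds
a study-level intercept N(0, σ²_study) and residual N(0, σ²_res), defaults
σ_study = 9 kg and σ_res = 7.5 kg, giving an analytic ICC of
81/137.25 ≈ 0.59 — the regime the assessment machinery is expected to
operate in. Everything is driven by one `numpy` Generator seed.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: real studies differ in breed, health,
housing and measurement protocol, so real "study effects" are neither
Gaussian nor purely additive; real observed weights deviate from the
simulator's curve in structured, diet-dependent ways, whereas here the
simulator is the truth by construction. Recovery tests validate the
statistical machinery (unbiased slope, calibrated CIs, ICC recovery), not
the biological fidelity of the growth model.

## Problem sizes and numerical choices

The parameter-recovery suite uses 200 replicated datasets of 27 × 3 × 3
records each — enough for the Monte Carlo standard error of the mean slope
(~0.001) and of the CI coverage (~1.5 points) to resolve the tested bands,
while keeping the whole suite around a minute. The retention round-trip is
asserted to 1e−9 over a 21 × 14 grid (NE 0–10 Mcal/d, EBW 20–150 kg), and
per-day energy conservation (`ME − MEm = NE/k_g` for non-negative NE) to
1e−9 along every simulated trajectory. The simulator itself is exact
arithmetic composition — no solver, no tolerance, no randomness — so
identical scenarios yield bit-identical trajectories.

## Known limitations

Disease, housing, genetics, heat/cold stress on performance, crude-protein
requirements and water intake are outside the model; ambient temperature
enters only through the starter-equation switch. The starter ME summative
coefficients and `k_g` are stated conventions, not fitted quantities. The
digestibility plateau is enforced exactly at 15 kg; the underlying linear
forms would otherwise keep drifting. Milk-replacer economics assume
cost-per-litre as mixed.
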