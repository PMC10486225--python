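# Methods

## Model structure

The package implements a deterministic population-level cohort Markov model
with an annual cycle and a 10-year horizon. A cohort of index self-harm
admissions — people aged 15+ presenting to hospital after self-harm — enters
at cycle 0, split into age–sex strata that evolve independently (no ageing
across bands over the horizon; the strata are risk classes, not a demographic
projection). Four states:

| state | role | utility |
|---|---|---|
| no self-harm | at-risk pool | 0.64 (95% CI 0.33–0.95) |
| non-fatal repeat self-harm | one-cycle event state; returns to the at-risk pool | 0.54 (95% CI 0.29–0.79) |
| died by suicide | absorbing | 0 |
| died other causes | absorbing | 0 |

Each year, everyone alive faces three exit probabilities: non-fatal repeat
self-harm `p_rep(t)`, suicide `p_sui(t)` (both per-year series shared across
strata, reflecting the declining hazard after an index episode) and
other-cause death `p_oth(s)` (per stratum, constant over the horizon).
Residual mass stays in / returns to the no-self-harm state. Because the repeat
state is a pure event state with the same onward risks as the at-risk pool,
the two alive rows of every transition matrix are identical; no tunnel states
or half-cycle correction are used — the model is intentionally a simple
annual-cycle design, and payoffs are taken at end of cycle.

Both arms are propagated as expectations (counts × row-stochastic matrices),
so persons are conserved exactly and the comparator ("do nothing") trace is
independent of the effect parameters. An individual-level microsimulation in
the test suite serves as an independent oracle for this propagation.

## Intervention effect

The intervention multiplies the odds of repeat self-harm by a pooled odds
ratio (point 0.69, 95% CI 0.55–0.87). Three modelling choices matter:

- **Decay.** Trial evidence covers roughly one year, so the effect is assumed
  to attenuate. Decay acts on the effect scale: the year-*t* treated odds
  ratio is `1 − (1 − OR) · m(t)` with multipliers m = (1, ½, ¼, ⅛, 1/16,
  0, …) in the base case ("50% decay over five years") and (1, 0, 0, …) in
  the conservative one-year scenario. This reproduces both schedules exactly
  at their endpoints and needs no baseline-dependent rescaling.
- **Uptake.** 73.3% of the eligible cohort engages (the published 821/1,120
  service-evaluation fraction). Inside the transition matrices uptake is an
  exact population mixture, `p = u·p_OR + (1 − u)·p_base`; the convenience
  function `effective_odds_ratio` instead folds uptake into the odds-ratio
  scale (`1 − (1 − OR)·m·u`), which agrees exactly at u ∈ {0, 1} and to
  second order in (1 − OR) otherwise.
- **Scope.** By default the odds ratio applies to both the non-fatal repeat
  and the suicide transition (the evaluation models "a lower probability of
  repeated self-harm and subsequent suicide"). Whether the effect should act
  on suicide directly is genuinely open; `settings.effect_on_suicide: false`
  restricts it to the non-fatal transition. Because most modelled savings come
  from averted suicide deaths, this switch moves results substantially.

The intervention never alters other-cause mortality.

## Economics

All monetary quantities are 2018 AUD discounted at 3%/year (`1/(1+r)^t`,
entry year undiscounted); QALYs are discounted identically. Partial societal
perspective: health-sector costs plus the productivity component embedded in
the per-suicide figure; no carer, time or travel costs.

- Intervention cost = entering cohort × uptake × AUD$615 (±20% uniform),
  charged once at cycle 0, undiscounted. Non-uptakers incur no cost.
- Healthcare savings = discounted averted non-fatal repeat events × per
  episode admission cost (event-based, not prevalence-based).
- Suicide-related savings = discounted averted suicide deaths × one of two
  valuations behind a single switch, avoiding double counting: the
  weighted-average cost of a suicide death (AUD$714,681; base case) or the
  value of a statistical life (AUD$4.5M; sensitivity analysis).
- ROI = total savings / intervention cost; strictly > 1 classifies as
  cost-saving. ICER = net cost / incremental QALYs, with `dominant`,
  `dominated` and `undefined` (ΔQALY = 0) flags. NMB = WTP·ΔQALY − ΔCost at
  AUD$50,000/QALY by default.

Sign convention: savings positive, net incremental cost negative when the
intervention is cost-saving; summaries additionally expose `net_savings`
(= −net cost), which keeps point estimates and uncertainty intervals on one
coherent signed scale.

## Uncertainty analysis

The PSA (default 3,000 iterations) samples, per iteration and in fixed order:

| parameter | distribution | why |
|---|---|---|
| odds ratio | lognormal, log-mean ln 0.69, log-sd (ln 0.87 − ln 0.55)/(2·1.96) | standard fit for a ratio with a 95% CI |
| self-harm utility | beta moment-matched to 0.54, sd (0.79 − 0.29)/(2·1.96) | bounded on [0,1] |
| no-self-harm utility | self-harm draw + 0.1 | the two CIs overlap; the joint rule keeps the state ordering in every draw |
| unit cost | uniform 615 × (1 ± 0.2) | the stated ±20% band |
| per-episode cost, per-suicide cost | uniform ±20% | synthetic defaults; same band as the unit cost |

The utility draw is truncated to [0, 1 − 0.1] *before* adding the 0.1 gap, so
the gap is exact and both utilities stay in [0, 1]. Baseline transition
probabilities stay at their point values in the PSA: their uncertainty ranges
are not published with the evaluation being emulated, and inventing spreads
for them would manufacture precision about the dominant driver of results.
Uncertainty intervals are therefore narrower than a fully parameterised PSA
would give.

Randomness uses one root seed spawning a child stream per iteration
(`numpy.random.SeedSequence`), so iteration *i* is reproducible and unchanged
by the total iteration count. Intervals are equal-tailed empirical 2.5/97.5
percentiles. The headline ICER is the ratio of mean ΔCost to mean ΔQALY
(coherently "dominant" even when iterations straddle quadrants); per-iteration
ICERs feed the interval. The probability of cost-effectiveness is the
fraction of iterations with NMB > 0, and the CEAC evaluates that fraction on
a WTP grid.

Scenario analyses are pure overrides of the base configuration: one-year
effect only; VSL valuation; population-norm utility 0.90 for the no-self-harm
state (the utility gap widening accordingly); intervention cost ±20%.

Threshold analyses bisect on the odds ratio of the deterministic model (decay
fixed at the base-case schedule) for two targets: net cost = 0 (end of
cost-saving) and ICER = WTP (end of cost-effectiveness, solved on the smooth
equivalent `net cost − WTP·ΔQALY = 0`). Both objectives are strictly
increasing in the OR, so bisection is exact up to the bracket width; default
tolerance 1e-4 on the OR, 50 iterations maximum, and the reported metric
tolerance is the objective spread over the final bracket. An unbracketed
target (an intervention that is never cost-saving on (0, 1]) returns a
no-solution flag rather than an error.

## Synthetic defaults and what passing tests show

No dataset underlies the model; the synthetic module builds the packaged
configuration:

- **Cohort**: 15+ population 20,000,000 admitted at 113 per 100,000 → 22,600
  index admissions, apportioned over 5 age bands × 2 sexes (weights 0.30,
  0.25, 0.20, 0.17, 0.08; 60% female) by largest remainder, so counts sum
  exactly. Counts are deterministic expectations, matching the
  population-level model.
- **Baseline risks** (*synthetic defaults — not from the evaluation being
  emulated, whose literature-review baselines are unpublished*): year-1
  non-fatal repetition 0.163 and suicide 0.016 — the widely cited 1-year
  post-self-harm review figures — declining geometrically by 0.8/year as a
  declining-hazard shape; other-cause mortality 0.0005–0.02/year by age band
  with a 1.5× male loading.
- **Per-episode admission cost**: AUD$6,000, a plausible national average for
  a self-harm admission (*synthetic default*).

Consequences: the packaged configuration demonstrates the machinery at a
realistic national scale, and ordering results (VSL > base ROI; cost −20% >
base > cost +20%; one-year effect < base QALYs; the cost-saving threshold OR
below the cost-effectiveness threshold OR) are structural and robust. The
*magnitudes* (ROI ≈ 9, ~757 incremental QALYs, thresholds ≈ 0.97) are
functions of the synthetic baselines — in particular the 1.6% year-1 suicide
probability makes averted-suicide savings the dominant term — and do not
reproduce the published headline magnitudes, which depended on unpublished
inputs. Passing tests show the engine, economics and uncertainty machinery
are correct and internally consistent, not that the synthetic defaults equal
the original inputs.

The generator also provides `perturb_parameters` (seeded multiplicative
jitter with clamping and closure repair) for robustness fixtures.

## Numerical notes and limitations

- Probability closure (`p_rep + p_sui + p_oth ≤ 1` per year/stratum) is
  validated at configuration time and re-guarded at propagation time (an OR
  > 1 could in principle break it; protective ORs cannot).
- `or_to_probability` handles p = 1 as its limit (returns 1); negative inputs
  are domain errors.
- ROI with zero intervention cost is undefined and returned as NaN; dominance
  is a flag, never an exception.
- Exact float equality is asserted only where it is structural (seeded
  reproducibility, arm equality under a null effect); the utility gap is
  checked to 1e-12 because float addition is not bitwise-exact.
- Not modelled: ageing across bands, readmission-driven service re-entry,
  individual heterogeneity beyond age–sex strata, carer/family or time/travel
  costs, expected value of perfect information.
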