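# aftercare-cea

Decision-analytic cost-effectiveness modelling of **brief aftercare
interventions** (follow-up contact, care coordination, safety planning)
offered after a hospital-treated self-harm episode.

Prior self-harm is the strongest risk factor for repeat self-harm and suicide.
Brief aftercare reduces the odds of a subsequent episode (pooled OR 0.69,
95% CI 0.55–0.87 across randomised trials), and this package asks the health
economist's question: offered to every eligible hospital-treated patient in a
population, is such a service worth its money? It is aimed at analysts who
build or review return-on-investment (ROI) and cost–utility (CUA) evaluations
of suicide-prevention programmes.

## The model

A population-level Markov cohort model. Index admissions (derived from a
population size and an admission rate of 113 per 100,000 aged 15+) enter as
age–sex strata and transition annually among four states over a 10-year
horizon:

- **no self-harm** (utility 0.64),
- **non-fatal repeat self-harm** (utility 0.54; a one-cycle event state whose
  occupants rejoin the at-risk pool),
- **died by suicide** and **died from other causes** (absorbing, utility 0).

In the intervention arm the fraction taking up the service (73.3%) has its
annual repeat and suicide odds multiplied by an odds ratio whose effect decays
50% per year over the first five years (zero afterwards); the comparator is
"do nothing". For year *t* with decay multiplier *m(t)*, the treated odds
ratio is `1 − (1 − OR)·m(t)`, converted to probabilities via
`p' = OR·p / (1 − p + OR·p)`.

Two result frameworks, both discounted at 3% per annum in 2018 AUD:

- **ROI**: cost-savings (averted non-fatal admissions at a per-episode cost,
  plus averted suicide deaths at the weighted-average cost of a suicide of
  AUD$714,681, or AUD$4.5M VSL in sensitivity analysis) divided by the
  intervention cost (AUD$615 ± 20% per engaged person). ROI > 1 is
  cost-saving.
- **CUA**: incremental cost per QALY gained (ICER, with dominance flags),
  judged against AUD$50,000/QALY; net monetary benefit
  `NMB = WTP·ΔQALY − ΔCost`.

Uncertainty is handled by a 3,000-iteration Monte Carlo probabilistic
sensitivity analysis (lognormal OR, beta utilities constrained to a fixed 0.1
gap between states, uniform ±20% costs), five one-way scenario analyses, and
two bisection threshold analyses that find the odds ratio at which the
intervention stops being cost-saving or cost-effective.

The baseline annual repeat-self-harm and suicide probabilities in the packaged
configuration are clearly-labelled **synthetic defaults** (16.3% and 1.6% in
year 1, declining 20%/year), as is the AUD$6,000 per-episode admission cost;
see `docs/methods.md`.

## Worked example

```
$ aftercare-cea base-case --out results/base
intervention cost AUD$10,187,967; savings AUD$93,322,216; ROI 9.16; incremental QALYs 757.5; ICER dominant
```

Reading: serving the 73.3% of 22,600 admissions who take up the programme
costs AUD$10.2M; discounted savings from averted repeat admissions and suicide
deaths total AUD$93.3M, so every dollar invested returns AUD$9.16 and the
intervention **dominates** doing nothing (cheaper *and* 757 QALYs healthier).
The large ROI is driven by the synthetic baseline suicide risk; with the
published (unavailable) baselines the evaluation this emulates reported a
smaller ROI of the same sign.

```
$ aftercare-cea psa --out results/psa --iterations 200 --seed 1
200 iterations; probability cost-effective at AUD$50,000/QALY: 99.5%

$ aftercare-cea threshold --target icer-at-wtp --out results/thr
OR* = 0.9757 (achieved 50,011.70, target 50,000.00)
```

The threshold run says the odds ratio would have to weaken to 0.976 before
the intervention stopped being cost-effective at AUD$50,000/QALY (it stops
being outright cost-saving already at 0.966 — the cost-saving criterion binds
first). `aftercare-cea scenarios` prints the base case plus the five
sensitivity scenarios as a table and CSV. Python users can do the same via
`aftercare_cea.evaluate_model`, `run_psa`, `run_scenarios` and
`threshold_search` on a `ModelConfig`.

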