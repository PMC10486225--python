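"""Probabilistic sensitivity analysis, scenario analyses and threshold analyses.

The PSA draws every uncertain parameter jointly from its configured
distribution, propagates each draw through the Markov engine and the economic
calculations, and summarises the per-iteration incremental costs, QALYs, ROI
ratios and ICERs with equal-tailed 95% uncertainty intervals (2.5th/97.5th
empirical percentiles). Reproducibility comes from a single root seed spawning
one child random stream per iteration, so the draw of iteration *i* never
depends on how many iterations are requested before or after it.

Scenario analyses are pure overrides of the base configuration; the five named
scenarios mirror the one-way sensitivity analyses of the evaluation (one-year
effect only, VSL valuation of suicide deaths, population-norm utility for the
no-self-harm state, intervention cost ±20%).

Threshold analyses bisect on the odds ratio of the deterministic model until
the intervention stops being cost-saving (net cost = 0) or stops being
cost-effective (ICER equal to the willingness-to-pay threshold).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd

from .economics import (
    EconomicResult,
    ICERFlag,
    evaluate_model,
    icer,
    net_monetary_benefit,
)
from .parameters import ModelConfig, ParameterDraw

__all__ = [
    "PSAResult",
    "ScenarioSpec",
    "ThresholdResult",
    "SCENARIOS",
    "sample_parameters",
    "run_psa",
    "ceac_curve",
    "apply_overrides",
    "scenario_config",
    "run_scenarios",
    "threshold_search",
]

logger = logging.getLogger(__name__)

#: outputs summarised with mean and 95% uncertainty interval
_SUMMARY_COLUMNS = (
    "intervention_cost",
    "total_savings",
    "net_savings",
    "delta_cost",
    "delta_qaly",
    "roi",
    "nmb",
)


def sample_parameters(config: ModelConfig, rng: np.random.Generator) -> ParameterDraw:
    """One joint draw of all uncertain parameters.

    Parameters are drawn in a fixed order. The utility constraint is enforced
    by sampling the self-harm state utility (truncated to
    ``[0, 1 − constraint_delta]``) and setting the no-self-harm utility to that
    value plus ``constraint_delta``, so every draw preserves the configured gap
    and both utilities stay in [0, 1]. Baseline transition probabilities are
    kept at their point values.
    """
    c = config
    odds_ratio = float(c.effect.odds_ratio.sample(rng))
    unit_cost = float(c.costs.intervention_unit_cost.sample(rng))
    hc_cost = float(c.costs.healthcare_cost_per_selfharm_episode.sample(rng))
    suicide_cost = float(c.costs.suicide_death_cost.sample(rng))
    vsl = float(c.costs.vsl.sample(rng))
    delta = c.utilities.constraint_delta
    u_sh = float(np.clip(c.utilities.u_selfharm.sample(rng), 0.0, 1.0 - delta))
    u_no = u_sh + delta

    point = ParameterDraw.point(config)
    return ParameterDraw(
        odds_ratio=odds_ratio,
        uptake=c.effect.uptake,
        unit_cost=unit_cost,
        healthcare_cost_per_episode=hc_cost,
        suicide_death_cost=suicide_cost,
        vsl=vsl,
        u_no_selfharm=u_no,
        u_selfharm=u_sh,
        p_repeat_nonfatal=point.p_repeat_nonfatal,
        p_suicide=point.p_suicide,
        p_other_death=point.p_other_death,
        discount_rate=point.discount_rate,
    )


@dataclass
class PSAResult:
    """Per-iteration records and summaries of one Monte Carlo run."""

    iterations: pd.DataFrame
    summaries: dict[str, dict[str, float]]
    probability_cost_effective: float
    mean_icer: Any  # ICEROutcome of mean Δcost over mean ΔQALY
    seed: int
    wtp: float

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def _iteration_record(draw: ParameterDraw, res: EconomicResult) -> dict[str, float]:
    return {
        "odds_ratio": draw.odds_ratio,
        "unit_cost": draw.unit_cost,
        "healthcare_cost_per_episode": draw.healthcare_cost_per_episode,
        "suicide_death_cost": draw.suicide_death_cost,
        "u_no_selfharm": draw.u_no_selfharm,
        "u_selfharm": draw.u_selfharm,
        "intervention_cost": res.intervention_cost,
        "healthcare_savings": res.healthcare_savings,
        "suicide_cost_savings": res.suicide_cost_savings,
        "total_savings": res.total_savings,
        "delta_cost": res.net_cost,
        "net_savings": res.net_savings,
        "delta_qaly": res.incremental_qalys,
        "roi": res.roi,
        "nmb": res.nmb,
        "icer_flag": res.icer.flag.value,
        "icer_value": np.nan if res.icer.value is None else res.icer.value,
    }


def run_psa(
    config: ModelConfig,
    seed: int | None = None,
    iterations: int | None = None,
) -> PSAResult:
    """Monte Carlo uncertainty analysis over the full model.

    ``seed`` and ``iterations`` default to the config's settings. The same
    seed and config produce bitwise-identical iteration records.
    """
    seed = config.settings.rng_seed if seed is None else seed
    n = config.settings.psa_iterations if iterations is None else iterations
    wtp = config.settings.wtp_threshold

    children = np.random.SeedSequence(seed).spawn(n)
    records = []
    for child in children:
        rng = np.random.default_rng(child)
        draw = sample_parameters(config, rng)
        res = evaluate_model(config, draw)
        records.append(_iteration_record(draw, res))
    frame = pd.DataFrame.from_records(records)
    frame.index.name = "iteration"

    summaries = {
        col: {
            "mean": float(frame[col].mean()),
            "ui_low": float(np.percentile(frame[col], 2.5)),
            "ui_high": float(np.percentile(frame[col], 97.5)),
        }
        for col in _SUMMARY_COLUMNS
    }
    # ICER interval from per-iteration ICERs; the headline ICER is the ratio
    # of mean incremental cost to mean incremental QALYs, which stays coherent
    # ("dominant") even when individual iterations straddle quadrants.
    icer_vals = frame["icer_value"].dropna()
    if len(icer_vals):
        summaries["icer"] = {
            "mean": float(icer_vals.mean()),
            "ui_low": float(np.percentile(icer_vals, 2.5)),
            "ui_high": float(np.percentile(icer_vals, 97.5)),
        }
    prob_ce = float((frame["nmb"] > 0).mean())
    mean_icer = icer(summaries["delta_cost"]["mean"], summaries["delta_qaly"]["mean"])
    return PSAResult(
        iterations=frame,
        summaries=summaries,
        probability_cost_effective=prob_ce,
        mean_icer=mean_icer,
        seed=seed,
        wtp=wtp,
    )


def ceac_curve(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    For each willingness-to-pay value, the fraction of iterations with
    positive net monetary benefit. At WTP 0 this is the fraction of strictly
    cost-saving iterations; as WTP grows it approaches the fraction with
    positive incremental QALYs.
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ValueError("wtp_grid must be non-empty")
    dq = psa.iterations["delta_qaly"].to_numpy()
    dc = psa.iterations["delta_cost"].to_numpy()
    probs = [float(np.mean(w * dq - dc > 0)) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": probs})


# ---------------------------------------------------------------------------
# Scenario analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """A named sparse override of the base configuration."""

    name: str
    description: str
    overrides: dict[str, Any] = field(default_factory=dict)


SCENARIOS: tuple[ScenarioSpec, ...] = (
    ScenarioSpec(
        "one_year_effect",
        "intervention effective in year 1 only (100% decay thereafter)",
        {"effect.decay.mode": "one_year_only"},
    ),
    ScenarioSpec(
        "vsl_valuation",
        "suicide deaths valued at the value of a statistical life",
        {"settings.suicide_valuation": "vsl"},
    ),
    ScenarioSpec(
        "population_norm_utility",
        "no-self-harm utility at the population norm of 0.90",
        {
            "utilities.u_no_selfharm": {"kind": "point", "point_value": 0.90},
            "utilities.constraint_delta": 0.36,
        },
    ),
    ScenarioSpec(
        "cost_minus_20pct",
        "intervention unit cost reduced by 20%",
        {"costs.intervention_unit_cost.point_value": "*0.8"},
    ),
    ScenarioSpec(
        "cost_plus_20pct",
        "intervention unit cost increased by 20%",
        {"costs.intervention_unit_cost.point_value": "*1.2"},
    ),
)


def apply_overrides(config: ModelConfig, overrides: dict[str, Any]) -> ModelConfig:
    """Return a new validated config with dotted-path overrides applied.

    A string value of the form ``"*<factor>"`` multiplies the existing value;
    anything else replaces it. Unknown paths raise ``KeyError``.
    """
    data = config.model_dump(mode="python", exclude_none=True)
    data = copy.deepcopy(data)
    for path, value in overrides.items():
        keys = path.split(".")
        node = data
        for key in keys[:-1]:
            if not isinstance(node, dict) or key not in node:
                raise KeyError(f"unknown parameter path: {path}")
            node = node[key]
        leaf = keys[-1]
        if not isinstance(node, dict) or leaf not in node:
            raise KeyError(f"unknown parameter path: {path}")
        if isinstance(value, str) and value.startswith("*"):
            node[leaf] = node[leaf] * float(value[1:])
        else:
            node[leaf] = value
    return ModelConfig.model_validate(data)


def scenario_config(config: ModelConfig, name: str) -> ModelConfig:
    """The base config with one named scenario applied."""
    for spec in SCENARIOS:
        if spec.name == name:
            return apply_overrides(config, spec.overrides)
    raise KeyError(f"unknown scenario {name!r}")


def run_scenarios(config: ModelConfig) -> pd.DataFrame:
    """Deterministic results for the base case and the five named scenarios."""
    rows = []
    for name, cfg in [("base_case", config)] + [
        (s.name, scenario_config(config, s.name)) for s in SCENARIOS
    ]:
        res = evaluate_model(cfg)
        row = {"scenario": name}
        row.update(
            {
                k: v
                for k, v in res.to_dict().items()
                if k
                in (
                    "intervention_cost",
                    "healthcare_savings",
                    "suicide_cost_savings",
                    "total_savings",
                    "net_cost",
                    "incremental_qalys",
                    "roi",
                    "cost_saving",
                    "icer",
                    "nmb",
                )
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Threshold analyses
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ThresholdResult:
    """Odds ratio at which the intervention stops meeting a value criterion."""

    target: Literal["net_cost_zero", "icer_at_wtp"]
    odds_ratio_star: float
    achieved_metric: float  # net cost (AUD) or ICER (AUD/QALY) at OR*
    target_value: float
    tolerance: float  # bound on |achieved − target| from the final bracket
    iterations_used: int
    bracketed: bool


def _threshold_objective(
    config: ModelConfig, target: str, wtp: float
) -> "tuple[Any, float]":
    """Monotone objective g(OR) with root at the threshold, plus target value."""
    base = ParameterDraw.point(config)

    if target == "net_cost_zero":

        def g(or_: float) -> float:
            return evaluate_model(config, base.with_odds_ratio(or_)).net_cost

        return g, 0.0

    if target == "icer_at_wtp":
        # ICER = wtp  <=>  net_cost − wtp × ΔQALY = 0 (for ΔQALY > 0);
        # this form is smooth through the dominance boundary.
        def g(or_: float) -> float:
            res = evaluate_model(config, base.with_odds_ratio(or_))
            return res.net_cost - wtp * res.incremental_qalys

        return g, wtp

    raise ValueError(f"unknown threshold target {target!r}")


def threshold_search(
    config: ModelConfig,
    target: Literal["net_cost_zero", "icer_at_wtp"],
    tol: float = 1e-4,
    max_iterations: int = 50,
    wtp: float | None = None,
) -> ThresholdResult:
    """Bisect on the odds ratio until a value-for-money criterion binds.

    ``net_cost_zero`` finds the OR at which the intervention stops being
    cost-saving (deterministic net cost crosses zero); ``icer_at_wtp`` finds
    the OR at which the deterministic ICER equals the willingness-to-pay
    threshold. ``tol`` is the bisection tolerance on the odds ratio. The decay
    schedule and all other parameters stay at their configured values.

    Returns a ``ThresholdResult`` with ``bracketed=False`` (and NaN solution)
    when the criterion never binds on (0, 1].
    """
    wtp = config.settings.wtp_threshold if wtp is None else wtp
    g, target_value = _threshold_objective(config, target, wtp)

    lo, hi = 1e-9, 1.0
    g_lo, g_hi = g(lo), g(hi)
    if not (g_lo < 0.0 <= g_hi):
        logger.warning("threshold target %s not bracketed on (0, 1]", target)
        return ThresholdResult(
            target=target,
            odds_ratio_star=float("nan"),
            achieved_metric=float("nan"),
            target_value=target_value,
            tolerance=float("nan"),
            iterations_used=2,
            bracketed=False,
        )

    used = 2
    for _ in range(max_iterations):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        used += 1
        if g_mid < 0.0:
            lo, g_lo = mid, g_mid
        else:
            hi, g_hi = mid, g_mid

    or_star = 0.5 * (lo + hi)
    res = evaluate_model(config, ParameterDraw.point(config).with_odds_ratio(or_star))
    if target == "net_cost_zero":
        achieved = res.net_cost
    else:
        achieved = (
            res.net_cost / res.incremental_qalys
            if res.incremental_qalys > 0
            else float("inf")
        )
    # the root lies in [lo, hi]; |g| there is bounded by the bracket spread
    metric_tol = float(abs(g_hi - g_lo))
    if target == "icer_at_wtp" and res.incremental_qalys > 0:
        metric_tol /= res.incremental_qalys
    return ThresholdResult(
        target=target,
        odds_ratio_star=float(or_star),
        achieved_metric=float(achieved),
        target_value=target_value,
        tolerance=metric_tol,
        iterations_used=used,
        bracketed=True,
    )
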