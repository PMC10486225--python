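"""Costing, QALYs, and the ROI / cost–utility result frameworks.

Given the two arm traces, this module computes, all discounted at the annual
rate and expressed in the config's price year (AUD 2018 by default):

- intervention cost: engaged cohort × unit cost, charged once at model entry;
- healthcare cost offsets: averted non-fatal repeat episodes × per-episode
  admission cost;
- suicide-related cost offsets: averted suicide deaths × either the weighted
  average cost of a suicide death (base case) or the value of a statistical
  life (sensitivity analysis) — a single switch to avoid double counting;
- QALYs per arm (utility-weighted, discounted state occupancy at end of
  cycle), the incremental QALYs, the ICER (with dominance flags), the ROI
  benefit/cost ratio, and the net monetary benefit at the configured
  willingness-to-pay.

Sign convention: savings are positive; the incremental (net) cost is negative
when the intervention is cost-saving.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, asdict
from typing import NamedTuple, Optional

import numpy as np

from .markov import NO_SELF_HARM, SELF_HARM_NONFATAL, CohortTrace, run_cohort
from .parameters import ModelConfig, ParameterDraw

__all__ = [
    "ICERFlag",
    "ICEROutcome",
    "EconomicResult",
    "discount_factor",
    "discount_factors",
    "compute_qalys",
    "compute_costs",
    "icer",
    "roi_ratio",
    "is_cost_saving",
    "net_monetary_benefit",
    "evaluate_model",
]


def discount_factor(rate: float, year: int) -> float:
    """1/(1+rate)^year; year 0 (model entry) is undiscounted."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    if year < 0:
        raise ValueError(f"year must be >= 0, got {year}")
    return (1.0 + rate) ** -year


def discount_factors(rate: float, horizon: int) -> np.ndarray:
    """Vector of discount factors for years 1..horizon."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"rate must lie in [0, 1), got {rate}")
    return (1.0 + rate) ** -np.arange(1, horizon + 1, dtype=float)


class ICERFlag(str, enum.Enum):
    RATIO = "ratio"
    DOMINANT = "dominant"  # cheaper and more effective
    DOMINATED = "dominated"  # dearer and less effective
    UNDEFINED = "undefined"  # zero QALY difference


class ICEROutcome(NamedTuple):
    flag: ICERFlag
    value: Optional[float]

    def __str__(self) -> str:
        if self.flag is ICERFlag.RATIO:
            return f"{self.value:,.0f}"
        return self.flag.value


def icer(delta_cost: float, delta_qaly: float) -> ICEROutcome:
    """Incremental cost-effectiveness ratio with dominance flags.

    A dominant result (negative incremental cost, positive incremental QALYs)
    means the intervention is both cost-saving and more effective; dominance
    and a zero QALY difference are reported as flags, never as exceptions.
    """
    if delta_qaly == 0.0:
        return ICEROutcome(ICERFlag.UNDEFINED, None)
    if delta_cost < 0.0 and delta_qaly > 0.0:
        return ICEROutcome(ICERFlag.DOMINANT, delta_cost / delta_qaly)
    if delta_cost > 0.0 and delta_qaly < 0.0:
        return ICEROutcome(ICERFlag.DOMINATED, delta_cost / delta_qaly)
    return ICEROutcome(ICERFlag.RATIO, delta_cost / delta_qaly)


def roi_ratio(total_savings: float, intervention_cost: float) -> float:
    """Benefit/cost ratio: total savings divided by intervention cost.

    Ratios strictly greater than 1 classify as cost-saving (see
    :func:`is_cost_saving`). A zero intervention cost has no defined ratio and
    returns NaN.
    """
    if intervention_cost < 0:
        raise ValueError("intervention_cost must be >= 0")
    if intervention_cost == 0:
        return float("nan")
    return total_savings / intervention_cost


def is_cost_saving(roi: float) -> bool:
    """Cost-saving classification: ROI strictly greater than one."""
    return bool(roi > 1.0)


def net_monetary_benefit(delta_qaly: float, delta_cost: float, wtp: float) -> float:
    """wtp × ΔQALY − ΔCost; positive means cost-effective at that threshold."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * delta_qaly - delta_cost


def compute_qalys(
    trace: CohortTrace, u_no_selfharm: float, u_selfharm: float, rate: float
) -> float:
    """Discounted QALYs for one arm.

    Sums, over cycles 1..horizon and strata, end-of-cycle occupancy × state
    utility × discount factor. Dead states contribute nothing.
    """
    h = trace.horizon
    disc = discount_factors(rate, h)
    alive_no = trace.occupancy[1:, :, NO_SELF_HARM].sum(axis=1)
    alive_sh = trace.occupancy[1:, :, SELF_HARM_NONFATAL].sum(axis=1)
    return float(np.sum(disc * (u_no_selfharm * alive_no + u_selfharm * alive_sh)))


def compute_costs(
    trace_intervention: CohortTrace,
    trace_comparator: CohortTrace,
    draw: ParameterDraw,
    suicide_valuation: str = "weighted_average",
) -> dict[str, float]:
    """Intervention cost and discounted cost offsets between the two arms.

    The intervention is charged at model entry (undiscounted) for the engaged
    fraction of the entering cohort only. Offsets are valued per averted event
    in the cycle it occurs: non-fatal repeat episodes at the per-episode
    admission cost, suicide deaths at the weighted-average cost of a suicide
    or the VSL depending on ``suicide_valuation``. Negative averted counts
    (harm) propagate as negative savings.
    """
    if suicide_valuation not in ("weighted_average", "vsl"):
        raise ValueError(f"unknown suicide_valuation {suicide_valuation!r}")
    entering = trace_comparator.occupancy[0].sum()
    intervention_cost = entering * draw.uptake * draw.unit_cost

    h = trace_comparator.horizon
    disc = discount_factors(draw.discount_rate, h)
    averted_repeats = (
        trace_comparator.repeat_events - trace_intervention.repeat_events
    ).sum(axis=1)
    averted_suicides = (
        trace_comparator.suicide_deaths - trace_intervention.suicide_deaths
    ).sum(axis=1)
    healthcare_savings = float(
        np.sum(disc * averted_repeats) * draw.healthcare_cost_per_episode
    )
    per_suicide = (
        draw.suicide_death_cost if suicide_valuation == "weighted_average" else draw.vsl
    )
    suicide_cost_savings = float(np.sum(disc * averted_suicides) * per_suicide)
    return {
        "intervention_cost": float(intervention_cost),
        "healthcare_savings": healthcare_savings,
        "suicide_cost_savings": suicide_cost_savings,
        "averted_repeat_events": float(averted_repeats.sum()),
        "averted_suicides": float(averted_suicides.sum()),
    }


@dataclass(frozen=True)
class EconomicResult:
    """Discounted economics of one deterministic model run."""

    intervention_cost: float
    healthcare_savings: float
    suicide_cost_savings: float
    total_savings: float
    net_cost: float  # intervention_cost − total_savings; negative = cost-saving
    qalys_intervention: float
    qalys_comparator: float
    incremental_qalys: float
    icer: ICEROutcome
    roi: float
    cost_saving: bool
    nmb: float
    wtp: float
    averted_repeat_events: float
    averted_suicides: float
    suicide_valuation: str

    @property
    def net_savings(self) -> float:
        return -self.net_cost

    def to_dict(self) -> dict:
        d = asdict(self)
        d["icer"] = str(self.icer)
        d["icer_flag"] = self.icer.flag.value
        d["icer_value"] = self.icer.value
        d["net_savings"] = self.net_savings
        return d


def evaluate_model(
    config: ModelConfig,
    draw: ParameterDraw | None = None,
    suicide_valuation: str | None = None,
    wtp: float | None = None,
) -> EconomicResult:
    """Run both arms and assemble the full economic result.

    ``draw`` defaults to the point-estimate parameter set; ``suicide_valuation``
    and ``wtp`` default to the config's settings.
    """
    if draw is None:
        draw = ParameterDraw.point(config)
    if suicide_valuation is None:
        suicide_valuation = config.settings.suicide_valuation
    if wtp is None:
        wtp = config.settings.wtp_threshold

    trace_int, trace_comp = run_cohort(config, draw)
    costs = compute_costs(trace_int, trace_comp, draw, suicide_valuation)
    total_savings = costs["healthcare_savings"] + costs["suicide_cost_savings"]
    net_cost = costs["intervention_cost"] - total_savings

    q_int = compute_qalys(trace_int, draw.u_no_selfharm, draw.u_selfharm, draw.discount_rate)
    q_comp = compute_qalys(trace_comp, draw.u_no_selfharm, draw.u_selfharm, draw.discount_rate)
    dq = q_int - q_comp

    roi = roi_ratio(total_savings, costs["intervention_cost"])
    return EconomicResult(
        intervention_cost=costs["intervention_cost"],
        healthcare_savings=costs["healthcare_savings"],
        suicide_cost_savings=costs["suicide_cost_savings"],
        total_savings=total_savings,
        net_cost=net_cost,
        qalys_intervention=q_int,
        qalys_comparator=q_comp,
        incremental_qalys=dq,
        icer=icer(net_cost, dq),
        roi=roi,
        cost_saving=is_cost_saving(roi),
        nmb=net_monetary_benefit(dq, net_cost, wtp),
        wtp=wtp,
        averted_repeat_events=costs["averted_repeat_events"],
        averted_suicides=costs["averted_suicides"],
        suicide_valuation=suicide_valuation,
    )
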