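"""Annual-cycle cohort state-transition model.

Four health states: people who had an index self-harm admission either do not
repeat self-harm, repeat with a non-fatal outcome, die by suicide, or die from
other causes. The two dead states are absorbing; the non-fatal repeat state is
a one-cycle event state whose occupants rejoin the at-risk pool the next cycle
with the same annual risks. Each age–sex stratum is propagated independently
over the horizon for an intervention arm and a "do nothing" comparator arm.

The intervention lowers the odds of repeat self-harm (and, by default, of
suicide) among the fraction of the cohort that takes it up, with the effect
attenuating per the configured decay schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import DecaySchedule, EffectParameters, ModelConfig, ParameterDraw

__all__ = [
    "STATES",
    "N_STATES",
    "NO_SELF_HARM",
    "SELF_HARM_NONFATAL",
    "DEAD_SUICIDE",
    "DEAD_OTHER",
    "ModelError",
    "CohortTrace",
    "or_to_probability",
    "effective_odds_ratio",
    "decayed_odds_ratio",
    "effective_event_probabilities",
    "build_transition_matrix",
    "run_cohort",
]

logger = logging.getLogger(__name__)

NO_SELF_HARM, SELF_HARM_NONFATAL, DEAD_SUICIDE, DEAD_OTHER = range(4)
STATES = ("NO_SELF_HARM", "SELF_HARM_NONFATAL", "DEAD_SUICIDE", "DEAD_OTHER")
N_STATES = 4
ARMS = ("intervention", "comparator")


class ModelError(RuntimeError):
    """The model produced an inconsistent state (e.g. probability closure broke)."""


def or_to_probability(p_base, odds_ratio):
    """Apply an odds ratio to a baseline probability.

    Returns p with odds(p) = odds_ratio × odds(p_base). Accepts scalars or
    arrays; p_base = 1 with a finite positive OR returns 1 (the limit).
    """
    p = np.asarray(p_base, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"p_base must lie in [0, 1], got {p_base}")
    if np.any(np.asarray(odds_ratio) <= 0):
        raise ValueError(f"odds_ratio must be > 0, got {odds_ratio}")
    num = odds_ratio * p
    out = np.where(p == 1.0, 1.0, num / ((1.0 - p) + num))
    return float(out) if np.isscalar(p_base) else out


def decayed_odds_ratio(odds_ratio: float, year: int, schedule: DecaySchedule) -> float:
    """Odds ratio among treated people in a given model year.

    Decay acts on the effect scale: the reduction (1 − OR) is scaled by the
    year's multiplier, so multiplier 1 gives the full OR and multiplier 0
    gives 1 (no effect).
    """
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    m = schedule.multiplier(year)
    return 1.0 - (1.0 - odds_ratio) * m


def effective_odds_ratio(
    odds_ratio: float, year: int, schedule: DecaySchedule, uptake: float
) -> float:
    """Population-level odds ratio for one model year.

    The treated-arm reduction (1 − OR) is attenuated by the decay multiplier
    for that year and diluted by uptake (non-uptakers receive no effect), then
    re-expressed as an odds ratio. Years beyond a custom schedule are treated
    as multiplier 0 (no residual effect) and logged.
    """
    if year < 1:
        raise ValueError(f"year must be >= 1, got {year}")
    if schedule.mode == "custom" and year > len(schedule.multipliers or ()):
        logger.debug("year %d beyond decay schedule; multiplier 0 applied", year)
    m = schedule.multiplier(year)
    return 1.0 - (1.0 - odds_ratio) * m * uptake


def effective_event_probabilities(
    draw: ParameterDraw,
    year: int,
    arm: str,
    effect: EffectParameters,
    effect_on_suicide: bool = True,
):
    """Annual (p_repeat, p_suicide, p_other) for one arm in one model year.

    Comparator probabilities are the baselines. In the intervention arm the
    odds ratio (decayed for the year) is applied to the treated fraction and
    mixed with the untreated fraction of the cohort:
    ``p = uptake × p_OR + (1 − uptake) × p_base``. ``p_other`` is a per-stratum
    vector and is never modified by the intervention.
    """
    p_rep = float(draw.p_repeat_nonfatal[year - 1])
    p_sui = float(draw.p_suicide[year - 1])
    p_oth = draw.p_other_death
    if arm == "comparator":
        return p_rep, p_sui, p_oth
    if arm != "intervention":
        raise ValueError(f"unknown arm {arm!r}")
    or_year = decayed_odds_ratio(draw.odds_ratio, year, effect.decay)
    u = draw.uptake
    p_rep_eff = u * or_to_probability(p_rep, or_year) + (1 - u) * p_rep
    if effect_on_suicide:
        p_sui_eff = u * or_to_probability(p_sui, or_year) + (1 - u) * p_sui
    else:
        p_sui_eff = p_sui
    return p_rep_eff, p_sui_eff, p_oth


def build_transition_matrix(
    draw: ParameterDraw,
    stratum_index: int,
    year: int,
    arm: str,
    effect: EffectParameters,
    effect_on_suicide: bool = True,
) -> np.ndarray:
    """4×4 one-cycle transition matrix for one stratum, year and arm.

    Rows for the two alive states are identical (the non-fatal repeat state is
    an event state with the same onward risks); residual mass goes to
    NO_SELF_HARM; dead rows are absorbing unit vectors.
    """
    p_rep, p_sui, p_oth_vec = effective_event_probabilities(
        draw, year, arm, effect, effect_on_suicide
    )
    p_oth = float(p_oth_vec[stratum_index])
    residual = 1.0 - p_rep - p_sui - p_oth
    if residual < -1e-12:
        raise ModelError(
            f"transition probabilities exceed 1 in year {year}, stratum "
            f"{stratum_index}, arm {arm}: {p_rep + p_sui + p_oth}"
        )
    alive_row = np.array([max(residual, 0.0), p_rep, p_sui, p_oth])
    mat = np.zeros((N_STATES, N_STATES))
    mat[NO_SELF_HARM] = alive_row
    mat[SELF_HARM_NONFATAL] = alive_row
    mat[DEAD_SUICIDE, DEAD_SUICIDE] = 1.0
    mat[DEAD_OTHER, DEAD_OTHER] = 1.0
    return mat


@dataclass
class CohortTrace:
    """State occupancy and event counts for one arm.

    ``occupancy[t, s, k]`` is the expected number of persons of stratum ``s``
    in state ``k`` at the end of cycle ``t`` (cycle 0 is model entry, everyone
    in NO_SELF_HARM). Event arrays are indexed by cycle 1..horizon (stored at
    index ``t − 1``) and count the new events of that cycle.
    """

    occupancy: np.ndarray  # (horizon+1, n_strata, 4)
    repeat_events: np.ndarray  # (horizon, n_strata)
    suicide_deaths: np.ndarray  # (horizon, n_strata)
    other_deaths: np.ndarray  # (horizon, n_strata)
    strata_labels: list[str]

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def total_repeat_events(self) -> float:
        return float(self.repeat_events.sum())

    def total_suicide_deaths(self) -> float:
        return float(self.suicide_deaths.sum())

    def occupancy_frame(self) -> pd.DataFrame:
        """Tidy occupancy table: cycle, stratum, state, persons."""
        h, s, _ = self.occupancy.shape
        idx = pd.MultiIndex.from_product(
            [range(h), self.strata_labels, STATES], names=["cycle", "stratum", "state"]
        )
        return pd.DataFrame({"persons": self.occupancy.ravel()}, index=idx).reset_index()

    def events_frame(self) -> pd.DataFrame:
        """Tidy per-cycle event counts."""
        h, s = self.repeat_events.shape
        idx = pd.MultiIndex.from_product(
            [range(1, h + 1), self.strata_labels], names=["cycle", "stratum"]
        )
        return pd.DataFrame(
            {
                "repeat_events": self.repeat_events.ravel(),
                "suicide_deaths": self.suicide_deaths.ravel(),
                "other_deaths": self.other_deaths.ravel(),
            },
            index=idx,
        ).reset_index()


def _run_arm(config: ModelConfig, draw: ParameterDraw, arm: str) -> CohortTrace:
    h = config.settings.horizon_years
    counts = config.cohort.counts
    n = len(counts)
    occ = np.zeros((h + 1, n, N_STATES))
    occ[0, :, NO_SELF_HARM] = counts
    repeat_events = np.zeros((h, n))
    suicide_deaths = np.zeros((h, n))
    other_deaths = np.zeros((h, n))

    for year in range(1, h + 1):
        p_rep, p_sui, p_oth = effective_event_probabilities(
            draw, year, arm, config.effect, config.settings.effect_on_suicide
        )
        residual = 1.0 - p_rep - p_sui - p_oth  # vector over strata
        if np.any(residual < -1e-12):
            raise ModelError(
                f"transition probabilities exceed 1 in year {year}, arm {arm}"
            )
        alive = occ[year - 1, :, NO_SELF_HARM] + occ[year - 1, :, SELF_HARM_NONFATAL]
        repeat_events[year - 1] = alive * p_rep
        suicide_deaths[year - 1] = alive * p_sui
        other_deaths[year - 1] = alive * p_oth
        occ[year, :, NO_SELF_HARM] = alive * np.maximum(residual, 0.0)
        occ[year, :, SELF_HARM_NONFATAL] = repeat_events[year - 1]
        occ[year, :, DEAD_SUICIDE] = occ[year - 1, :, DEAD_SUICIDE] + suicide_deaths[year - 1]
        occ[year, :, DEAD_OTHER] = occ[year - 1, :, DEAD_OTHER] + other_deaths[year - 1]

    return CohortTrace(
        occupancy=occ,
        repeat_events=repeat_events,
        suicide_deaths=suicide_deaths,
        other_deaths=other_deaths,
        strata_labels=config.cohort.labels,
    )


def run_cohort(
    config: ModelConfig, draw: ParameterDraw | None = None
) -> tuple[CohortTrace, CohortTrace]:
    """Propagate the cohort through both arms.

    Returns ``(intervention_trace, comparator_trace)``. The propagation is the
    deterministic expectation: stratum counts times row-stochastic one-cycle
    matrices, so persons are conserved exactly and the comparator trace does
    not depend on the effect parameters.
    """
    if draw is None:
        draw = ParameterDraw.point(config)
    return _run_arm(config, draw, "intervention"), _run_arm(config, draw, "comparator")
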