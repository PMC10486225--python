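import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aftercare_cea import (
    CohortSpec,
    ModelConfig,
    ParameterDraw,
    RunSettings,
    StratumSpec,
    TransitionParameters,
    default_parameter_set,
)
from aftercare_cea.markov import effective_event_probabilities

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def base_config() -> ModelConfig:
    """The packaged national-scale base case (synthetic default inputs)."""
    return default_parameter_set()


def make_single_stratum_config(
    count: int = 1000,
    p_repeat: float = 0.163,
    p_suicide: float = 0.016,
    p_other: float = 0.002,
    hazard_decline: float = 0.8,
    horizon: int = 10,
    **settings_overrides,
) -> ModelConfig:
    """A small one-stratum configuration for focused tests."""
    base = default_parameter_set()
    decline = [hazard_decline**t for t in range(horizon)]
    return ModelConfig(
        cohort=CohortSpec(
            strata=[StratumSpec(age_band="15-64", sex="female", count=count)]
        ),
        transitions=TransitionParameters(
            p_repeat_nonfatal=[p_repeat * d for d in decline],
            p_suicide=[p_suicide * d for d in decline],
            p_other_death=[p_other],
        ),
        effect=base.effect,
        costs=base.costs,
        utilities=base.utilities,
        settings=RunSettings(horizon_years=horizon, **settings_overrides),
    )


@pytest.fixture
def single_stratum_config() -> ModelConfig:
    return make_single_stratum_config()


def microsimulate_arm(
    config: ModelConfig,
    arm: str,
    n_persons: int,
    n_replicates: int,
    seed: int,
):
    """Individual-level simulation of one single-stratum arm.

    An independent oracle for the cohort engine: each person draws a uniform
    per year and experiences at most one of (non-fatal repeat, suicide death,
    other death); the dead leave the risk pool. Returns per-replicate
    cumulative counts of repeat events and suicide deaths.
    """
    assert len(config.cohort.strata) == 1, "oracle is single-stratum"
    draw = ParameterDraw.point(config)
    h = config.settings.horizon_years
    rng = np.random.default_rng(seed)
    cum_rep = np.zeros(n_replicates)
    cum_sui = np.zeros(n_replicates)
    for r in range(n_replicates):
        alive = np.ones(n_persons, dtype=bool)
        for year in range(1, h + 1):
            p_rep, p_sui, p_oth = effective_event_probabilities(
                draw, year, arm, config.effect, config.settings.effect_on_suicide
            )
            p_oth = float(p_oth[0])
            u = rng.random(n_persons)
            rep = alive & (u < p_rep)
            sui = alive & (u >= p_rep) & (u < p_rep + p_sui)
            oth = alive & (u >= p_rep + p_sui) & (u < p_rep + p_sui + p_oth)
            cum_rep[r] += rep.sum()
            cum_sui[r] += sui.sum()
            alive &= ~(sui | oth)
    return cum_rep, cum_sui
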