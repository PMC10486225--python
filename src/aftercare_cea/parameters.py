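"""Parameter schema, validation and file round-trip for the aftercare model.

The model consumes a single structured configuration: an admission cohort split
into age–sex strata, baseline annual transition probabilities, the intervention
effect (odds ratio, decay schedule, uptake), unit costs, utility weights, and
run settings (horizon, discount rate, willingness-to-pay, Monte Carlo size).
Every uncertain quantity is declared as a :class:`DistributionSpec` so that the
deterministic model and the probabilistic sensitivity analysis read the same
file.

Configurations are YAML mappings with top-level keys ``cohort``,
``transitions``, ``effect``, ``costs``, ``utilities`` and ``settings``.
Validation is strict: unknown keys are rejected and any out-of-range value
raises an error naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Any, Literal, Optional

import numpy as np
import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)
from scipy import stats

__all__ = [
    "ConfigError",
    "DistributionSpec",
    "DecaySchedule",
    "EffectParameters",
    "TransitionParameters",
    "CostParameters",
    "UtilityParameters",
    "StratumSpec",
    "CohortSpec",
    "RunSettings",
    "ModelConfig",
    "ParameterDraw",
    "load_config",
    "save_config",
    "load_default_config",
    "default_config_path",
    "validate_probability_closure",
]

#: z-score used to convert a 95% CI into a standard deviation when fitting
#: sampling distributions (the conventional 1.96, not the exact quantile).
Z_95 = 1.96


class ConfigError(ValueError):
    """A configuration file could not be read or failed validation."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

DistributionKind = Literal[
    "point", "lognormal_from_ci", "beta_from_ci", "uniform_pct", "uniform_bounds"
]


class DistributionSpec(_StrictModel):
    """A point estimate plus the sampling distribution used in the PSA.

    ``kind`` selects how uncertainty is represented:

    - ``point``: degenerate; sampling always returns ``point_value``.
    - ``lognormal_from_ci``: lognormal with log-mean ``ln(point_value)`` and
      log-sd ``(ln ci_high − ln ci_low) / (2 × 1.96)`` — the standard fit for
      a ratio measure reported with a 95% CI.
    - ``beta_from_ci``: beta distribution moment-matched to mean
      ``point_value`` and sd ``(ci_high − ci_low) / (2 × 1.96)``; used for
      probabilities and utility weights.
    - ``uniform_pct``: uniform on ``point_value × (1 ± pct_halfwidth)``; used
      for unit costs reported with a ±percentage band.
    - ``uniform_bounds``: uniform on ``[ci_low, ci_high]``.
    """

    kind: DistributionKind = "point"
    point_value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    pct_halfwidth: Optional[float] = None

    @model_validator(mode="after")
    def _check_fields(self) -> "DistributionSpec":
        if self.kind in ("lognormal_from_ci", "beta_from_ci", "uniform_bounds"):
            if self.ci_low is None or self.ci_high is None:
                raise ValueError(f"kind={self.kind} requires ci_low and ci_high")
            if not (self.ci_low <= self.point_value <= self.ci_high):
                raise ValueError(
                    f"ci_low ({self.ci_low}) <= point_value ({self.point_value})"
                    f" <= ci_high ({self.ci_high}) violated"
                )
        if self.kind == "lognormal_from_ci" and self.ci_low is not None and self.ci_low <= 0:
            raise ValueError("lognormal_from_ci requires ci_low > 0")
        if self.kind == "uniform_pct":
            if self.pct_halfwidth is None or self.pct_halfwidth <= 0:
                raise ValueError("uniform_pct requires pct_halfwidth > 0")
        return self

    def frozen(self):
        """The frozen scipy distribution, or ``None`` for a point mass."""
        if self.kind == "point":
            return None
        if self.kind == "lognormal_from_ci":
            sdlog = (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * Z_95)
            return stats.lognorm(s=sdlog, scale=self.point_value)
        if self.kind == "beta_from_ci":
            m = self.point_value
            sd = (self.ci_high - self.ci_low) / (2 * Z_95)
            v = sd * sd
            if not 0 < m < 1:
                raise ConfigError(f"beta_from_ci needs point_value in (0,1), got {m}")
            if v >= m * (1 - m):
                raise ConfigError("beta_from_ci: CI-implied variance too large for a beta")
            k = m * (1 - m) / v - 1
            return stats.beta(a=m * k, b=(1 - m) * k)
        if self.kind == "uniform_pct":
            lo = self.point_value * (1 - self.pct_halfwidth)
            return stats.uniform(loc=lo, scale=2 * self.point_value * self.pct_halfwidth)
        if self.kind == "uniform_bounds":
            return stats.uniform(loc=self.ci_low, scale=self.ci_high - self.ci_low)
        raise ConfigError(f"unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        dist = self.frozen()
        if dist is None:
            return self.point_value if size is None else np.full(size, self.point_value)
        return dist.rvs(size=size, random_state=rng)

    def quantile(self, q):
        dist = self.frozen()
        if dist is None:
            return self.point_value
        return dist.ppf(q)


# ---------------------------------------------------------------------------
# Intervention effect
# ---------------------------------------------------------------------------


class DecaySchedule(_StrictModel):
    """Per-year attenuation of the intervention effect.

    ``halving_5yr`` is the base case: the effect halves each year for five
    years and is zero thereafter — multipliers (1, 0.5, 0.25, 0.125, 0.0625,
    0, 0, ...). ``one_year_only`` keeps the full effect in year 1 only.
    ``custom`` takes explicit per-year multipliers indexed from model year 1;
    years beyond the list get multiplier 0.
    """

    mode: Literal["halving_5yr", "one_year_only", "custom"] = "halving_5yr"
    multipliers: Optional[list[float]] = None

    @model_validator(mode="after")
    def _check(self) -> "DecaySchedule":
        if self.mode == "custom":
            if not self.multipliers:
                raise ValueError("custom decay requires multipliers")
            if any(not 0 <= m <= 1 for m in self.multipliers):
                raise ValueError("multipliers must lie in [0, 1]")
        elif self.multipliers is not None:
            raise ValueError("multipliers only allowed with mode=custom")
        return self

    def multiplier(self, year: int) -> float:
        """Effect multiplier for model year ``year`` (1-indexed)."""
        if year < 1:
            raise ValueError(f"year must be >= 1, got {year}")
        if self.mode == "halving_5yr":
            return 0.5 ** (year - 1) if year <= 5 else 0.0
        if self.mode == "one_year_only":
            return 1.0 if year == 1 else 0.0
        return self.multipliers[year - 1] if year <= len(self.multipliers) else 0.0


class EffectParameters(_StrictModel):
    odds_ratio: DistributionSpec
    decay: DecaySchedule = Field(default_factory=DecaySchedule)
    uptake: float = Field(ge=0.0, le=1.0)

    @field_validator("odds_ratio")
    @classmethod
    def _positive_or(cls, v: DistributionSpec) -> DistributionSpec:
        if v.point_value <= 0:
            raise ValueError("odds_ratio point value must be > 0")
        return v


# ---------------------------------------------------------------------------
# Transitions, costs, utilities
# ---------------------------------------------------------------------------


class TransitionParameters(_StrictModel):
    """Baseline annual event probabilities in the comparator arm.

    ``p_repeat_nonfatal`` and ``p_suicide`` are per-model-year series (year 1
    onward, applied to every stratum); ``p_other_death`` is a per-stratum
    annual probability aligned with the cohort's strata order.
    """

    p_repeat_nonfatal: list[float]
    p_suicide: list[float]
    p_other_death: list[float]

    @field_validator("p_repeat_nonfatal", "p_suicide", "p_other_death")
    @classmethod
    def _probabilities(cls, v: list[float]) -> list[float]:
        if any(not 0.0 <= p <= 1.0 for p in v):
            raise ValueError("probabilities must lie in [0, 1]")
        return v


def validate_probability_closure(tp: TransitionParameters, horizon: int) -> bool:
    """True iff every (year, stratum) pair has total exit probability <= 1.

    Raises ``ConfigError`` if either annual series is shorter than ``horizon``.
    """
    if len(tp.p_repeat_nonfatal) < horizon or len(tp.p_suicide) < horizon:
        raise ConfigError(
            "transition series shorter than horizon: "
            f"p_repeat_nonfatal has {len(tp.p_repeat_nonfatal)}, "
            f"p_suicide has {len(tp.p_suicide)}, horizon is {horizon}"
        )
    for year in range(horizon):
        base = tp.p_repeat_nonfatal[year] + tp.p_suicide[year]
        if any(base + p_oth > 1.0 for p_oth in tp.p_other_death):
            return False
    return True


class CostParameters(_StrictModel):
    intervention_unit_cost: DistributionSpec
    healthcare_cost_per_selfharm_episode: DistributionSpec
    suicide_death_cost: DistributionSpec
    vsl: DistributionSpec
    discount_rate: float = Field(ge=0.0, lt=1.0, default=0.03)

    @field_validator(
        "intervention_unit_cost",
        "healthcare_cost_per_selfharm_episode",
        "suicide_death_cost",
        "vsl",
    )
    @classmethod
    def _nonnegative(cls, v: DistributionSpec) -> DistributionSpec:
        if v.point_value < 0:
            raise ValueError("monetary values must be >= 0")
        return v


class UtilityParameters(_StrictModel):
    """Utility weights: alive states carry a weight in [0,1]; death is 0.

    In the PSA the two alive-state utilities are sampled jointly: ``u_selfharm``
    is drawn from its distribution and ``u_no_selfharm`` is set to
    ``u_selfharm + constraint_delta`` so the gap between states is preserved in
    every draw despite their overlapping confidence intervals.
    """

    u_no_selfharm: DistributionSpec
    u_selfharm: DistributionSpec
    constraint_delta: float = 0.1

    #: utility of both dead states, fixed by the QALY scale
    U_DEAD: float = 0.0

    @field_validator("u_no_selfharm", "u_selfharm")
    @classmethod
    def _unit_interval(cls, v: DistributionSpec) -> DistributionSpec:
        if not 0.0 <= v.point_value <= 1.0:
            raise ValueError("utility weights must lie in [0, 1]")
        return v

    @field_validator("U_DEAD")
    @classmethod
    def _dead_is_zero(cls, v: float) -> float:
        if v != 0.0:
            raise ValueError("U_DEAD is fixed at 0")
        return v


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


class StratumSpec(_StrictModel):
    age_band: str
    sex: Literal["female", "male"]
    count: int = Field(ge=0)

    @property
    def label(self) -> str:
        return f"{self.age_band}/{self.sex}"


class CohortSpec(_StrictModel):
    """Age–sex strata of index self-harm admissions entering the model."""

    strata: list[StratumSpec]
    population_basis: Optional[int] = Field(default=None, ge=0)
    admission_rate_per_100k: Optional[float] = Field(default=None, ge=0.0)

    @property
    def total(self) -> int:
        return sum(s.count for s in self.strata)

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.strata]

    @property
    def counts(self) -> np.ndarray:
        return np.array([s.count for s in self.strata], dtype=float)


# ---------------------------------------------------------------------------
# Run settings and the full configuration
# ---------------------------------------------------------------------------


class RunSettings(_StrictModel):
    horizon_years: int = Field(default=10, ge=1)
    wtp_threshold: float = Field(default=50_000.0, gt=0.0)
    psa_iterations: int = Field(default=3000, ge=1)
    rng_seed: int = Field(default=2018, ge=0)
    price_year: int = 2018
    suicide_valuation: Literal["weighted_average", "vsl"] = "weighted_average"
    #: whether the intervention odds ratio also lowers the suicide transition
    #: (the pooled effect covers repeat attempts; the model claims an effect on
    #: both repeat self-harm and subsequent suicide — switchable)
    effect_on_suicide: bool = True


class ModelConfig(_StrictModel):
    """Every input of one model run. See the packaged ``base_case.yaml``."""

    cohort: CohortSpec
    transitions: TransitionParameters
    effect: EffectParameters
    costs: CostParameters
    utilities: UtilityParameters
    settings: RunSettings = Field(default_factory=RunSettings)

    @model_validator(mode="after")
    def _cross_checks(self) -> "ModelConfig":
        h = self.settings.horizon_years
        if len(self.transitions.p_repeat_nonfatal) < h:
            raise ValueError(
                f"transitions.p_repeat_nonfatal covers "
                f"{len(self.transitions.p_repeat_nonfatal)} years < horizon {h}"
            )
        if len(self.transitions.p_suicide) < h:
            raise ValueError(
                f"transitions.p_suicide covers {len(self.transitions.p_suicide)}"
                f" years < horizon {h}"
            )
        if len(self.transitions.p_other_death) != len(self.cohort.strata):
            raise ValueError(
                "transitions.p_other_death must have one entry per cohort stratum"
                f" ({len(self.transitions.p_other_death)} vs {len(self.cohort.strata)})"
            )
        if not validate_probability_closure(self.transitions, h):
            raise ValueError(
                "transitions: p_repeat_nonfatal + p_suicide + p_other_death > 1 "
                "for some year/stratum"
            )
        return self

    # convenience passthroughs
    @property
    def horizon_years(self) -> int:
        return self.settings.horizon_years

    @property
    def wtp_threshold(self) -> float:
        return self.settings.wtp_threshold

    @property
    def psa_iterations(self) -> int:
        return self.settings.psa_iterations


# ---------------------------------------------------------------------------
# Realised parameter values (a single joint draw or the point set)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterDraw:
    """Concrete numeric values for one model evaluation.

    The deterministic base case uses :meth:`point`; the PSA produces one
    ``ParameterDraw`` per iteration (see ``uncertainty.sample_parameters``).
    """

    odds_ratio: float
    uptake: float
    unit_cost: float
    healthcare_cost_per_episode: float
    suicide_death_cost: float
    vsl: float
    u_no_selfharm: float
    u_selfharm: float
    p_repeat_nonfatal: np.ndarray
    p_suicide: np.ndarray
    p_other_death: np.ndarray
    discount_rate: float

    @classmethod
    def point(cls, config: ModelConfig) -> "ParameterDraw":
        """The all-point-estimate draw (deterministic base case)."""
        t = config.transitions
        return cls(
            odds_ratio=config.effect.odds_ratio.point_value,
            uptake=config.effect.uptake,
            unit_cost=config.costs.intervention_unit_cost.point_value,
            healthcare_cost_per_episode=(
                config.costs.healthcare_cost_per_selfharm_episode.point_value
            ),
            suicide_death_cost=config.costs.suicide_death_cost.point_value,
            vsl=config.costs.vsl.point_value,
            u_no_selfharm=config.utilities.u_no_selfharm.point_value,
            u_selfharm=config.utilities.u_selfharm.point_value,
            p_repeat_nonfatal=np.asarray(t.p_repeat_nonfatal, dtype=float),
            p_suicide=np.asarray(t.p_suicide, dtype=float),
            p_other_death=np.asarray(t.p_other_death, dtype=float),
            discount_rate=config.costs.discount_rate,
        )

    def with_odds_ratio(self, odds_ratio: float) -> "ParameterDraw":
        return replace(self, odds_ratio=odds_ratio)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a YAML model configuration.

    Raises ``ConfigError`` for unreadable/unparseable files and re-raises
    pydantic's ``ValidationError`` (which names the offending field) for
    schema violations.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - depends on yaml internals
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    return ModelConfig.model_validate(raw)


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write the canonical YAML form; ``load_config`` round-trips it exactly."""
    data = config.model_dump(mode="json", exclude_none=True)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_config_path() -> Path:
    """Path of the packaged base-case configuration file."""
    return Path(resources.files("aftercare_cea").joinpath("data/base_case.yaml"))


def load_default_config() -> ModelConfig:
    """The packaged base-case configuration."""
    return load_config(default_config_path())
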