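"""Model inputs: health states, costs, utilities, trial arm data, life tables.

All transition intensities in the model are per-annum rates; the rate/probability
algebra here converts them to per-cycle probabilities under a constant-hazard
assumption within each cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "DEATH_STATES",
    "N_STATES",
    "ModelConfig",
    "CostInputs",
    "UtilityInputs",
    "TrialArmData",
    "ArmRates",
    "AdverseEventRates",
    "LifeTable",
    "ModelInputs",
    "STRATEGIES",
    "rate_to_probability",
    "probability_to_rate",
    "derive_arm_rates",
    "background_mortality_per_cycle",
    "load_inputs",
    "fixture_inputs",
]


class HealthState(IntEnum):
    """The six internal states of the cohort model.

    Death from disease and death from other (background) causes are tracked
    separately; reports may merge them into a single "death" column.
    """

    FFS = 0                # failure-free survival (ongoing first remission)
    FAILURE = 1            # relapsed / progressive disease, retreated once
    TRANSFORMATION = 2     # histologic transformation, no transplant
    POST_ASCT = 3          # transformation treated with autologous transplant
    DEATH_DISEASE = 4
    DEATH_BACKGROUND = 5


ALIVE_STATES = (
    HealthState.FFS,
    HealthState.FAILURE,
    HealthState.TRANSFORMATION,
    HealthState.POST_ASCT,
)
DEATH_STATES = (HealthState.DEATH_DISEASE, HealthState.DEATH_BACKGROUND)
N_STATES = len(HealthState)

STRATEGIES = ("RT", "RT+CVP", "RT+R-CVP")


def rate_to_probability(rate: float, dt: float) -> float:
    """Probability of at least one event in ``dt`` years at constant ``rate``.

    p = 1 - exp(-rate * dt)

    Parameters
    ----------
    rate : events per person-year, >= 0
    dt : interval length in years, >= 0
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    return -math.expm1(-rate * dt)


def probability_to_rate(p: float, dt: float) -> float:
    """Inverse of :func:`rate_to_probability`: rate = -ln(1 - p) / dt."""
    if not 0 <= p < 1:
        raise ValueError(f"p must be in [0, 1), got {p}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    return -math.log1p(-p) / dt


@dataclass(frozen=True)
class ModelConfig:
    """Global simulation settings.

    The cohort is followed for ``n_cycles`` cycles of ``cycle_length`` years
    (base case: 30 half-year cycles, a 15-year horizon). Costs and QALYs are
    discounted at ``discount_rate`` per annum; the willingness-to-pay
    threshold ``wtp`` is in currency units per QALY.
    """

    cycle_length: float = 0.5
    n_cycles: int = 30
    discount_rate: float = 0.05
    wtp: float = 50_000.0
    start_age: float = 50.0
    sex: str = "male"
    currency_year: int = 2022

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be > 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount_rate must be in [0, 1)")
        if self.wtp <= 0:
            raise ValueError("wtp must be > 0")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def horizon(self) -> float:
        """Total modelled time in years (n_cycles x cycle_length)."""
        return self.n_cycles * self.cycle_length


@dataclass(frozen=True)
class CostInputs:
    """Unit costs of therapy, 2022 AUD, Australian tax-payer perspective.

    The radiotherapy course is costed from its components (simulation,
    dosimetry plan, and per-fraction treatment + verification); systemic
    regimens from a per-cycle drug cost plus day-care cost over
    ``n_cycles_systemic`` three-weekly cycles.
    """

    rt_simulation: float = 739.35
    rt_planning: float = 3448.10
    rt_fraction: float = 190.35
    rt_verification: float = 79.70
    rt_n_fractions: int = 15
    drug_rituximab: float = 562.00
    drug_rcvp: float = 811.18
    drug_cvp: float = 249.18
    drug_rchop: float = 923.28
    day_care: float = 110.80
    n_cycles_systemic: int = 6
    asct: float = 45_638.63
    adverse_event_admission: float = 5000.0
    pegfilgrastim: float = 142.0

    def __post_init__(self) -> None:
        for name in (
            "rt_simulation", "rt_planning", "rt_fraction", "rt_verification",
            "drug_rituximab", "drug_rcvp", "drug_cvp", "drug_rchop",
            "day_care", "asct", "adverse_event_admission", "pegfilgrastim",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def rt_course(self) -> float:
        """Total cost of the radiotherapy course (base case 8238.20)."""
        return self.rt_simulation + self.rt_planning + self.rt_n_fractions * (
            self.rt_fraction + self.rt_verification
        )

    def regimen_course(self, drug_per_cycle: float) -> float:
        return (drug_per_cycle + self.day_care) * self.n_cycles_systemic

    @property
    def cvp_course(self) -> float:
        return self.regimen_course(self.drug_cvp)

    @property
    def rcvp_course(self) -> float:
        return self.regimen_course(self.drug_rcvp)

    @property
    def rchop_course(self) -> float:
        """Second-line R-CHOP course, charged once at first failure."""
        return self.regimen_course(self.drug_rchop)

    @property
    def rituximab_cycle(self) -> float:
        """One cycle of single-agent rituximab plus day care (672.80)."""
        return self.drug_rituximab + self.day_care


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and treatment disutilities.

    ``u_ffs`` applies while failure-free; ``u_progressed`` in the failure,
    transformation and post-transplant states. Disutilities are one-off
    utility decrements during the cycle in which the treatment is delivered.
    """

    u_ffs: float = 0.88
    u_progressed: float = 0.74
    d_rt: float = -0.05
    d_systemic: float = -0.15
    d_asct: float = -0.20

    def __post_init__(self) -> None:
        for name in ("u_ffs", "u_progressed"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("d_rt", "d_systemic", "d_asct"):
            if not -1 <= getattr(self, name) <= 0:
                raise ValueError(f"{name} must be in [-1, 0]")

    def state_utilities(self) -> np.ndarray:
        """Utility weight per health state, indexed by :class:`HealthState`."""
        u = np.zeros(N_STATES)
        u[HealthState.FFS] = self.u_ffs
        u[HealthState.FAILURE] = self.u_progressed
        u[HealthState.TRANSFORMATION] = self.u_progressed
        u[HealthState.POST_ASCT] = self.u_progressed
        return u


@dataclass(frozen=True)
class TrialArmData:
    """Arm-level event counts from the source trial.

    Counts of first progressions, transformations and deaths among ``n``
    randomised patients over a median follow-up in years.
    """

    arm_name: str
    n: int
    progressions: int
    transformations: int
    deaths: int
    median_followup: float = 11.3

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("progressions", "transformations", "deaths"):
            count = getattr(self, name)
            if count < 0:
                raise ValueError(f"{name} must be >= 0")
            if count > self.n:
                raise ValueError(f"{name} ({count}) exceeds n ({self.n})")


@dataclass(frozen=True)
class ArmRates:
    """Per-annum transition intensities out of the failure-free state."""

    progression: float
    transformation: float
    disease_death: float

    def __post_init__(self) -> None:
        for name in ("progression", "transformation", "disease_death"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} rate must be >= 0")


@dataclass(frozen=True)
class AdverseEventRates:
    """First-cycle adverse-event incidences for a strategy (fractions)."""

    admission_incidence: float = 0.0
    pegfilgrastim_incidence: float = 0.0

    def __post_init__(self) -> None:
        for name in ("admission_incidence", "pegfilgrastim_incidence"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def derive_arm_rates(arm: TrialArmData) -> ArmRates:
    """Convert arm event counts to per-annum rates.

    rate = events / (n x median follow-up) — a person-time approximation
    that treats every patient as observed for the median follow-up. It is
    accurate in the rare-event regime and mildly biased downward when the
    cumulative event probability is large (every event-free patient
    contributes full follow-up, while actual person-time at risk is shorter).
    """
    if arm.n == 0:
        raise ValueError("cannot derive rates from an arm with n=0")
    if arm.median_followup <= 0:
        raise ValueError("median_followup must be > 0")
    person_years = arm.n * arm.median_followup
    return ArmRates(
        progression=arm.progressions / person_years,
        transformation=arm.transformations / person_years,
        disease_death=arm.deaths / person_years,
    )


class LifeTable:
    """Annual death probabilities (qx) by integer age and sex.

    Lookup is by completed years of age (non-integer ages floor to the row
    below); requesting an age outside the table raises rather than
    extrapolating.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"age", "sex", "qx"}
        if not required.issubset(table.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if ((table["qx"] < 0) | (table["qx"] > 1)).any():
            raise ValueError("qx values must lie in [0, 1]")
        self._table = table.copy()
        self._qx = {
            (int(row.age), str(row.sex)): float(row.qx)
            for row in table.itertuples()
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self._table.to_csv(path, index=False)

    def to_dataframe(self) -> pd.DataFrame:
        return self._table.copy()

    def annual_qx(self, age: float, sex: str) -> float:
        key = (int(math.floor(age)), sex)
        if key not in self._qx:
            raise KeyError(
                f"age {age} ({sex}) outside life table range; no extrapolation"
            )
        return self._qx[key]

    def background_rate(self, age: float, sex: str) -> float:
        """Annual background mortality hazard at ``age`` (constant within year)."""
        qx = self.annual_qx(age, sex)
        if qx >= 1.0:
            return math.inf
        return probability_to_rate(qx, 1.0)


def background_mortality_per_cycle(
    table: LifeTable, age: float, sex: str, cycle_length: float = 0.5
) -> float:
    """Per-cycle background death probability from the annual qx.

    p_cycle = 1 - (1 - qx)^cycle_length, i.e. the annual probability
    converted through the rate algebra assuming constant hazard within the
    year of age.
    """
    qx = table.annual_qx(age, sex)
    if qx >= 1.0:
        return 1.0
    return -math.expm1(cycle_length * math.log1p(-qx))


@dataclass(frozen=True)
class ModelInputs:
    """Everything one base-case evaluation of all three strategies needs."""

    config: ModelConfig = field(default_factory=ModelConfig)
    costs: CostInputs = field(default_factory=CostInputs)
    utilities: UtilityInputs = field(default_factory=UtilityInputs)
    arms: Mapping[str, TrialArmData] = field(default_factory=dict)
    adverse_events: Mapping[str, AdverseEventRates] = field(default_factory=dict)
    life_table: LifeTable | None = None
    post_failure_death_rate: float = 0.05
    explicit_rates: Mapping[str, ArmRates] = field(default_factory=dict)
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.post_failure_death_rate < 0:
            raise ValueError("post_failure_death_rate must be >= 0")

    def arm_rates(self, strategy: str) -> ArmRates:
        """Transition rates for a strategy: explicit overrides (used by the
        sensitivity analyses) take precedence over rates derived from the
        trial counts."""
        if strategy in self.explicit_rates:
            return self.explicit_rates[strategy]
        return derive_arm_rates(self.arms[strategy])

    def with_overrides(self, **kwargs) -> "ModelInputs":
        return replace(self, **kwargs)


# --- configuration file loading -------------------------------------------

_REQUIRED_MODEL_KEYS = ("cycle_length", "n_cycles", "discount_rate", "wtp",
                        "start_age", "sex")
_ARM_KEYS = ("n", "progressions", "transformations", "deaths")


def _require(section: Mapping, key: str, where: str):
    if key not in section:
        raise KeyError(f"config is missing required key '{key}' in '{where}'")
    return section[key]


def load_inputs(path: str | Path) -> ModelInputs:
    """Read a YAML parameter file (plus its life-table CSV) into ModelInputs.

    The life-table path in the config is resolved relative to the config
    file's directory. Every scalar must be present; a missing key raises a
    KeyError naming it.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} did not parse to a mapping")

    model = _require(raw, "model", "top level")
    config = ModelConfig(
        cycle_length=float(_require(model, "cycle_length", "model")),
        n_cycles=int(_require(model, "n_cycles", "model")),
        discount_rate=float(_require(model, "discount_rate", "model")),
        wtp=float(_require(model, "wtp", "model")),
        start_age=float(_require(model, "start_age", "model")),
        sex=str(_require(model, "sex", "model")),
        currency_year=int(model.get("currency_year", 2022)),
    )

    costs = CostInputs(**{k: v for k, v in _require(raw, "costs", "top level").items()})
    utilities = UtilityInputs(**_require(raw, "utilities", "top level"))

    followup = float(_require(raw, "median_followup", "top level"))
    arms = {}
    for name, section in _require(raw, "arms", "top level").items():
        kwargs = {k: int(_require(section, k, f"arms.{name}")) for k in _ARM_KEYS}
        arms[name] = TrialArmData(arm_name=name, median_followup=followup, **kwargs)

    adverse = {}
    for name, section in _require(raw, "adverse_events", "top level").items():
        adverse[name] = AdverseEventRates(
            admission_incidence=float(section.get("admission_incidence", 0.0)),
            pegfilgrastim_incidence=float(section.get("pegfilgrastim_incidence", 0.0)),
        )

    lt_path = Path(_require(raw, "life_table", "top level"))
    if not lt_path.is_absolute():
        lt_path = path.parent / lt_path
    life_table = LifeTable.from_csv(lt_path)

    return ModelInputs(
        config=config,
        costs=costs,
        utilities=utilities,
        arms=arms,
        adverse_events=adverse,
        life_table=life_table,
        post_failure_death_rate=float(
            _require(raw, "post_failure_death_rate", "top level")
        ),
        provenance=dict(raw.get("provenance", {})),
    )


def fixture_inputs() -> ModelInputs:
    """The packaged base-case parameter set (printed values + documented
    reconstructions, with a synthetic life table)."""
    from importlib.resources import files

    return load_inputs(files("flcea").joinpath("data/fixture_config.yaml"))
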