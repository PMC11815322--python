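"""Cohort state-transition engine.

Builds one transition matrix per half-year cycle from competing per-annum
rates and age-dependent background mortality, propagates a unit cohort,
and accumulates half-cycle-corrected, discounted costs and QALYs.

Competing-risk construction: the total probability of leaving the
failure-free state over a cycle of length dt is 1 - exp(-(sum of rates)*dt),
apportioned among destinations in proportion to their rates. This is exact
for competing exponential processes and guarantees row-stochastic matrices
for any non-negative rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    N_STATES,
    ArmRates,
    HealthState,
    LifeTable,
    ModelConfig,
    ModelInputs,
)

__all__ = [
    "TransitionMatrix",
    "CohortTrace",
    "EconomicResult",
    "build_matrix",
    "build_matrices",
    "run_cohort",
    "accumulate",
    "run_strategy",
    "run_all_strategies",
]

_ROW_SUM_TOL = 1e-10
S = HealthState  # local alias


@dataclass(frozen=True)
class TransitionMatrix:
    """One cycle's transition probabilities plus its cycle index and the
    cohort age at the start of the cycle."""

    probs: np.ndarray
    cycle_index: int
    age: float

    def __post_init__(self) -> None:
        p = self.probs
        if p.shape != (N_STATES, N_STATES):
            raise ValueError(f"expected {(N_STATES, N_STATES)} matrix")
        if (p < -1e-15).any() or (p > 1 + 1e-15).any():
            raise ValueError("transition probabilities outside [0, 1]")
        rows = p.sum(axis=1)
        if np.abs(rows - 1.0).max() > _ROW_SUM_TOL:
            raise ValueError(f"rows not stochastic: sums {rows}")


@dataclass
class CohortTrace:
    """State occupancy of the unit cohort over time.

    ``occupancy`` has n_cycles + 1 rows (cycle boundaries); ``first_entries``
    has n_cycles rows and records the cohort fraction newly arriving in each
    state during each cycle — the hook for one-off costs and disutilities.
    """

    occupancy: np.ndarray
    first_entries: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.first_entries.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        cols = [s.name for s in HealthState]
        df = pd.DataFrame(self.occupancy, columns=cols)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        # the final occupancy row closes the last cycle; it has no entry flow
        entries = pd.DataFrame(
            np.vstack([self.first_entries, np.zeros((1, N_STATES))]),
            columns=[f"enter_{c}" for c in cols],
        )
        return pd.concat([df, entries[["enter_FAILURE", "enter_TRANSFORMATION",
                                       "enter_POST_ASCT"]]], axis=1)


@dataclass(frozen=True)
class EconomicResult:
    """Discounted (and undiscounted) cost and QALY totals for one strategy."""

    strategy: str
    cost: float
    qaly: float
    undiscounted_cost: float
    undiscounted_qaly: float


def _split_exit(rates: dict[HealthState, float], dt: float) -> dict[HealthState, float]:
    """Competing-exponential apportionment of a cycle's exit probability."""
    total = sum(rates.values())
    if total <= 0:
        return {dest: 0.0 for dest in rates}
    p_exit = -np.expm1(-total * dt)
    return {dest: p_exit * r / total for dest, r in rates.items()}


def build_matrix(
    rates: ArmRates,
    life_table: LifeTable,
    config: ModelConfig,
    cycle_index: int,
    post_failure_death_rate: float = 0.0,
    asct_age_limit: float = 65.0,
) -> TransitionMatrix:
    """Transition matrix for one cycle.

    From FFS the competing exits are progression (-> FAILURE), transformation
    (-> POST_ASCT while the cohort is younger than ``asct_age_limit`` at the
    start of the cycle, else -> TRANSFORMATION), disease death and background
    death. From the three progressed states only disease death (at
    ``post_failure_death_rate``) and background death compete. Death states
    are absorbing.
    """
    age = config.start_age + cycle_index * config.cycle_length
    dt = config.cycle_length
    r_bg = life_table.background_rate(age, config.sex)

    m = np.zeros((N_STATES, N_STATES))

    transform_dest = S.POST_ASCT if age < asct_age_limit else S.TRANSFORMATION
    ffs_exits = _split_exit(
        {
            S.FAILURE: rates.progression,
            transform_dest: rates.transformation,
            S.DEATH_DISEASE: rates.disease_death,
            S.DEATH_BACKGROUND: r_bg,
        },
        dt,
    )
    for dest, p in ffs_exits.items():
        m[S.FFS, dest] += p
    m[S.FFS, S.FFS] = 1.0 - m[S.FFS].sum()

    for state in (S.FAILURE, S.TRANSFORMATION, S.POST_ASCT):
        exits = _split_exit(
            {S.DEATH_DISEASE: post_failure_death_rate, S.DEATH_BACKGROUND: r_bg},
            dt,
        )
        for dest, p in exits.items():
            m[state, dest] = p
        m[state, state] = 1.0 - sum(exits.values())

    for state in (S.DEATH_DISEASE, S.DEATH_BACKGROUND):
        m[state, state] = 1.0

    return TransitionMatrix(probs=m, cycle_index=cycle_index, age=age)


def build_matrices(
    rates: ArmRates,
    life_table: LifeTable,
    config: ModelConfig,
    post_failure_death_rate: float = 0.0,
) -> list[TransitionMatrix]:
    return [
        build_matrix(rates, life_table, config, t, post_failure_death_rate)
        for t in range(config.n_cycles)
    ]


def run_cohort(
    matrices: list[TransitionMatrix],
    config: ModelConfig,
    initial: np.ndarray | None = None,
) -> CohortTrace:
    """Propagate the cohort: row t+1 = row t @ matrix t.

    The first-entry ledger records, for each cycle, the fraction flowing into
    each state from *other* states during that cycle.
    """
    if len(matrices) != config.n_cycles:
        raise ValueError(
            f"need {config.n_cycles} matrices, got {len(matrices)}"
        )
    if initial is None:
        initial = np.zeros(N_STATES)
        initial[S.FFS] = 1.0
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (N_STATES,):
        raise ValueError("initial distribution has wrong length")

    occ = np.zeros((config.n_cycles + 1, N_STATES))
    entries = np.zeros((config.n_cycles, N_STATES))
    occ[0] = initial
    for t, tm in enumerate(matrices):
        p = tm.probs
        occ[t + 1] = occ[t] @ p
        # inflow from other states only (diagonal excluded)
        entries[t] = occ[t] @ p - occ[t] * np.diag(p)
        if abs(occ[t + 1].sum() - 1.0) > _ROW_SUM_TOL:
            raise ValueError(f"cohort mass not conserved at cycle {t}")
    return CohortTrace(occupancy=occ, first_entries=entries)


def _frontline(inputs: ModelInputs, strategy: str) -> tuple[float, float]:
    """(one-off front-line cost, one-off front-line disutility) in cycle 1."""
    c = inputs.costs
    u = inputs.utilities
    ae = inputs.adverse_events.get(strategy)
    cost = c.rt_course
    disutility = u.d_rt
    if strategy == "RT+CVP":
        cost += c.cvp_course
        disutility += u.d_systemic
    elif strategy == "RT+R-CVP":
        cost += c.rcvp_course
        disutility += u.d_systemic
    elif strategy != "RT":
        raise ValueError(f"unknown strategy {strategy!r}")
    if ae is not None:
        cost += (
            ae.admission_incidence * c.adverse_event_admission
            + ae.pegfilgrastim_incidence * c.pegfilgrastim
        )
    return cost, disutility


def accumulate(
    trace: CohortTrace,
    inputs: ModelInputs,
    strategy: str,
) -> EconomicResult:
    """Accumulate discounted cost and QALY totals from a cohort trace.

    State rewards (utility x occupancy x cycle length) use the half-cycle
    corrected occupancy (mean of start- and end-of-cycle occupancy) and are
    discounted at mid-cycle. One-off flows — front-line therapy and expected
    adverse-event costs in cycle 1, R-CHOP on first entry into any failed
    state, transplant cost and disutility on entry into POST_ASCT — attach to
    the first-entry ledger, undiscounted within the cycle (cycle-start
    discounting) and exempt from half-cycle correction.
    """
    cfg = inputs.config
    c = inputs.costs
    u = inputs.utilities
    dt = cfg.cycle_length
    r = cfg.discount_rate
    state_u = u.state_utilities()

    frontline_cost, frontline_disutility = _frontline(inputs, strategy)

    occ = trace.occupancy
    entries = trace.first_entries
    rchop_states = (S.FAILURE, S.TRANSFORMATION, S.POST_ASCT)

    totals = {}
    for discounted in (True, False):
        cost_total = 0.0
        qaly_total = 0.0
        for t in range(trace.n_cycles):
            d_mid = (1 + r) ** (-(t + 0.5) * dt) if discounted else 1.0
            d_start = (1 + r) ** (-t * dt) if discounted else 1.0

            hcc = 0.5 * (occ[t] + occ[t + 1])
            qaly_total += float(state_u @ hcc) * dt * d_mid

            rchop_inflow = float(entries[t, list(rchop_states)].sum())
            asct_inflow = float(entries[t, S.POST_ASCT])
            cost_total += (c.rchop_course * rchop_inflow + c.asct * asct_inflow) * d_start
            qaly_total += u.d_asct * dt * asct_inflow * d_start

            if t == 0:
                treated = float(occ[0, S.FFS])
                cost_total += frontline_cost * treated * d_start
                qaly_total += frontline_disutility * dt * treated * d_start
        totals[discounted] = (cost_total, qaly_total)

    return EconomicResult(
        strategy=strategy,
        cost=totals[True][0],
        qaly=totals[True][1],
        undiscounted_cost=totals[False][0],
        undiscounted_qaly=totals[False][1],
    )


def run_strategy(strategy: str, inputs: ModelInputs) -> EconomicResult:
    """build_matrix -> run_cohort -> accumulate for one strategy."""
    if strategy not in inputs.arms:
        raise ValueError(f"unknown strategy {strategy!r}")
    rates = inputs.arm_rates(strategy)
    matrices = build_matrices(
        rates, inputs.life_table, inputs.config, inputs.post_failure_death_rate
    )
    trace = run_cohort(matrices, inputs.config)
    return accumulate(trace, inputs, strategy)


def run_all_strategies(inputs: ModelInputs) -> list[EconomicResult]:
    return [run_strategy(s, inputs) for s in inputs.arms]
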