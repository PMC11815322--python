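"""Synthetic data: trial arms, life tables, and a microsimulation oracle.

The trial generator draws competing exponential first-event times
(progression, transformation, death) per patient with administrative
censoring at a single follow-up horizon — the statistical structure the
rate-based cohort model assumes. ``recover_rates`` closes the loop: counts
from a simulated arm go back through the person-time rate derivation, so
the approximation error of that derivation can be measured against known
truth.

The microsimulation pushes individual patients through exactly the same
per-cycle transition matrices and reward conventions as the cohort engine
(half-cycle-corrected state rewards, one-off flows at state entry), giving
an independent Monte-Carlo estimate of the same expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import build_matrices, _frontline
from .parameters import (
    N_STATES,
    ArmRates,
    HealthState,
    LifeTable,
    ModelInputs,
    TrialArmData,
    derive_arm_rates,
)

__all__ = [
    "SyntheticTrialResult",
    "MicrosimResult",
    "simulate_arm",
    "simulate_trial",
    "recover_rates",
    "synthetic_life_table",
    "microsim",
]

S = HealthState
EVENT_TYPES = ("progression", "transformation", "death")


@dataclass
class SyntheticTrialResult:
    """Per-patient first events for one simulated arm.

    ``event_type`` is the index into EVENT_TYPES, or -1 for patients
    censored event-free at the follow-up horizon; ``event_time`` is the
    first-event time (censored patients carry the follow-up time).
    """

    arm_name: str
    n: int
    followup: float
    event_type: np.ndarray
    event_time: np.ndarray

    @property
    def counts(self) -> dict[str, int]:
        return {
            name: int((self.event_type == k).sum())
            for k, name in enumerate(EVENT_TYPES)
        }

    def to_trial_arm_data(self) -> TrialArmData:
        c = self.counts
        return TrialArmData(
            arm_name=self.arm_name,
            n=self.n,
            progressions=c["progression"],
            transformations=c["transformation"],
            deaths=c["death"],
            median_followup=self.followup,
        )

    def to_dataframe(self) -> pd.DataFrame:
        labels = np.array(EVENT_TYPES + ("censored",))
        return pd.DataFrame(
            {
                "arm": self.arm_name,
                "event_type": labels[self.event_type],
                "event_time": self.event_time,
                "censored": self.event_type == -1,
            }
        )


def simulate_arm(
    n: int,
    hazards: ArmRates | tuple[float, float, float],
    followup: float,
    seed: int | np.random.Generator = 0,
    arm_name: str = "arm",
) -> SyntheticTrialResult:
    """Simulate one arm under competing exponential hazards.

    Each patient's time to each event type is exponential with the given
    per-annum hazard; the earliest event before ``followup`` is recorded,
    otherwise the patient is censored.
    """
    if isinstance(hazards, ArmRates):
        lam = np.array([hazards.progression, hazards.transformation,
                        hazards.disease_death])
    else:
        lam = np.asarray(hazards, dtype=float)
    if (lam < 0).any():
        raise ValueError("hazards must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    times = np.full((n, len(lam)), np.inf)
    positive = lam > 0
    if positive.any():
        times[:, positive] = rng.exponential(
            1.0 / lam[positive], size=(n, int(positive.sum()))
        )
    first = times.argmin(axis=1)
    t_first = times[np.arange(n), first]
    censored = t_first > followup
    event_type = np.where(censored, -1, first).astype(int)
    event_time = np.where(censored, followup, t_first)
    return SyntheticTrialResult(
        arm_name=arm_name, n=n, followup=followup,
        event_type=event_type, event_time=event_time,
    )


def simulate_trial(
    arm_specs: dict[str, tuple[int, ArmRates]],
    followup: float = 11.3,
    seed: int = 0,
) -> dict[str, SyntheticTrialResult]:
    """Simulate a multi-arm trial; each arm gets an independent substream."""
    rng = np.random.default_rng(seed)
    return {
        name: simulate_arm(n, rates, followup, rng, arm_name=name)
        for name, (n, rates) in arm_specs.items()
    }


def recover_rates(result: SyntheticTrialResult) -> ArmRates:
    """Person-time rate estimates from a simulated arm's counts.

    Applies the same events/(n x follow-up) derivation used on the real
    counts. Unbiased only as total event probability -> 0; at realistic
    event probabilities the denominator overstates person-time at risk and
    the estimate is biased downward.
    """
    return derive_arm_rates(result.to_trial_arm_data())


def synthetic_life_table(
    start_age: int = 50,
    end_age: int = 85,
    base_qx: float = 0.0032,
    annual_increase: float = 0.093,
    sex: str = "male",
) -> LifeTable:
    """Gompertz-like annual mortality: qx(age) = min(1, base_qx *
    exp(annual_increase * (age - start_age))).

    Defaults approximate a contemporary high-income-country male schedule
    (qx ~ 0.3% at 50 doubling roughly every 7.5 years).
    """
    if not 0 < base_qx < 1:
        raise ValueError("base_qx must be in (0, 1)")
    ages = np.arange(start_age, end_age + 1)
    qx = np.minimum(1.0, base_qx * np.exp(annual_increase * (ages - start_age)))
    return LifeTable(pd.DataFrame({"age": ages, "sex": sex, "qx": qx}))


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo means and standard errors from the individual-level run."""

    strategy: str
    n_patients: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float


def microsim(
    inputs: ModelInputs,
    strategy: str,
    n_patients: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> MicrosimResult:
    """Individual-level simulation through the cohort engine's matrices.

    Every patient starts failure-free and steps through the identical
    per-cycle transition probabilities; rewards copy the cohort conventions:
    per-cycle QALY = mean of start- and end-of-cycle utility x cycle length,
    discounted mid-cycle; one-off flows (front-line therapy in cycle 1,
    adverse events drawn Bernoulli per patient, R-CHOP at entry into a
    failed state, transplant cost and disutility at POST_ASCT entry)
    discounted at cycle start. The sample means estimate exactly the
    quantities the cohort engine computes in expectation.
    """
    cfg = inputs.config
    c = inputs.costs
    u = inputs.utilities
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    matrices = build_matrices(
        inputs.arm_rates(strategy), inputs.life_table, cfg,
        inputs.post_failure_death_rate,
    )
    state_u = u.state_utilities()
    dt = cfg.cycle_length
    r = cfg.discount_rate

    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)

    # cycle-1 one-offs: front-line therapy for everyone, adverse events Bernoulli
    frontline_cost, frontline_disutility = _frontline(
        inputs.with_overrides(adverse_events={}), strategy
    )
    cost += frontline_cost
    qaly += frontline_disutility * dt
    ae = inputs.adverse_events.get(strategy)
    if ae is not None:
        cost += (rng.random(n_patients) < ae.admission_incidence) * c.adverse_event_admission
        cost += (rng.random(n_patients) < ae.pegfilgrastim_incidence) * c.pegfilgrastim

    rchop_states = np.array([S.FAILURE, S.TRANSFORMATION, S.POST_ASCT])
    states = np.full(n_patients, int(S.FFS))
    for t, tm in enumerate(matrices):
        cum = np.cumsum(tm.probs, axis=1)
        draws = rng.random(n_patients)
        new_states = np.empty_like(states)
        for s_val in np.unique(states):
            mask = states == s_val
            new_states[mask] = np.searchsorted(cum[s_val], draws[mask], side="right")
        np.clip(new_states, 0, N_STATES - 1, out=new_states)

        d_mid = (1 + r) ** (-(t + 0.5) * dt)
        d_start = (1 + r) ** (-t * dt)
        qaly += 0.5 * (state_u[states] + state_u[new_states]) * dt * d_mid

        entered = new_states != states
        rchop_entry = entered & np.isin(new_states, rchop_states)
        asct_entry = entered & (new_states == S.POST_ASCT)
        cost += rchop_entry * c.rchop_course * d_start
        cost += asct_entry * c.asct * d_start
        qaly += asct_entry * u.d_asct * dt * d_start

        states = new_states

    return MicrosimResult(
        strategy=strategy,
        n_patients=n_patients,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n_patients)),
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n_patients)),
    )
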