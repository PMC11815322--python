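"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis moves a single parameter to the edges of its plausible
range (costs and transition probabilities +/-30% of base, utilities +/-10%,
annual discount rate 3%-7%) while everything else stays at base case.

The PSA draws every varied parameter independently — gamma for costs, beta
for utilities and transition probabilities — with method-of-moments
parameters chosen so the distribution mean equals the base-case value and
the one-way range spans an approximate 95% interval (sd = range half-width
/ 1.96). Transition intensities are sampled on the per-cycle probability
scale and mapped back to rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import economics
from .markov import EconomicResult, run_strategy
from .parameters import (
    ModelInputs,
    probability_to_rate,
    rate_to_probability,
)

__all__ = [
    "TornadoEntry",
    "GammaDist",
    "BetaDist",
    "PSAResult",
    "parameter_kind",
    "base_value",
    "apply_override",
    "default_varied_parameters",
    "one_way",
    "tornado",
    "fit_gamma",
    "fit_beta",
    "run_psa",
    "quadrant_summary",
    "ceac",
    "icer_outcome",
    "nmb_outcome",
]

SPREAD_COST = 0.30
SPREAD_PROB = 0.30
SPREAD_UTILITY = 0.10
DISCOUNT_RANGE = (0.03, 0.07)

_COST_FIELDS = (
    "rt_simulation", "rt_planning", "rt_fraction", "rt_verification",
    "drug_rituximab", "drug_rcvp", "drug_cvp", "drug_rchop", "day_care",
    "asct", "adverse_event_admission", "pegfilgrastim",
)
_UTILITY_FIELDS = ("u_ffs", "u_progressed", "d_rt", "d_systemic", "d_asct")
_RATE_EVENTS = ("progression", "transformation", "disease_death")


# --- parameter namespace ---------------------------------------------------
#
# Flat dotted names address every varied scalar:
#   cost.<field>                     unit costs
#   utility.<field>                  utilities and (negative) disutilities
#   rate.<arm>.<event>               per-annum transition rates out of FFS
#   rate.post_failure_death          per-annum death rate after failure
#   ae.<arm>.<field>                 adverse-event incidences
#   config.discount_rate             annual discount rate

def parameter_kind(name: str) -> str:
    head = name.split(".", 1)[0]
    if head == "cost":
        return "cost"
    if head == "utility":
        return "utility"
    if head in ("rate", "ae"):
        return "probability"
    if name == "config.discount_rate":
        return "discount"
    raise KeyError(f"unknown parameter {name!r}")


def base_value(inputs: ModelInputs, name: str) -> float:
    parts = name.split(".")
    if parts[0] == "cost":
        if not hasattr(inputs.costs, parts[1]):
            raise KeyError(f"unknown parameter {name!r}")
        return float(getattr(inputs.costs, parts[1]))
    if parts[0] == "utility":
        if not hasattr(inputs.utilities, parts[1]):
            raise KeyError(f"unknown parameter {name!r}")
        return float(getattr(inputs.utilities, parts[1]))
    if parts[0] == "rate":
        if parts[1] == "post_failure_death":
            return inputs.post_failure_death_rate
        arm, event = parts[1], parts[2]
        return float(getattr(inputs.arm_rates(arm), event))
    if parts[0] == "ae":
        return float(getattr(inputs.adverse_events[parts[1]], parts[2]))
    if name == "config.discount_rate":
        return inputs.config.discount_rate
    raise KeyError(f"unknown parameter {name!r}")


def apply_override(inputs: ModelInputs, name: str, value: float) -> ModelInputs:
    """Return a copy of the inputs with one named parameter replaced."""
    parts = name.split(".")
    if parts[0] == "cost":
        if not hasattr(inputs.costs, parts[1]):
            raise KeyError(f"unknown parameter {name!r}")
        return replace(inputs, costs=replace(inputs.costs, **{parts[1]: value}))
    if parts[0] == "utility":
        if not hasattr(inputs.utilities, parts[1]):
            raise KeyError(f"unknown parameter {name!r}")
        return replace(
            inputs, utilities=replace(inputs.utilities, **{parts[1]: value})
        )
    if parts[0] == "rate":
        if parts[1] == "post_failure_death":
            return replace(inputs, post_failure_death_rate=value)
        arm, event = parts[1], parts[2]
        rates = inputs.arm_rates(arm)
        new = {arm: replace(rates, **{event: value})}
        return replace(inputs, explicit_rates={**inputs.explicit_rates, **new})
    if parts[0] == "ae":
        arm, field_name = parts[1], parts[2]
        ae = dict(inputs.adverse_events)
        ae[arm] = replace(ae[arm], **{field_name: value})
        return replace(inputs, adverse_events=ae)
    if name == "config.discount_rate":
        return replace(inputs, config=replace(inputs.config, discount_rate=value))
    raise KeyError(f"unknown parameter {name!r}")


def apply_overrides(inputs: ModelInputs, overrides: Mapping[str, float]) -> ModelInputs:
    for name, value in overrides.items():
        inputs = apply_override(inputs, name, value)
    return inputs


def default_varied_parameters(inputs: ModelInputs) -> list[str]:
    """Every cost, utility and transition parameter with a nonzero base
    value (zero-valued parameters are held fixed — they admit no gamma/beta
    distribution and a +/-30% range collapses to a point)."""
    names: list[str] = []
    for f in _COST_FIELDS:
        if getattr(inputs.costs, f) > 0:
            names.append(f"cost.{f}")
    for f in _UTILITY_FIELDS:
        if getattr(inputs.utilities, f) != 0:
            names.append(f"utility.{f}")
    for arm in inputs.arms:
        rates = inputs.arm_rates(arm)
        for event in _RATE_EVENTS:
            if getattr(rates, event) > 0:
                names.append(f"rate.{arm}.{event}")
    if inputs.post_failure_death_rate > 0:
        names.append("rate.post_failure_death")
    for arm, ae in inputs.adverse_events.items():
        for f in ("admission_incidence", "pegfilgrastim_incidence"):
            if getattr(ae, f) > 0:
                names.append(f"ae.{arm}.{f}")
    return names


# --- one-way / tornado -----------------------------------------------------

@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def bar_width(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _one_way_bounds(name: str, base: float) -> tuple[float, float]:
    kind = parameter_kind(name)
    if kind == "cost":
        return base * (1 - SPREAD_COST), base * (1 + SPREAD_COST)
    if kind == "probability":
        lo, hi = base * (1 - SPREAD_PROB), base * (1 + SPREAD_PROB)
        return max(lo, 0.0), min(hi, 1.0) if name.startswith("ae.") else hi
    if kind == "utility":
        lo, hi = base * (1 - SPREAD_UTILITY), base * (1 + SPREAD_UTILITY)
        if base < 0:  # disutility: widen/narrow on the magnitude
            lo, hi = base * (1 + SPREAD_UTILITY), base * (1 - SPREAD_UTILITY)
            return max(lo, -1.0), min(hi, 0.0)
        return max(lo, 0.0), min(hi, 1.0)
    if kind == "discount":
        return DISCOUNT_RANGE
    raise KeyError(name)


def one_way(
    inputs: ModelInputs,
    name: str,
    outcome_fn: Callable[[list[EconomicResult]], float],
) -> TornadoEntry:
    """Re-run the full model at the lower and upper bound of one parameter.

    ``outcome_fn`` maps the per-strategy results to the scalar of interest
    (an ICER or an NMB difference; see :func:`icer_outcome`,
    :func:`nmb_outcome`).
    """
    base = base_value(inputs, name)
    low, high = _one_way_bounds(name, base)
    results = {}
    for bound in (low, high):
        perturbed = apply_override(inputs, name, bound)
        results[bound] = outcome_fn(
            [run_strategy(s, perturbed) for s in perturbed.arms]
        )
    return TornadoEntry(
        parameter=name,
        low_value=low,
        high_value=high,
        outcome_at_low=results[low],
        outcome_at_high=results[high],
    )


def tornado(
    inputs: ModelInputs,
    outcome_fn: Callable[[list[EconomicResult]], float],
    names: Sequence[str] | None = None,
) -> list[TornadoEntry]:
    """One-way results for many parameters, widest bar first."""
    if names is None:
        names = default_varied_parameters(inputs) + ["config.discount_rate"]
    entries = [one_way(inputs, n, outcome_fn) for n in names]
    return sorted(entries, key=lambda e: e.bar_width, reverse=True)


def icer_outcome(comparator: str, reference: str, wtp: float):
    """Outcome function: pairwise ICER (delta cost / delta QALY)."""

    def fn(results: list[EconomicResult]) -> float:
        by = {r.strategy: r for r in results}
        return economics.compare_pair(by[comparator], by[reference], wtp).icer

    return fn


def nmb_outcome(comparator: str, reference: str, wtp: float):
    """Outcome function: incremental net monetary benefit at the WTP."""

    def fn(results: list[EconomicResult]) -> float:
        by = {r.strategy: r for r in results}
        return (
            economics.net_monetary_benefit(by[comparator].cost, by[comparator].qaly, wtp)
            - economics.net_monetary_benefit(by[reference].cost, by[reference].qaly, wtp)
        )

    return fn


# --- PSA distributions -----------------------------------------------------

@dataclass(frozen=True)
class GammaDist:
    """Gamma distribution parameterised by shape and rate (1/scale)."""

    shape: float
    rate: float

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) / self.rate

    def sample(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


@dataclass(frozen=True)
class BetaDist:
    alpha: float
    beta: float

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))

    def sample(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)


@dataclass(frozen=True)
class DegenerateDist:
    """Point mass: the sd -> 0 limit of the fitted distributions."""

    value: float

    @property
    def mean(self) -> float:
        return self.value

    @property
    def sd(self) -> float:
        return 0.0

    def sample(self, rng: np.random.Generator, size=None):
        return self.value if size is None else np.full(size, self.value)


def fit_gamma(mean: float, spread: float = SPREAD_COST) -> GammaDist | DegenerateDist:
    """Gamma by method of moments: sd = spread*mean/1.96 so that the +/-spread
    one-way range is an approximate 95% interval."""
    if mean <= 0:
        raise ValueError("gamma mean must be > 0 (zero-cost parameters stay fixed)")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    sd = spread * mean / 1.96
    if sd == 0:
        return DegenerateDist(mean)
    shape = mean**2 / sd**2
    rate = mean / sd**2
    return GammaDist(shape=shape, rate=rate)


def fit_beta(mean: float, spread: float = SPREAD_UTILITY) -> BetaDist | DegenerateDist:
    """Beta by method of moments with the same spread-to-sd mapping; the sd
    is capped below the feasibility bound sqrt(mean*(1-mean))."""
    if not 0 < mean < 1:
        raise ValueError("beta mean must be in (0, 1)")
    if spread < 0:
        raise ValueError("spread must be >= 0")
    sd = spread * mean / 1.96
    cap = 0.99 * math.sqrt(mean * (1 - mean))
    sd = min(sd, cap)
    if sd == 0:
        return DegenerateDist(mean)
    nu = mean * (1 - mean) / sd**2 - 1
    return BetaDist(alpha=mean * nu, beta=(1 - mean) * nu)


# --- probabilistic sensitivity analysis ------------------------------------

@dataclass
class PSAResult:
    """Monte-Carlo draws of parameters with their per-strategy outcomes.

    ``params`` is one row per draw, one column per varied parameter;
    ``outcomes`` holds ``cost_<strategy>`` and ``qaly_<strategy>`` columns.
    """

    params: pd.DataFrame
    outcomes: pd.DataFrame
    strategies: tuple[str, ...]
    n_rejected: int = 0

    @property
    def n_iter(self) -> int:
        return len(self.outcomes)

    def deltas(self, comparator: str, reference: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "delta_cost": self.outcomes[f"cost_{comparator}"]
                - self.outcomes[f"cost_{reference}"],
                "delta_qaly": self.outcomes[f"qaly_{comparator}"]
                - self.outcomes[f"qaly_{reference}"],
            }
        )

    def scatter_table(self, pairs: Iterable[tuple[str, str]]) -> pd.DataFrame:
        out = {"draw": np.arange(self.n_iter)}
        for comp, ref in pairs:
            d = self.deltas(comp, ref)
            key = f"{comp}_vs_{ref}".replace(" ", "")
            out[f"delta_cost_{key}"] = d["delta_cost"].to_numpy()
            out[f"delta_qaly_{key}"] = d["delta_qaly"].to_numpy()
        return pd.DataFrame(out)


def _sample_parameter(
    name: str,
    base: float,
    rng: np.random.Generator,
    cycle_length: float,
    spreads: Mapping[str, float],
) -> float:
    kind = parameter_kind(name)
    if kind == "cost":
        spread = spreads["cost"]
        if spread == 0 or base == 0:
            return base
        return float(fit_gamma(base, spread).sample(rng))
    if kind == "utility":
        spread = spreads["utility"]
        if spread == 0 or base == 0:
            return base
        if base < 0:  # disutility: beta on the magnitude, then negate
            return -float(fit_beta(-base, spread).sample(rng))
        return float(fit_beta(base, spread).sample(rng))
    if kind == "probability":
        spread = spreads["probability"]
        if spread == 0 or base == 0:
            return base
        if name.startswith("ae."):
            return float(fit_beta(base, spread).sample(rng))
        # transition intensity: sample on the per-cycle probability scale
        p = rate_to_probability(base, cycle_length)
        p_draw = float(fit_beta(p, spread).sample(rng))
        return probability_to_rate(p_draw, cycle_length)
    raise KeyError(f"parameter {name!r} cannot be sampled")


def run_psa(
    inputs: ModelInputs,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    varied: Sequence[str] | None = None,
    spreads: Mapping[str, float] | None = None,
    max_reject_fraction: float = 0.01,
) -> PSAResult:
    """Monte-Carlo PSA: ``n_iter`` independent joint draws of all varied
    parameters, each propagated through the full three-strategy model.

    Draws whose parameter set is infeasible (e.g. a sampled per-cycle
    probability of exactly 1) are redrawn; more than ``max_reject_fraction``
    rejections aborts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if varied is None:
        varied = default_varied_parameters(inputs)
    if spreads is None:
        spreads = {}
    spreads = {
        "cost": SPREAD_COST,
        "probability": SPREAD_PROB,
        "utility": SPREAD_UTILITY,
        **spreads,
    }
    bases = {name: base_value(inputs, name) for name in varied}
    strategies = tuple(inputs.arms)
    dt = inputs.config.cycle_length

    param_rows = []
    outcome_rows = []
    n_rejected = 0
    for _ in range(n_iter):
        while True:
            try:
                draw = {
                    name: _sample_parameter(name, bases[name], rng, dt, spreads)
                    for name in varied
                }
                perturbed = apply_overrides(inputs, draw)
                results = [run_strategy(s, perturbed) for s in strategies]
            except (ValueError, OverflowError):
                n_rejected += 1
                if n_rejected > max(1, max_reject_fraction * n_iter):
                    raise RuntimeError(
                        f"PSA rejected {n_rejected} draws (> "
                        f"{max_reject_fraction:.0%} of {n_iter})"
                    )
                continue
            break
        param_rows.append(draw)
        row = {}
        for res in results:
            row[f"cost_{res.strategy}"] = res.cost
            row[f"qaly_{res.strategy}"] = res.qaly
        outcome_rows.append(row)

    return PSAResult(
        params=pd.DataFrame(param_rows, columns=list(varied)),
        outcomes=pd.DataFrame(outcome_rows),
        strategies=strategies,
        n_rejected=n_rejected,
    )


def quadrant_summary(
    psa: PSAResult, comparator: str, reference: str, wtp: float
) -> dict[str, float]:
    """Fractions of PSA draws in each quadrant of the incremental
    cost-effectiveness plane, plus the fraction cost-effective at the WTP
    (positive incremental NMB).

    Quadrants are named for the scatter-plot geometry with QALYs on x and
    cost on y: lower_right = more effective and cheaper (dominant),
    upper_right = more effective, dearer; boundary draws (a delta exactly 0)
    count toward the 'right'/'lower' side.
    """
    if psa.n_iter == 0:
        raise ValueError("no PSA samples")
    d = psa.deltas(comparator, reference)
    de = d["delta_qaly"].to_numpy()
    dc = d["delta_cost"].to_numpy()
    right = de >= 0
    lower = dc <= 0
    n = len(de)
    frac = {
        "lower_right": float((right & lower).mean()),
        "upper_right": float((right & ~lower).mean()),
        "lower_left": float((~right & lower).mean()),
        "upper_left": float((~right & ~lower).mean()),
    }
    frac["cost_effective"] = float((wtp * de - dc > 0).mean())
    return frac


def ceac(
    psa: PSAResult,
    wtp_grid: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    At each WTP value the probability that each strategy attains the maximal
    net monetary benefit across draws; exact ties split their draw's weight
    equally. Rows sum to 1.
    """
    if wtp_grid is None:
        wtp_grid = np.arange(0, 100_001, 2500)
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    strategies = psa.strategies
    if len(strategies) < 1:
        raise ValueError("need at least one strategy")

    costs = np.column_stack([psa.outcomes[f"cost_{s}"] for s in strategies])
    qalys = np.column_stack([psa.outcomes[f"qaly_{s}"] for s in strategies])
    rows = []
    for wtp in wtp_grid:
        nmb = wtp * qalys - costs  # (n_iter, n_strategies)
        best = nmb.max(axis=1, keepdims=True)
        is_best = nmb >= best - 1e-12 * np.maximum(1.0, np.abs(best))
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        rows.append({"wtp": wtp, **dict(zip(strategies, probs))})
    return pd.DataFrame(rows)
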