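"""Incremental cost-effectiveness analysis.

Pairwise incremental costs and QALYs, ICERs with dominance classification,
net monetary benefit, and an optional efficiency frontier with extended
dominance. Incremental quantities are computed from unrounded model outputs;
rounding happens only when a table is exported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .markov import EconomicResult

__all__ = [
    "IncrementalResult",
    "regimen_total_cost",
    "rt_course_cost",
    "net_monetary_benefit",
    "incremental_analysis",
    "compare_pair",
    "efficiency_frontier",
    "incremental_table",
]

VERDICTS = ("dominant", "dominated", "icer_below_wtp", "icer_above_wtp",
            "indifferent")


def regimen_total_cost(per_cycle_drug: float, day_care: float, n_cycles: int) -> float:
    """Total systemic-regimen cost: (drug + day-care per cycle) x cycles."""
    if per_cycle_drug < 0 or day_care < 0 or n_cycles < 0:
        raise ValueError("costs and cycle count must be >= 0")
    return (per_cycle_drug + day_care) * n_cycles


def rt_course_cost(
    sim: float, plan: float, fraction: float, verification: float, n_fractions: int
) -> float:
    """Radiotherapy course cost: simulation + plan + per-fraction charges."""
    if min(sim, plan, fraction, verification, n_fractions) < 0:
        raise ValueError("costs and fraction count must be >= 0")
    return sim + plan + n_fractions * (fraction + verification)


def net_monetary_benefit(cost: float, qaly: float, wtp: float) -> float:
    """NMB = WTP x QALYs - cost; positive differences favour a strategy."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return wtp * qaly - cost


@dataclass(frozen=True)
class IncrementalResult:
    """One pairwise comparison (comparator minus reference)."""

    comparator: str
    reference: str
    delta_cost: float
    delta_qaly: float
    icer: float          # currency per QALY; +/-inf when delta_qaly == 0; nan if indifferent
    verdict: str

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")


def compare_pair(
    comparator: EconomicResult, reference: EconomicResult, wtp: float
) -> IncrementalResult:
    """Classify comparator vs reference.

    dominant: cheaper and more effective. dominated: dearer and less
    effective. Otherwise the ICER trades cost against QALYs and the verdict
    reflects whether the trade is acceptable at the WTP (equivalently,
    whether the comparator's NMB is higher). With equal QALYs the ICER is
    signed infinity: a pure cost difference.
    """
    dc = comparator.cost - reference.cost
    de = comparator.qaly - reference.qaly

    if dc == 0 and de == 0:
        return IncrementalResult(comparator.strategy, reference.strategy,
                                 0.0, 0.0, math.nan, "indifferent")
    if dc < 0 and de >= 0:
        icer = dc / de if de != 0 else -math.inf
        return IncrementalResult(comparator.strategy, reference.strategy,
                                 dc, de, icer, "dominant")
    if dc > 0 and de <= 0:
        icer = dc / de if de != 0 else math.inf
        return IncrementalResult(comparator.strategy, reference.strategy,
                                 dc, de, icer, "dominated")
    icer = dc / de
    nmb_gain = wtp * de - dc
    verdict = "icer_below_wtp" if nmb_gain > 0 else "icer_above_wtp"
    return IncrementalResult(comparator.strategy, reference.strategy,
                             dc, de, icer, verdict)


def incremental_analysis(
    results: Sequence[EconomicResult],
    reference: str,
    wtp: float,
    extra_pairs: Iterable[tuple[str, str]] = (),
) -> list[IncrementalResult]:
    """Compare every non-reference strategy against the reference, plus any
    explicitly requested (comparator, reference) pairs."""
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")
    by_name = {r.strategy: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference strategy {reference!r} not in results")

    out = [
        compare_pair(by_name[name], by_name[reference], wtp)
        for name in names
        if name != reference
    ]
    for comp, ref in extra_pairs:
        out.append(compare_pair(by_name[comp], by_name[ref], wtp))
    return out


def efficiency_frontier(results: Sequence[EconomicResult]) -> list[EconomicResult]:
    """Strategies on the cost-effectiveness frontier.

    Sorts by QALYs, drops strictly dominated strategies, then removes
    extended dominance (a strategy whose incremental ICER exceeds that of
    the next frontier step).
    """
    ordered = sorted(results, key=lambda r: (r.qaly, -r.cost))
    # strict dominance: keep strategies whose cost is below every more
    # effective alternative's cost
    frontier: list[EconomicResult] = []
    for r in ordered:
        while frontier and frontier[-1].cost >= r.cost:
            frontier.pop()
        frontier.append(r)
    # extended dominance: ICERs along the frontier must be increasing
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = frontier[i - 1], frontier[i], frontier[i + 1]
            icer_lo = (mid.cost - lo.cost) / (mid.qaly - lo.qaly)
            icer_hi = (hi.cost - mid.cost) / (hi.qaly - mid.qaly)
            if icer_lo >= icer_hi:
                frontier.pop(i)
                changed = True
                break
    return frontier


def incremental_table(
    results: Sequence[EconomicResult],
    reference: str,
    wtp: float,
    extra_pairs: Iterable[tuple[str, str]] = (),
) -> pd.DataFrame:
    """Report-style table: per-strategy totals then incremental rows,
    rounded at report time (costs to the dollar, QALYs to 3 dp)."""
    rows = [
        {"strategy": r.strategy, "cost": round(r.cost, 2),
         "qaly": round(r.qaly, 3), "icer": ""}
        for r in results
    ]
    for inc in incremental_analysis(results, reference, wtp, extra_pairs):
        if inc.verdict in ("dominant", "dominated", "indifferent"):
            icer_repr = inc.verdict
        else:
            icer_repr = f"{inc.icer:.0f}"
        rows.append(
            {
                "strategy": f"{inc.comparator} vs. {inc.reference}",
                "cost": round(inc.delta_cost, 2),
                "qaly": round(inc.delta_qaly, 3),
                "icer": icer_repr,
            }
        )
    return pd.DataFrame(rows)
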