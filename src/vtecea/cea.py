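"""Incremental cost-effectiveness comparison.

Builds the incremental table from per-strategy expectations: strategies are
sorted by expected cost, strongly dominated ones (more costly, no more
effective than some other strategy) and extendedly dominated ones (ICER above
that of a more effective frontier strategy) are flagged, and incremental
cost-effectiveness ratios are computed along the efficiency frontier.

The ICER between two strategies is ΔCost / ΔEffectiveness, in R$ per adverse
event avoided.  The net monetary benefit at willingness-to-pay λ is
λ × effectiveness − cost; maximizing NMB is the decision rule the
acceptability curve uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .tree import CEResult

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "EXTENDEDLY_DOMINATED",
    "REFERENCE",
    "TIE",
    "icer",
    "IncrementalRow",
    "incremental_table",
    "incremental_frame",
    "net_monetary_benefit",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EXTENDEDLY_DOMINATED = "extendedly dominated"
REFERENCE = "reference"
TIE = "tie"


def icer(delta_cost: float, delta_effect: float) -> float | str:
    """ΔCost/ΔEffect, or a dominance status when the ratio is not meaningful.

    Numeric in the trade-off quadrants (both deltas positive, or — read from
    the cheaper comparator's perspective — both negative); ``"dominant"``
    when the comparator is no costlier and no less effective (and not
    identical); ``"dominated"`` for the reverse; ``"tie"`` when both deltas
    are zero.
    """
    if delta_cost == 0.0 and delta_effect == 0.0:
        return TIE
    if delta_cost <= 0.0 and delta_effect >= 0.0:
        return DOMINANT
    if delta_cost >= 0.0 and delta_effect <= 0.0:
        return DOMINATED
    return delta_cost / delta_effect


@dataclass(frozen=True)
class IncrementalRow:
    """One strategy's row of the incremental comparison table."""

    strategy_label: str
    expected_cost: float
    expected_effectiveness: float
    incremental_cost: float | None  # vs the previous frontier strategy
    incremental_effectiveness: float | None
    icer: float | None
    status: str  # REFERENCE / DOMINATED / EXTENDEDLY_DOMINATED / TIE or "" (numeric ICER row)


def _strongly_dominated(results: list[CEResult]) -> set[int]:
    flagged: set[int] = set()
    for i, a in enumerate(results):
        for j, b in enumerate(results):
            if i == j:
                continue
            cheaper = b.expected_cost <= a.expected_cost
            better = b.expected_effectiveness >= a.expected_effectiveness
            strictly = (
                b.expected_cost < a.expected_cost
                or b.expected_effectiveness > a.expected_effectiveness
            )
            if cheaper and better and strictly:
                flagged.add(i)
    return flagged


def incremental_table(results: list[CEResult]) -> list[IncrementalRow]:
    """Full dominance analysis and frontier ICERs for ≥ 2 strategies.

    Rows come back sorted by ascending expected cost.  The cheapest strategy
    on the frontier is the reference; each subsequent frontier strategy's
    ICER is taken against the previous frontier member.  Extended dominance
    is removed iteratively (a strategy whose ICER exceeds that of the next,
    more effective frontier strategy is excluded and ICERs recomputed).
    """
    if len(results) < 2:
        raise ValueError("incremental comparison requires at least 2 strategies")

    order = sorted(
        range(len(results)),
        key=lambda i: (results[i].expected_cost, -results[i].expected_effectiveness),
    )
    sorted_results = [results[i] for i in order]

    dominated = _strongly_dominated(sorted_results)
    # exact ties: the later row is flagged as a tie, not dominated
    ties: set[int] = set()
    for i in range(1, len(sorted_results)):
        for j in range(i):
            if (
                sorted_results[i].expected_cost == sorted_results[j].expected_cost
                and sorted_results[i].expected_effectiveness
                == sorted_results[j].expected_effectiveness
            ):
                ties.add(i)
                dominated.discard(i)

    candidates = [i for i in range(len(sorted_results)) if i not in dominated and i not in ties]
    extended: set[int] = set()
    while True:
        frontier = [i for i in candidates if i not in extended]
        icers: dict[int, float] = {}
        violator = None
        for prev, cur in zip(frontier, frontier[1:]):
            d_cost = sorted_results[cur].expected_cost - sorted_results[prev].expected_cost
            d_eff = (
                sorted_results[cur].expected_effectiveness
                - sorted_results[prev].expected_effectiveness
            )
            icers[cur] = d_cost / d_eff if d_eff > 0 else math.inf
        for prev, cur in zip(frontier[1:], frontier[2:]):
            if icers[prev] > icers[cur]:
                violator = prev
                break
        if violator is None:
            break
        extended.add(violator)

    frontier = [i for i in candidates if i not in extended]
    rows: list[IncrementalRow] = []
    prev_on_frontier: dict[int, int] = {
        cur: prev for prev, cur in zip(frontier, frontier[1:])
    }
    for i, result in enumerate(sorted_results):
        label = result.strategy.label
        if i in ties:
            rows.append(
                IncrementalRow(label, result.expected_cost, result.expected_effectiveness,
                               None, None, None, TIE)
            )
        elif i in dominated:
            rows.append(
                IncrementalRow(label, result.expected_cost, result.expected_effectiveness,
                               None, None, None, DOMINATED)
            )
        elif i in extended:
            rows.append(
                IncrementalRow(label, result.expected_cost, result.expected_effectiveness,
                               None, None, None, EXTENDEDLY_DOMINATED)
            )
        elif i not in prev_on_frontier:
            rows.append(
                IncrementalRow(label, result.expected_cost, result.expected_effectiveness,
                               None, None, None, REFERENCE)
            )
        else:
            ref = sorted_results[prev_on_frontier[i]]
            d_cost = result.expected_cost - ref.expected_cost
            d_eff = result.expected_effectiveness - ref.expected_effectiveness
            rows.append(
                IncrementalRow(label, result.expected_cost, result.expected_effectiveness,
                               d_cost, d_eff, d_cost / d_eff, "")
            )
    return rows


def incremental_frame(rows: list[IncrementalRow]) -> pd.DataFrame:
    """Incremental table as a DataFrame mirroring the published columns."""
    return pd.DataFrame(
        {
            "strategy": [r.strategy_label for r in rows],
            "cost": [r.expected_cost for r in rows],
            "incremental_cost": [r.incremental_cost for r in rows],
            "effectiveness": [r.expected_effectiveness for r in rows],
            "incremental_effectiveness": [r.incremental_effectiveness for r in rows],
            "icer": [r.icer for r in rows],
            "status": [r.status for r in rows],
        }
    )


def net_monetary_benefit(result: CEResult, wtp: float) -> float:
    """λ × expected effectiveness − expected cost (R$)."""
    if wtp < 0:
        raise ValueError(f"willingness-to-pay must be non-negative, got {wtp}")
    return wtp * result.expected_effectiveness - result.expected_cost
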