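"""Deterministic uncertainty analyses.

* **One-way sensitivity (tornado)** — each parameter is pushed to its low and
  high bound with everything else at base, and a chosen outcome (ICER of IPC
  vs no prophylaxis, or a cost difference) is recomputed; entries are ranked
  by swing.
* **Threshold analysis** — the baseline DVT incidence at which IPC stops
  costing more than no prophylaxis, found by root bracketing on the
  expected-cost difference (PE risk scales with DVT through the conditional
  PE probability).
* **Scenario analysis** — IPC used intra+postoperatively, only
  postoperatively, or only intraoperatively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .parameters import ParameterSet, UNCERTAIN_KEYS
from .strategies import StrategySpec
from .tree import evaluate_strategy

__all__ = [
    "TornadoEntry",
    "ThresholdResult",
    "OUTCOME_NAMES",
    "one_way_sensitivity",
    "tornado_frame",
    "threshold_vte_incidence",
    "scenario_analysis",
    "scenario_frame",
]

OUTCOME_NAMES = ("icer_ipc_vs_none", "delta_cost_ipc_vs_lmwh", "delta_cost_ipc_vs_none")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_input: float
    high_input: float
    outcome_at_low: float
    outcome_at_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even baseline VTE incidence between two strategies."""

    parameter: str
    crossing_value: float  # as a fraction
    outcome_relation: str
    grid: pd.DataFrame  # columns: p_dvt_baseline + one expected-cost column per strategy

    @property
    def crossing_percent(self) -> float:
        return 100.0 * self.crossing_value


def _outcome(params: ParameterSet, outcome: str) -> float:
    none = evaluate_strategy(params, StrategySpec("no_prophylaxis"))
    ipc = evaluate_strategy(params, StrategySpec("IPC"))
    if outcome == "icer_ipc_vs_none":
        d_eff = ipc.expected_effectiveness - none.expected_effectiveness
        d_cost = ipc.expected_cost - none.expected_cost
        # signed ratio so the tornado stays numeric when a bound flips
        # dominance; NaN only in the degenerate equal-effectiveness case
        return d_cost / d_eff if d_eff != 0 else math.nan
    if outcome == "delta_cost_ipc_vs_none":
        return ipc.expected_cost - none.expected_cost
    if outcome == "delta_cost_ipc_vs_lmwh":
        lmwh = evaluate_strategy(params, StrategySpec("LMWH"))
        return ipc.expected_cost - lmwh.expected_cost
    raise ValueError(f"unknown outcome: {outcome!r}; expected one of {OUTCOME_NAMES}")


def one_way_sensitivity(params: ParameterSet, outcome: str) -> list[TornadoEntry]:
    """Tornado entries for every uncertain parameter, sorted by descending
    swing (ties broken by parameter name for determinism)."""
    if outcome not in OUTCOME_NAMES:
        raise ValueError(f"unknown outcome: {outcome!r}; expected one of {OUTCOME_NAMES}")
    entries = []
    for key in UNCERTAIN_KEYS:
        q = params.get(key)
        at_low = _outcome(params.with_value(key, q.low), outcome)
        at_high = _outcome(params.with_value(key, q.high), outcome)
        entries.append(TornadoEntry(key, q.low, q.high, at_low, at_high))
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [e.parameter for e in entries],
            "low_input": [e.low_input for e in entries],
            "high_input": [e.high_input for e in entries],
            "outcome_at_low": [e.outcome_at_low for e in entries],
            "outcome_at_high": [e.outcome_at_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )


def _cost_difference(params: ParameterSet, p_dvt: float) -> float:
    trial = params.with_value("p_dvt_baseline", p_dvt)
    ipc = evaluate_strategy(trial, StrategySpec("IPC"))
    none = evaluate_strategy(trial, StrategySpec("no_prophylaxis"))
    return ipc.expected_cost - none.expected_cost


def threshold_vte_incidence(
    params: ParameterSet,
    lo: float = 0.001,
    hi: float = 0.05,
    tol: float = 1e-6,
    grid_points: int = 50,
) -> ThresholdResult:
    """Baseline DVT incidence at which IPC and no prophylaxis cost the same.

    Uses Brent root finding on the expected-cost difference over
    ``[lo, hi]`` down to an absolute cost difference below ``tol`` R$, and
    attaches an evaluation grid of per-strategy expected costs for plotting.
    """
    f_lo, f_hi = _cost_difference(params, lo), _cost_difference(params, hi)
    if f_lo == 0.0:
        crossing = lo
    elif f_hi == 0.0:
        crossing = hi
    elif f_lo * f_hi > 0:
        raise ValueError(
            f"expected-cost difference does not change sign on [{lo}, {hi}] "
            f"(Δcost {f_lo:+.2f} at {lo}, {f_hi:+.2f} at {hi})"
        )
    else:
        crossing = brentq(lambda p: _cost_difference(params, p), lo, hi, xtol=1e-14)
    assert abs(_cost_difference(params, crossing)) < tol

    grid_rows = []
    for p in np.linspace(lo, hi, grid_points):
        trial = params.with_value("p_dvt_baseline", float(p))
        row = {"p_dvt_baseline": float(p)}
        for name in ("no_prophylaxis", "IPC", "LMWH"):
            row[f"cost_{name}"] = evaluate_strategy(trial, StrategySpec(name)).expected_cost
        grid_rows.append(row)

    relation = (
        "no_prophylaxis cheaper below the crossing; IPC cheaper above"
        if f_lo > 0
        else "IPC cheaper below the crossing; no_prophylaxis cheaper above"
    )
    return ThresholdResult(
        parameter="p_dvt_baseline",
        crossing_value=float(crossing),
        outcome_relation=relation,
        grid=pd.DataFrame(grid_rows),
    )


def scenario_analysis(params: ParameterSet) -> list[tuple[str, float, float]]:
    """Expected cost and effectiveness of IPC under the three phase-of-use
    scenarios (intra+post, post-only, intra-only)."""
    rows = []
    for phase in ("intra_and_post", "post_only", "intra_only"):
        result = evaluate_strategy(params, StrategySpec("IPC", phase=phase))
        rows.append((f"IPC_{phase}", result.expected_cost, result.expected_effectiveness))
    return rows


def scenario_frame(rows: list[tuple[str, float, float]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["scenario", "expected_cost", "expected_effectiveness"])
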