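"""Decision-tree construction and expected-value rollback.

The tree for every strategy has the same shape.  After the decision node the
patient passes an intraoperative chance node (spinal-anesthesia hypotension,
which adds its management cost but is *not* counted as a prophylaxis-related
adverse event) and then a mutually exclusive postoperative chance node with
four branches: DVT (splitting into DVT-with-PE and DVT-without-PE), minor
bleed, major bleed, and no adverse event (the complement).  That yields
2 × 5 = 10 terminal pathways.

Payoffs per pathway:

* **cost** — prophylaxis cost, plus hypotension management if it occurred,
  plus the management cost of the postoperative event (a PE is incremental to
  the DVT it evolved from, so that pathway accrues both costs);
* **effectiveness** — 1 exactly when the postoperative branch is "no adverse
  event", 0 otherwise.  Expected effectiveness is therefore the probability
  of avoiding every VTE-related adverse event.

Deaths (PE case fatality) are tracked as a secondary expectation only; they
carry no extra cost and do not change effectiveness.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import ParameterSet
from .strategies import EventProbabilities, StrategySpec, resolve_strategy

__all__ = [
    "PathwayOutcome",
    "CEResult",
    "TreeStructureError",
    "enumerate_pathways",
    "build_and_rollback",
    "evaluate_strategy",
    "pathway_table",
    "INTRAOP_LABELS",
    "POSTOP_LABELS",
]

INTRAOP_LABELS = ("hypotension", "no_hypotension")
POSTOP_LABELS = ("DVT_no_PE", "DVT_with_PE", "minor_bleed", "major_bleed", "no_AE")

_PROB_TOL = 1e-12


class TreeStructureError(ValueError):
    """The event probabilities are inconsistent with the tree structure."""


@dataclass(frozen=True)
class PathwayOutcome:
    """One terminal pathway: its event labels, probability and payoffs."""

    labels: tuple[str, str]  # (intraoperative label, postoperative label)
    probability: float
    cost: float
    effectiveness: int

    @property
    def intraop_label(self) -> str:
        return self.labels[0]

    @property
    def postop_label(self) -> str:
        return self.labels[1]


@dataclass(frozen=True)
class CEResult:
    """Rolled-back expectations for one strategy."""

    strategy: StrategySpec
    expected_cost: float
    expected_effectiveness: float
    expected_deaths: float
    pathways: tuple[PathwayOutcome, ...]


def enumerate_pathways(
    probs: EventProbabilities, params: ParameterSet
) -> list[PathwayOutcome]:
    """Enumerate the 10 terminal pathways in deterministic order.

    Order: hypotension before no-hypotension; postoperative branches as in
    :data:`POSTOP_LABELS`.  Probabilities multiply along branches.
    """
    p_post_sum = probs.p_dvt + probs.p_minor + probs.p_major
    if p_post_sum > 1.0 + _PROB_TOL:
        raise TreeStructureError(
            "postoperative probabilities sum to "
            f"{p_post_sum:.6g} > 1 (DVT {probs.p_dvt}, minor {probs.p_minor}, "
            f"major {probs.p_major}); the no-AE complement would be negative"
        )
    p_no_ae = max(1.0 - p_post_sum, 0.0)

    postop = {
        "DVT_no_PE": (probs.p_dvt * (1.0 - probs.p_pe_given_dvt), params.c_dvt.value, 0),
        "DVT_with_PE": (
            probs.p_dvt * probs.p_pe_given_dvt,
            params.c_dvt.value + params.c_pe.value,  # PE is incremental to DVT care
            0,
        ),
        "minor_bleed": (probs.p_minor, params.c_minor.value, 0),
        "major_bleed": (probs.p_major, params.c_major.value, 0),
        "no_AE": (p_no_ae, 0.0, 1),
    }
    intraop = {
        "hypotension": (probs.p_hypo, params.c_hypo.value),
        "no_hypotension": (1.0 - probs.p_hypo, 0.0),
    }

    pathways = []
    for intra_label in INTRAOP_LABELS:
        p_intra, c_intra = intraop[intra_label]
        for post_label in POSTOP_LABELS:
            p_post, c_post, eff = postop[post_label]
            pathways.append(
                PathwayOutcome(
                    labels=(intra_label, post_label),
                    probability=p_intra * p_post,
                    cost=probs.c_prophylaxis + c_intra + c_post,
                    effectiveness=eff,
                )
            )
    return pathways


def build_and_rollback(
    params: ParameterSet,
    probs: EventProbabilities,
    strategy: StrategySpec | None = None,
) -> CEResult:
    """Roll the tree back to expected cost, effectiveness and deaths.

    Expectations are probability-weighted sums over the enumerated terminal
    pathways.  Expected deaths is the secondary output
    ``p_dvt × p_pe|dvt × p_mortality`` (death is modelled only as PE case
    fatality and does not feed cost or effectiveness).
    """
    pathways = tuple(enumerate_pathways(probs, params))
    expected_cost = sum(p.probability * p.cost for p in pathways)
    expected_eff = sum(p.probability * p.effectiveness for p in pathways)
    expected_deaths = probs.p_dvt * probs.p_pe_given_dvt * params.p_mortality.value
    if strategy is None:
        strategy = StrategySpec("no_prophylaxis")
    return CEResult(
        strategy=strategy,
        expected_cost=expected_cost,
        expected_effectiveness=expected_eff,
        expected_deaths=expected_deaths,
        pathways=pathways,
    )


def evaluate_strategy(params: ParameterSet, strategy: StrategySpec) -> CEResult:
    """Resolve a strategy's probabilities and roll back its tree."""
    probs = resolve_strategy(params, strategy)
    return build_and_rollback(params, probs, strategy)


def pathway_table(results: list[CEResult]) -> pd.DataFrame:
    """Tabulate every pathway of every strategy for CSV export."""
    rows = []
    for result in results:
        for p in result.pathways:
            rows.append(
                {
                    "strategy": result.strategy.name,
                    "phase": result.strategy.phase,
                    "intraop_label": p.intraop_label,
                    "postop_label": p.postop_label,
                    "probability": p.probability,
                    "cost": p.cost,
                    "effectiveness": p.effectiveness,
                }
            )
    return pd.DataFrame(rows)
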