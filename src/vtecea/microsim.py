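"""Patient-level microsimulation oracle and synthetic fixture generation.

Simulates individual patients through the same decision tree the analytic
rollback evaluates: a Bernoulli draw for intraoperative hypotension, a single
uniform draw against the ordered postoperative categories
(DVT, minor bleed, major bleed, no adverse event), a Bernoulli PE draw within
DVT, and a Bernoulli death draw within PE.  Cohort means of cost and
adverse-event-free status converge to the rollback expectations by the law of
large numbers, giving an implementation-independent check of the tree.

The single-uniform categorical draw with fixed category ordering keeps the
random stream consumption identical across platforms for a given seed.
Deaths are recorded but never stop cost accrual, matching the tree's payoff
rules.

``generate_fixture`` produces jittered but valid parameter sets so that every
downstream module can be property-tested away from the published inputs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .parameters import (
    PARAMETER_KINDS,
    ParameterSet,
    UncertainQuantity,
)
from .strategies import StrategySpec, resolve_strategy
from .tree import enumerate_pathways

__all__ = ["simulate_cohort", "generate_fixture", "COHORT_COLUMNS"]

COHORT_COLUMNS = (
    "patient_id",
    "strategy",
    "phase",
    "had_hypotension",
    "postop_event",
    "died",
    "cost",
    "ae_free",
)


def simulate_cohort(
    params: ParameterSet,
    strategy: StrategySpec,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Simulate ``n`` independent patients under one strategy.

    Returns one row per patient with the columns in :data:`COHORT_COLUMNS`.
    Per-record cost equals the cost of the terminal pathway the patient
    realized, exactly.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    probs = resolve_strategy(params, strategy)
    rng = np.random.default_rng(seed)

    hypo = rng.random(n) < probs.p_hypo
    # single uniform against ordered categories: DVT, minor, major, no AE
    u = rng.random(n)
    edge_dvt = probs.p_dvt
    edge_minor = edge_dvt + probs.p_minor
    edge_major = edge_minor + probs.p_major
    dvt = u < edge_dvt
    minor = (u >= edge_dvt) & (u < edge_minor)
    major = (u >= edge_minor) & (u < edge_major)
    # PE and death draws are consumed for every patient so that the stream
    # position does not depend on earlier outcomes
    pe = (rng.random(n) < probs.p_pe_given_dvt) & dvt
    died = (rng.random(n) < params.p_mortality.value) & pe

    postop = np.full(n, "no_AE", dtype=object)
    postop[dvt & ~pe] = "DVT_no_PE"
    postop[pe] = "DVT_with_PE"
    postop[minor] = "minor_bleed"
    postop[major] = "major_bleed"

    event_cost = {
        "DVT_no_PE": params.c_dvt.value,
        "DVT_with_PE": params.c_dvt.value + params.c_pe.value,
        "minor_bleed": params.c_minor.value,
        "major_bleed": params.c_major.value,
        "no_AE": 0.0,
    }
    cost = (
        probs.c_prophylaxis
        + np.where(hypo, params.c_hypo.value, 0.0)
        + np.vectorize(event_cost.__getitem__, otypes=[float])(postop)
    )

    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "strategy": strategy.name,
            "phase": strategy.phase,
            "had_hypotension": hypo,
            "postop_event": postop,
            "died": died,
            "cost": cost,
            "ae_free": (postop == "no_AE").astype(int),
        }
    )


def cohort_vs_rollback(cohort: pd.DataFrame, params: ParameterSet, strategy: StrategySpec):
    """Convenience: the strategy's enumerated pathways, for cross-checks."""
    return enumerate_pathways(resolve_strategy(params, strategy), params)


def generate_fixture(
    params: ParameterSet, perturbation: float, seed: int
) -> ParameterSet:
    """A valid parameter set with every point value jittered by up to
    ±``perturbation`` (relative); ranges are widened where needed so the
    jittered value stays inside them.  Reproducible by seed."""
    if not 0.0 <= perturbation < 1.0:
        raise ValueError(f"perturbation must be in [0, 1), got {perturbation}")
    rng = np.random.default_rng(seed)
    updates: dict[str, UncertainQuantity] = {}
    for key, q in params.uncertain_items():
        factor = 1.0 + perturbation * float(rng.uniform(-1.0, 1.0))
        value = q.value * factor
        if PARAMETER_KINDS[key] == "probability":
            value = min(max(value, 0.0), 1.0)
        elif PARAMETER_KINDS[key] == "rr":
            value = max(value, 1e-12)
        else:
            value = max(value, 0.0)
        updates[key] = dataclasses.replace(
            q, value=value, low=min(q.low, value), high=max(q.high, value)
        )
    out = params
    for key, q in updates.items():
        out = out.with_quantity(key, q)
    return out.validate()
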