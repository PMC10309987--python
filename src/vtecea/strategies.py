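"""Per-strategy event probabilities.

Maps the no-prophylaxis baseline probabilities onto each prophylaxis strategy
by applying the published relative risks:

* **LMWH** scales DVT down (RR 0.33) and both bleeding probabilities up
  (RR 2.12 minor, 1.48 major); hypotension is unaffected.
* **IPC** has no direct trial against no treatment, so its DVT effect is the
  composition baseline × RR(LMWH vs none) × RR(IPC vs LMWH).  Mechanical
  prophylaxis carries no bleeding risk, so bleeding stays at baseline.  Worn
  intraoperatively, the sleeves also reduce spinal-anesthesia hypotension
  (RR 0.36).
* The IPC *phase* variants model using the device only during surgery
  (``intra_only``: hypotension benefit, no postoperative VTE protection) or
  only after it (``post_only``: VTE protection, baseline hypotension).

Every probability × RR product is clamped to 1, which matters when the
probabilistic analysis samples RRs far above their point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ParameterSet

__all__ = [
    "StrategySpec",
    "EventProbabilities",
    "resolve_strategy",
    "all_strategies",
    "NO_PROPHYLAXIS",
    "IPC",
    "LMWH",
    "STRATEGY_NAMES",
    "IPC_PHASES",
]

STRATEGY_NAMES = ("no_prophylaxis", "IPC", "LMWH")
IPC_PHASES = ("intra_and_post", "intra_only", "post_only")


@dataclass(frozen=True)
class StrategySpec:
    """A prophylaxis strategy plus, for IPC, the phase of device use."""

    name: str
    phase: str = "intra_and_post"

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"unknown strategy name: {self.name!r}")
        if self.phase not in IPC_PHASES:
            raise ValueError(f"unknown phase: {self.phase!r}")
        if self.phase != "intra_and_post" and self.name != "IPC":
            raise ValueError(f"phase {self.phase!r} only applies to IPC")

    @property
    def label(self) -> str:
        if self.name == "IPC" and self.phase != "intra_and_post":
            return f"IPC_{self.phase}"
        return self.name


NO_PROPHYLAXIS = StrategySpec("no_prophylaxis")
IPC = StrategySpec("IPC")
LMWH = StrategySpec("LMWH")


@dataclass(frozen=True)
class EventProbabilities:
    """Resolved per-strategy event probabilities and prophylaxis cost.

    ``p_dvt``, ``p_minor`` and ``p_major`` feed one mutually exclusive
    postoperative chance node, so their sum may not exceed 1 (checked by the
    tree builder).  ``p_pe_given_dvt`` is conditional on DVT and identical
    across strategies.
    """

    p_hypo: float
    p_dvt: float
    p_pe_given_dvt: float
    p_minor: float
    p_major: float
    c_prophylaxis: float


def _clamp(p: float) -> float:
    return min(max(p, 0.0), 1.0)


def resolve_strategy(params: ParameterSet, strategy: StrategySpec) -> EventProbabilities:
    """Apply the strategy's relative risks to the baseline probabilities."""
    p_dvt0 = params.p_dvt_baseline.value
    p_minor0 = params.p_minor_baseline.value
    p_major0 = params.p_major_baseline.value
    p_hypo0 = params.p_hypo_baseline.value
    p_pe = params.p_pe_given_dvt.value

    if strategy.name == "no_prophylaxis":
        return EventProbabilities(p_hypo0, p_dvt0, p_pe, p_minor0, p_major0, 0.0)

    if strategy.name == "LMWH":
        return EventProbabilities(
            p_hypo=p_hypo0,
            p_dvt=_clamp(p_dvt0 * params.rr_lmwh_dvt.value),
            p_pe_given_dvt=p_pe,
            p_minor=_clamp(p_minor0 * params.rr_lmwh_minor.value),
            p_major=_clamp(p_major0 * params.rr_lmwh_major.value),
            c_prophylaxis=params.c_lmwh.value,
        )

    # IPC: DVT effect chained through LMWH (no direct IPC-vs-none RR exists);
    # bleeding at baseline (mechanical prophylaxis does not cause bleeding)
    p_dvt_ipc = _clamp(p_dvt0 * params.rr_lmwh_dvt.value * params.rr_ipc_vs_lmwh_vte.value)
    p_hypo_ipc = _clamp(p_hypo0 * params.rr_compression_hypo.value)
    if strategy.phase == "post_only":
        p_hypo_ipc = p_hypo0  # device not worn during surgery
    elif strategy.phase == "intra_only":
        p_dvt_ipc = p_dvt0  # device removed before the postoperative period
    return EventProbabilities(
        p_hypo=p_hypo_ipc,
        p_dvt=p_dvt_ipc,
        p_pe_given_dvt=p_pe,
        p_minor=p_minor0,
        p_major=p_major0,
        c_prophylaxis=params.c_ipc.value,
    )


def all_strategies(
    params: ParameterSet,
    names: tuple[str, ...] = STRATEGY_NAMES,
) -> list[tuple[StrategySpec, EventProbabilities]]:
    """Resolve the base-case strategies in fixed order (no prophylaxis, IPC,
    LMWH)."""
    specs = [StrategySpec(name) for name in names]
    return [(spec, resolve_strategy(params, spec)) for spec in specs]
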