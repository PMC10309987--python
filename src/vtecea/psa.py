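"""Probabilistic sensitivity analysis.

Each uncertain parameter gets a distribution fitted from its point estimate
and 95% interval — beta for probabilities and gamma for costs (method of
moments, with the interval width read as 3.92 standard deviations), lognormal
for relative risks (point estimate as the median, log-scale sd from the
interval of the log bounds).  Every Monte Carlo draw samples one value per
parameter, resolves all three strategies with the *same* sampled vector
(common random numbers), rolls back the tree, and records per-strategy
expected cost and effectiveness.

Summaries: cost-effectiveness plane quadrant proportions and a 95%
confidence ellipse for a pairwise comparison, and the cost-effectiveness
acceptability curve (probability each strategy attains the maximum net
monetary benefit, ties split equally) over a willingness-to-pay grid.

Sampled probability × RR products above 1 are clamped, and draws whose
mutually exclusive postoperative probabilities sum above 1 are rescaled to
sum exactly 1; both events are counted on the run object, never silent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .parameters import ParameterSet, UncertainQuantity, UNCERTAIN_KEYS
from .strategies import STRATEGY_NAMES, StrategySpec, EventProbabilities
from .tree import build_and_rollback

__all__ = [
    "DistributionSpec",
    "PSASample",
    "PSARun",
    "CEACCurve",
    "CEPlaneSummary",
    "fit_distribution",
    "sample_distribution",
    "run_psa",
    "ce_plane_summary",
    "acceptability_curve",
    "default_wtp_grid",
    "psa_frame",
    "ceac_frame",
    "PSA_SAMPLED_KEYS",
]

# every uncertain quantity except mortality, which feeds only the secondary
# expected-deaths output and is held at its point value in the PSA
PSA_SAMPLED_KEYS: tuple[str, ...] = tuple(k for k in UNCERTAIN_KEYS if k != "p_mortality")

_Z95_WIDTH = 3.92  # a 95% normal interval spans 3.92 standard deviations


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``params`` holds the two family-specific shape parameters:
    (alpha, beta) for beta, (shape, scale) for gamma, (log-median, log-sd)
    for lognormal, and (value, 0) for fixed.
    """

    family: str
    params: tuple[float, float]
    derived_from: tuple[float, float, float]  # (value, low, high)

    @property
    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params
            return a / (a + b)
        if self.family == "gamma":
            k, theta = self.params
            return k * theta
        if self.family == "lognormal":
            mu, sigma = self.params
            return math.exp(mu + sigma**2 / 2.0)
        return self.params[0]

    @property
    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.params[0])
        raise NotImplementedError(f"median not defined here for family {self.family!r}")


def fit_distribution(q: UncertainQuantity) -> DistributionSpec:
    """Fit the sampling distribution for one uncertain quantity.

    Beta and gamma are moment-matched to (value, sd) with
    sd = (high − low)/3.92; their fitted means equal the point value exactly.
    Lognormal takes the point value as its median with
    log-sd = (ln high − ln low)/3.92.
    """
    provenance = (q.value, q.low, q.high)
    if q.family == "fixed" or q.high == q.low:
        return DistributionSpec("fixed", (q.value, 0.0), provenance)
    sd = (q.high - q.low) / _Z95_WIDTH
    var = sd * sd
    if q.family == "beta":
        m = q.value
        if var >= m * (1.0 - m):
            raise ValueError(
                f"infeasible beta moments: sd^2 = {var:.3g} >= value(1-value) = "
                f"{m * (1 - m):.3g}"
            )
        nu = m * (1.0 - m) / var - 1.0
        return DistributionSpec("beta", (m * nu, (1.0 - m) * nu), provenance)
    if q.family == "gamma":
        return DistributionSpec("gamma", (q.value**2 / var, var / q.value), provenance)
    if q.family == "lognormal":
        if q.low <= 0 or q.high <= 0 or q.value <= 0:
            raise ValueError("lognormal requires strictly positive value and bounds")
        sigma = (math.log(q.high) - math.log(q.low)) / _Z95_WIDTH
        return DistributionSpec("lognormal", (math.log(q.value), sigma), provenance)
    raise ValueError(f"unknown distribution family: {q.family!r}")


def sample_distribution(
    spec: DistributionSpec, rng: np.random.Generator, size: int
) -> np.ndarray:
    if spec.family == "fixed":
        return np.full(size, spec.params[0])
    if spec.family == "beta":
        return rng.beta(spec.params[0], spec.params[1], size)
    if spec.family == "gamma":
        return rng.gamma(spec.params[0], spec.params[1], size)
    if spec.family == "lognormal":
        return rng.lognormal(spec.params[0], spec.params[1], size)
    raise ValueError(f"unknown distribution family: {spec.family!r}")


@dataclass(frozen=True)
class PSASample:
    """Per-strategy (expected cost, expected effectiveness) for one draw."""

    draw_index: int
    results: dict[str, tuple[float, float]]  # strategy name -> (cost, effectiveness)

    def cost(self, strategy: str) -> float:
        return self.results[strategy][0]

    def effectiveness(self, strategy: str) -> float:
        return self.results[strategy][1]


@dataclass
class PSARun:
    """All Monte Carlo draws plus clamping diagnostics."""

    samples: list[PSASample]
    n_product_clamped: int  # probability × RR products clamped at 1
    n_renormalized: int  # draws whose post-op probabilities were rescaled to sum 1
    seed: int

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def costs(self, strategy: str) -> np.ndarray:
        return np.array([s.cost(strategy) for s in self.samples])

    def effects(self, strategy: str) -> np.ndarray:
        return np.array([s.effectiveness(strategy) for s in self.samples])


def _resolve_sampled(
    draw: dict[str, float],
) -> tuple[dict[str, EventProbabilities], int]:
    """Resolve all strategies from one sampled parameter vector.

    Mirrors :func:`vtecea.strategies.resolve_strategy` on raw floats so that
    clamping events can be counted.
    """
    clamps = 0

    def clamp(x: float) -> float:
        nonlocal clamps
        if x > 1.0:
            clamps += 1
            return 1.0
        return max(x, 0.0)

    p_pe = draw["p_pe_given_dvt"]
    out = {
        "no_prophylaxis": EventProbabilities(
            draw["p_hypo_baseline"], draw["p_dvt_baseline"], p_pe,
            draw["p_minor_baseline"], draw["p_major_baseline"], 0.0,
        ),
        "IPC": EventProbabilities(
            clamp(draw["p_hypo_baseline"] * draw["rr_compression_hypo"]),
            clamp(draw["p_dvt_baseline"] * draw["rr_lmwh_dvt"] * draw["rr_ipc_vs_lmwh_vte"]),
            p_pe,
            draw["p_minor_baseline"], draw["p_major_baseline"], draw["c_ipc"],
        ),
        "LMWH": EventProbabilities(
            draw["p_hypo_baseline"],
            clamp(draw["p_dvt_baseline"] * draw["rr_lmwh_dvt"]),
            p_pe,
            clamp(draw["p_minor_baseline"] * draw["rr_lmwh_minor"]),
            clamp(draw["p_major_baseline"] * draw["rr_lmwh_major"]),
            draw["c_lmwh"],
        ),
    }
    return out, clamps


def _rescale_postop(probs: EventProbabilities) -> tuple[EventProbabilities, bool]:
    total = probs.p_dvt + probs.p_minor + probs.p_major
    if total <= 1.0:
        return probs, False
    return (
        EventProbabilities(
            probs.p_hypo,
            probs.p_dvt / total,
            probs.p_pe_given_dvt,
            probs.p_minor / total,
            probs.p_major / total,
            probs.c_prophylaxis,
        ),
        True,
    )


def run_psa(params: ParameterSet, n: int | None = None, seed: int | None = None) -> PSARun:
    """Draw ``n`` Monte Carlo samples and evaluate all strategies per draw.

    Reproducible given ``(params, n, seed)``: parameters are sampled in the
    canonical key order, each as one array of length ``n`` from a single
    ``numpy`` Generator.  ``n`` and ``seed`` default to the parameter set's
    ``n_psa`` and ``rng_seed``.
    """
    if n is None:
        n = params.n_psa
    if seed is None:
        seed = params.rng_seed
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    specs = {key: fit_distribution(params.get(key)) for key in PSA_SAMPLED_KEYS}
    draws = {key: sample_distribution(specs[key], rng, n) for key in PSA_SAMPLED_KEYS}

    samples: list[PSASample] = []
    n_clamped = 0
    n_renorm = 0
    unit_cost_keys = ("c_dvt", "c_pe", "c_minor", "c_major", "c_hypo")
    for i in range(n):
        vector = {key: float(draws[key][i]) for key in PSA_SAMPLED_KEYS}
        resolved, clamps = _resolve_sampled(vector)
        n_clamped += clamps
        # pathway costs must use the sampled unit costs, not the base ones
        trial = params
        for key in unit_cost_keys:
            trial = trial.with_value(key, vector[key])
        results: dict[str, tuple[float, float]] = {}
        for name in STRATEGY_NAMES:
            probs, rescaled = _rescale_postop(resolved[name])
            n_renorm += rescaled
            ce = build_and_rollback(trial, probs, StrategySpec(name))
            results[name] = (ce.expected_cost, ce.expected_effectiveness)
        samples.append(PSASample(i, results))
    return PSARun(samples, n_clamped, n_renorm, seed)


@dataclass(frozen=True)
class CEPlaneSummary:
    """Quadrant proportions and 95% confidence ellipse for comp − ref."""

    reference: str
    comparator: str
    wtp: float
    delta_cost: np.ndarray
    delta_effect: np.ndarray
    p_superior: float  # comparator cheaper AND more effective (dominant quadrant)
    p_acceptable: float  # below the WTP line (positive incremental NMB)
    ellipse_center: tuple[float, float]  # (mean Δeffect, mean Δcost)
    ellipse_axes: tuple[float, float]  # semi-axis lengths, major first
    ellipse_angle_deg: float  # major axis vs the Δeffect axis
    degenerate: bool


def ce_plane_summary(
    run: PSARun, ref: str, comp: str, wtp: float
) -> CEPlaneSummary:
    """Incremental cost-effectiveness plane of ``comp`` against ``ref``."""
    if len(run.samples) < 2:
        raise ValueError("cost-effectiveness plane summary needs at least 2 draws")
    d_cost = run.costs(comp) - run.costs(ref)
    d_eff = run.effects(comp) - run.effects(ref)
    p_superior = float(np.mean((d_eff > 0) & (d_cost < 0)))
    p_acceptable = float(np.mean(wtp * d_eff - d_cost > 0))

    points = np.column_stack([d_eff, d_cost])
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    degenerate = bool(np.linalg.matrix_rank(cov, tol=1e-300) < 2)
    if degenerate:
        axes, angle = (0.0, 0.0), 0.0
    else:
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        q = chi2.ppf(0.95, df=2)
        axes = (float(np.sqrt(q * eigvals[0])), float(np.sqrt(q * eigvals[1])))
        angle = float(np.degrees(np.arctan2(eigvecs[1, 0], eigvecs[0, 0])))
    return CEPlaneSummary(
        reference=ref,
        comparator=comp,
        wtp=wtp,
        delta_cost=d_cost,
        delta_effect=d_eff,
        p_superior=p_superior,
        p_acceptable=p_acceptable,
        ellipse_center=(float(center[0]), float(center[1])),
        ellipse_axes=axes,
        ellipse_angle_deg=angle,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class CEACCurve:
    """Probability each strategy is optimal, per willingness-to-pay value."""

    wtp_grid: np.ndarray
    probabilities: dict[str, np.ndarray]  # strategy name -> probability per grid point


def default_wtp_grid() -> np.ndarray:
    """R$0 to R$30,000 in R$500 steps (brackets the R$15,000 threshold)."""
    return np.arange(0.0, 30_000.0 + 1, 500.0)


def acceptability_curve(run: PSARun, wtp_grid: np.ndarray | None = None) -> CEACCurve:
    """CEAC by the max-net-monetary-benefit rule, ties split equally."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if len(run.samples) == 0 or wtp_grid.size == 0:
        raise ValueError("acceptability curve needs non-empty draws and WTP grid")
    costs = np.column_stack([run.costs(name) for name in STRATEGY_NAMES])
    effects = np.column_stack([run.effects(name) for name in STRATEGY_NAMES])
    n = costs.shape[0]
    probs = {name: np.zeros(wtp_grid.size) for name in STRATEGY_NAMES}
    for j, wtp in enumerate(wtp_grid):
        nmb = wtp * effects - costs
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        weights = winners / winners.sum(axis=1, keepdims=True)
        share = weights.sum(axis=0) / n
        for k, name in enumerate(STRATEGY_NAMES):
            probs[name][j] = share[k]
    return CEACCurve(wtp_grid=wtp_grid, probabilities=probs)


def psa_frame(run: PSARun) -> pd.DataFrame:
    """One row per draw with per-strategy cost and effectiveness columns."""
    data: dict[str, list[float]] = {"draw_index": [s.draw_index for s in run.samples]}
    for name in STRATEGY_NAMES:
        data[f"cost_{name}"] = [s.cost(name) for s in run.samples]
        data[f"effectiveness_{name}"] = [s.effectiveness(name) for s in run.samples]
    return pd.DataFrame(data)


def ceac_frame(curve: CEACCurve) -> pd.DataFrame:
    data = {"wtp": curve.wtp_grid}
    for name, values in curve.probabilities.items():
        data[f"p_{name}"] = values
    return pd.DataFrame(data)
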