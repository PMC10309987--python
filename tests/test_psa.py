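"""Distribution fitting, Monte Carlo propagation, CE plane and CEAC."""

import dataclasses
import math

import numpy as np
import pytest

from vtecea import (
    UncertainQuantity,
    acceptability_curve,
    ce_plane_summary,
    default_parameters,
    default_wtp_grid,
    fit_distribution,
    run_psa,
)
from vtecea.parameters import PARAMETER_KINDS
from vtecea.psa import PSA_SAMPLED_KEYS, sample_distribution
from vtecea.strategies import STRATEGY_NAMES


def test_beta_fit_matches_method_of_moments_algebra(defaults):
    """Independent moment-matching algebra for the DVT probability."""
    spec = fit_distribution(defaults.p_dvt_baseline)
    sd = (0.03 - 0.001) / 3.92
    assert sd == pytest.approx(0.0073980, abs=1e-7)
    nu = 0.007 * 0.993 / sd**2 - 1.0
    assert spec.params == pytest.approx((0.007 * nu, 0.993 * nu))
    assert spec.params == pytest.approx((0.88, 125.1), rel=5e-3)
    assert spec.mean == pytest.approx(0.007, abs=1e-9)


@pytest.mark.parametrize("key", [k for k in PSA_SAMPLED_KEYS])
def test_fitted_mean_or_median_recovers_point_value(defaults, key):
    q = defaults.get(key)
    spec = fit_distribution(q)
    if spec.family == "lognormal":
        assert spec.median == pytest.approx(q.value, abs=1e-9)
    else:
        assert spec.mean == pytest.approx(q.value, abs=1e-9)


def test_gamma_fit_mean_identity(defaults):
    spec = fit_distribution(defaults.c_dvt)
    assert spec.family == "gamma"
    assert spec.mean == pytest.approx(9524.0, abs=1e-9)


def test_infeasible_beta_moments_rejected():
    q = UncertainQuantity(0.5, 0.0, 2.0, family="beta")  # sd = 0.51 > sqrt(0.25)
    with pytest.raises(ValueError, match="infeasible beta"):
        fit_distribution(q)


def test_nonpositive_lognormal_bounds_rejected():
    q = UncertainQuantity(1.0, 0.0, 2.0, family="lognormal")
    with pytest.raises(ValueError, match="positive"):
        fit_distribution(q)


def test_fixed_family_always_returns_point_value():
    spec = fit_distribution(UncertainQuantity(7.0, 6.0, 8.0, family="fixed"))
    draws = sample_distribution(spec, np.random.default_rng(0), 100)
    assert (draws == 7.0).all()


@pytest.mark.parametrize("key", ["p_dvt_baseline", "c_dvt", "rr_lmwh_minor"])
def test_sampler_calibration(defaults, key):
    """Empirical mean (beta/gamma) within 3 SE of the fitted mean, or
    empirical median (lognormal) close to the point value, at 1e5 draws."""
    q = defaults.get(key)
    spec = fit_distribution(q)
    draws = sample_distribution(spec, np.random.default_rng(1234), 100_000)
    if spec.family == "lognormal":
        assert np.median(draws) == pytest.approx(q.value, rel=0.02)
    else:
        se = draws.std(ddof=1) / math.sqrt(draws.size)
        assert abs(draws.mean() - spec.mean) < 3 * se


def test_psa_reproducible_and_single_draw(defaults):
    one = run_psa(defaults, n=1, seed=7)
    again = run_psa(defaults, n=1, seed=7)
    assert len(one) == 1
    assert one.samples[0].results == again.samples[0].results


def test_psa_bitwise_deterministic(defaults):
    a = run_psa(defaults, n=50, seed=11)
    b = run_psa(defaults, n=50, seed=11)
    for name in STRATEGY_NAMES:
        assert (a.costs(name) == b.costs(name)).all()
        assert (a.effects(name) == b.effects(name)).all()


def test_all_fixed_families_collapse_to_base_case(defaults):
    from vtecea import evaluate_strategy, StrategySpec

    pinned = defaults
    for key in PSA_SAMPLED_KEYS:
        q = pinned.get(key)
        pinned = pinned.with_quantity(key, dataclasses.replace(q, family="fixed"))
    run = run_psa(pinned, n=5, seed=3)
    for name in STRATEGY_NAMES:
        expected = evaluate_strategy(defaults, StrategySpec(name))
        assert np.allclose(run.costs(name), expected.expected_cost)
        assert np.allclose(run.effects(name), expected.expected_effectiveness)


def test_psa_mean_near_base_case_for_symmetric_parameters(defaults):
    """With relative risks pinned, parameter distributions are mean-matched,
    so PSA means converge on the deterministic base case."""
    pinned = defaults
    for key in PSA_SAMPLED_KEYS:
        if key.startswith("rr_"):
            q = pinned.get(key)
            pinned = pinned.with_quantity(key, dataclasses.replace(q, family="fixed"))
    run = run_psa(pinned, n=2_000, seed=5)
    from vtecea import evaluate_strategy, StrategySpec

    for name in STRATEGY_NAMES:
        base = evaluate_strategy(defaults, StrategySpec(name))
        costs = run.costs(name)
        se = costs.std(ddof=1) / math.sqrt(costs.size)
        assert abs(costs.mean() - base.expected_cost) < 4 * se


def test_clamping_is_counted_not_silent(defaults):
    # force frequent clamping with a huge bleeding relative risk
    q = defaults.rr_lmwh_minor
    hot = defaults.with_quantity(
        "rr_lmwh_minor", dataclasses.replace(q, value=30.0, low=10.0, high=90.0)
    )
    run = run_psa(hot, n=200, seed=2)
    assert run.n_product_clamped > 0


def test_ce_plane_quadrants_and_ellipse(defaults):
    run = run_psa(defaults, n=500, seed=9)
    summary = ce_plane_summary(run, ref="LMWH", comp="IPC", wtp=15_000.0)
    assert 0.0 <= summary.p_superior <= 1.0
    assert summary.p_acceptable >= summary.p_superior  # dominant draws are acceptable
    # ellipse axes agree with an independent eigen-decomposition
    points = np.column_stack([summary.delta_effect, summary.delta_cost])
    eigvals = np.sort(np.linalg.eigvalsh(np.cov(points, rowvar=False)))[::-1]
    from scipy.stats import chi2

    expected_axes = np.sqrt(chi2.ppf(0.95, 2) * eigvals)
    assert summary.ellipse_axes == pytest.approx(tuple(expected_axes))
    assert not summary.degenerate


def test_ce_plane_degenerate_covariance_flagged(defaults):
    pinned = defaults
    for key in PSA_SAMPLED_KEYS:
        q = pinned.get(key)
        pinned = pinned.with_quantity(key, dataclasses.replace(q, family="fixed"))
    run = run_psa(pinned, n=10, seed=1)
    summary = ce_plane_summary(run, ref="LMWH", comp="IPC", wtp=15_000.0)
    assert summary.degenerate


def test_ceac_probabilities_partition_draws(defaults):
    run = run_psa(defaults, n=300, seed=21)
    curve = acceptability_curve(run)
    total = sum(curve.probabilities[name] for name in STRATEGY_NAMES)
    assert np.allclose(total, 1.0, atol=1e-12)


def test_ceac_zero_wtp_limit_is_cost_minimization(defaults):
    run = run_psa(defaults, n=300, seed=22)
    curve = acceptability_curve(run, np.array([0.0]))
    costs = np.column_stack([run.costs(name) for name in STRATEGY_NAMES])
    cheapest = costs.argmin(axis=1)
    for k, name in enumerate(STRATEGY_NAMES):
        # ties are measure-zero for continuous cost draws
        assert curve.probabilities[name][0] == pytest.approx(
            np.mean(cheapest == k), abs=1e-12
        )


def test_ceac_infinite_wtp_limit_is_effect_maximization(defaults):
    run = run_psa(defaults, n=300, seed=23)
    curve = acceptability_curve(run, np.array([1e12]))
    effects = np.column_stack([run.effects(name) for name in STRATEGY_NAMES])
    best = effects.argmax(axis=1)
    for k, name in enumerate(STRATEGY_NAMES):
        assert curve.probabilities[name][0] == pytest.approx(
            np.mean(best == k), abs=0.02
        )


def test_default_wtp_grid_brackets_threshold():
    grid = default_wtp_grid()
    assert grid[0] == 0.0 and grid[-1] == 30_000.0
    assert 15_000.0 in grid
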