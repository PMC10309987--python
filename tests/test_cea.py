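"""ICER quadrants, dominance analysis, frontier construction, NMB."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from vtecea import (
    StrategySpec,
    default_parameters,
    evaluate_strategy,
    icer,
    incremental_table,
    net_monetary_benefit,
)
from vtecea.cea import DOMINANT, DOMINATED, REFERENCE, TIE, EXTENDEDLY_DOMINATED
from vtecea.tree import CEResult


def fake_result(cost, effect, name="no_prophylaxis"):
    return CEResult(
        strategy=StrategySpec(name),
        expected_cost=cost,
        expected_effectiveness=effect,
        expected_deaths=0.0,
        pathways=(),
    )


@pytest.mark.parametrize(
    "d_cost, d_eff, expected",
    [
        (100.0, 0.5, 200.0),
        (351.0, -0.055, DOMINATED),
        (-10.0, 0.0, DOMINANT),
        (0.0, 0.1, DOMINANT),
        (10.0, 0.0, DOMINATED),
        (0.0, 0.0, TIE),
        (-100.0, -0.5, 200.0),  # cheaper-comparator perspective
    ],
)
def test_icer_quadrant_mapping(d_cost, d_eff, expected):
    assert icer(d_cost, d_eff) == expected


def test_icer_published_increments_reproduce_ratio():
    assert icer(36.0, 0.00459) == pytest.approx(7843, rel=2e-3)


def test_base_case_table_flags_lmwh_dominated(defaults):
    results = [
        evaluate_strategy(defaults, StrategySpec(name))
        for name in ("no_prophylaxis", "IPC", "LMWH")
    ]
    rows = {r.strategy_label: r for r in incremental_table(results)}
    assert rows["LMWH"].status == DOMINATED
    assert rows["no_prophylaxis"].status == REFERENCE
    assert rows["IPC"].icer == pytest.approx(
        (rows["IPC"].expected_cost - rows["no_prophylaxis"].expected_cost)
        / (rows["IPC"].expected_effectiveness - rows["no_prophylaxis"].expected_effectiveness)
    )


def test_equal_strategies_flagged_tie():
    rows = incremental_table([fake_result(10.0, 0.5), fake_result(10.0, 0.5, "IPC")])
    assert [r.status for r in rows] == [REFERENCE, TIE]


def test_extended_dominance_removed_from_frontier():
    # middle strategy lies above the line joining the outer two
    rows = incremental_table(
        [fake_result(0.0, 0.5), fake_result(10.0, 0.9, "IPC"), fake_result(5.0, 0.6, "LMWH")]
    )
    by_label = {r.strategy_label: r for r in rows}
    assert by_label["LMWH"].status == EXTENDEDLY_DOMINATED
    assert by_label["IPC"].icer == pytest.approx(10.0 / 0.4)


def test_fewer_than_two_strategies_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        incremental_table([fake_result(1.0, 0.5)])


def brute_force_frontier(points):
    """Oracle: a point is on the frontier iff no convex combination of two
    others is at least as effective for no more cost (exact rational
    arithmetic; inputs must be exactly representable floats)."""
    from fractions import Fraction

    exact = [(Fraction(c), Fraction(e)) for c, e in points]
    frontier = []
    for i, (c_i, e_i) in enumerate(exact):
        others = [p for j, p in enumerate(exact) if j != i]
        dominated = any(c <= c_i and e >= e_i and (c < c_i or e > e_i) for c, e in others)
        ext = False
        for (c_a, e_a), (c_b, e_b) in itertools.combinations(others, 2):
            # the feasible lambda set is an interval whose endpoints lie in
            # {0, 1, lam_c, lam_e}; testing those plus all their midpoints is
            # exhaustive for a linear system
            cands = {Fraction(0), Fraction(1)}
            if c_a != c_b:
                cands.add(Fraction(c_i - c_b, c_a - c_b))
            if e_a != e_b:
                cands.add(Fraction(e_i - e_b, e_a - e_b))
            cands |= {(x + y) / 2 for x, y in itertools.combinations(sorted(cands), 2)}
            for lam in cands:
                if not 0 <= lam <= 1:
                    continue
                c_mix = lam * c_a + (1 - lam) * c_b
                e_mix = lam * e_a + (1 - lam) * e_b
                if c_mix <= c_i and e_mix >= e_i and (c_mix < c_i or e_mix > e_i):
                    ext = True
        if not dominated and not ext:
            frontier.append((float(c_i), float(e_i)))
    return sorted(set(frontier))


@settings(deadline=None, max_examples=40)
@given(
    points=st.lists(
        st.tuples(
            # small-integer costs and sixteenths for effectiveness: exactly
            # representable, so float and rational arithmetic agree
            st.integers(0, 20).map(float),
            st.integers(0, 16).map(lambda k: k / 16),
        ),
        min_size=2,
        max_size=5,
        unique=True,
    )
)
def test_frontier_matches_brute_force_oracle(points):
    names = ("no_prophylaxis", "IPC", "LMWH", "no_prophylaxis", "IPC")
    results = [fake_result(c, e, names[i]) for i, (c, e) in enumerate(points)]
    rows = incremental_table(results)
    frontier_rows = sorted(
        {
            (r.expected_cost, r.expected_effectiveness)
            for r in rows
            if r.status in (REFERENCE, "")
        }
    )
    assert frontier_rows == brute_force_frontier(points)


def test_net_monetary_benefit_values():
    assert net_monetary_benefit(fake_result(0.0, 1.0), 15_000.0) == 15_000.0
    assert net_monetary_benefit(fake_result(914.0, 0.912), 0.0) == -914.0
    with pytest.raises(ValueError, match="non-negative"):
        net_monetary_benefit(fake_result(0.0, 1.0), -1.0)


def test_nmb_and_icer_rules_agree_at_base_case(defaults):
    none = evaluate_strategy(defaults, StrategySpec("no_prophylaxis"))
    ipc = evaluate_strategy(defaults, StrategySpec("IPC"))
    ratio = icer(
        ipc.expected_cost - none.expected_cost,
        ipc.expected_effectiveness - none.expected_effectiveness,
    )
    assert ratio < defaults.wtp  # ICER rule accepts IPC
    assert net_monetary_benefit(ipc, defaults.wtp) > net_monetary_benefit(none, defaults.wtp)


@settings(deadline=None, max_examples=100)
@given(
    cost_a=st.floats(0, 2000),
    cost_b=st.floats(0, 2000),
    eff_a=st.floats(0, 1),
    eff_b=st.floats(0, 1),
    wtp=st.floats(0, 50_000),
)
def test_nmb_preference_matches_icer_decision_rule(cost_a, cost_b, eff_a, eff_b, wtp):
    """For any strategy pair, maximizing NMB picks the same strategy as the
    ICER-vs-threshold rule."""
    from hypothesis import assume

    # knife-edge indifference is sensitive to float rounding in either rule
    assume(abs(wtp * (eff_b - eff_a) - (cost_b - cost_a)) > 1e-6)
    a, b = fake_result(cost_a, eff_a), fake_result(cost_b, eff_b, "IPC")
    nmb_prefers_b = net_monetary_benefit(b, wtp) > net_monetary_benefit(a, wtp)
    ratio = icer(cost_b - cost_a, eff_b - eff_a)
    if ratio == DOMINANT:
        icer_prefers_b = True
    elif ratio in (DOMINATED, TIE):
        icer_prefers_b = False
    elif eff_b > eff_a:  # b costlier but more effective: accept iff ICER < wtp
        icer_prefers_b = ratio < wtp
    else:  # b cheaper but less effective: keep b iff forgone value < savings
        icer_prefers_b = ratio > wtp
    assert nmb_prefers_b == icer_prefers_b


def test_icer_scale_invariance(defaults):
    results = [
        evaluate_strategy(defaults, StrategySpec(name))
        for name in ("no_prophylaxis", "IPC")
    ]
    scaled = defaults
    for key in ("c_dvt", "c_pe", "c_minor", "c_major", "c_hypo", "c_ipc", "c_lmwh"):
        scaled = scaled.with_value(key, 3.0 * defaults.get(key).value)
    results_scaled = [
        evaluate_strategy(scaled, StrategySpec(name))
        for name in ("no_prophylaxis", "IPC")
    ]
    base_icer = incremental_table(results)[1].icer
    scaled_icer = incremental_table(results_scaled)[1].icer
    assert scaled_icer == pytest.approx(3.0 * base_icer)
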