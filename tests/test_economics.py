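"""Valuation tests: utility adjustment with capping, discounted lifetime
outcomes against hand-computed sums, ICER quadrant logic, net benefit,
nonparametric CIs against a sorting oracle, and convergence checking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exocea import (
    CEOutcome,
    CostModel,
    DiscountSpec,
    HealthState,
    UtilityModel,
    apply_utility_adjustments,
    check_convergence,
    incremental,
    is_cost_effective,
    lifetime_outcomes,
    net_monetary_benefit,
    percentile_ci,
)
from exocea.states import Trace

S = HealthState


def full_alive_trace(cycles, state=S.POST_PRIMARY_HOME):
    occ = np.zeros((cycles + 1, 7))
    occ[:, int(state)] = 1.0
    return Trace(occ)


def zero_costs(**kw):
    return CostModel(
        annual_state_costs=np.zeros(7), event_cost_shf=0.0, event_cost_major=0.0, **kw
    )


# --- utility adjustment ----------------------------------------------------


@pytest.mark.parametrize(
    "base,mult,ratio,expected",
    [
        (0.66, 0.74, 1.0, 0.4884),  # dementia decrement, hand product
        (0.66, 0.96, 1.70, 1.0),  # raw product 1.0771 -> capped at full health
        (0.44, 1.0, 1.0, 0.44),
    ],
)
def test_utility_adjustment_and_cap(base, mult, ratio, expected):
    assert apply_utility_adjustments(base, mult, ratio) == pytest.approx(expected, abs=1e-10)


def test_utility_adjustment_rejects_nonpositive():
    with pytest.raises(ValueError):
        apply_utility_adjustments(0.66, 0.0, 1.0)


# --- lifetime outcomes -----------------------------------------------------


def test_undiscounted_full_health_qalys_equal_years():
    u = UtilityModel(u_post_primary=1.0, u_fracture_year=1.0)
    out = lifetime_outcomes(
        full_alive_trace(10), u, zero_costs(), DiscountSpec(rate=0.0, half_cycle=True)
    )
    assert out.qaly == pytest.approx(10.0)
    assert out.cost == 0.0


def test_half_cycle_trapezoid_of_instant_death():
    occ = np.zeros((2, 7))
    occ[0, S.POST_PRIMARY_HOME] = 1.0
    occ[1, S.DEAD] = 1.0
    u = UtilityModel(u_post_primary=1.0, u_fracture_year=1.0)
    out = lifetime_outcomes(
        Trace(occ), u, zero_costs(), DiscountSpec(rate=0.0, half_cycle=True)
    )
    assert out.qaly == pytest.approx(0.5)


def test_two_cycle_discounted_sum_matches_hand_computation():
    # occupancy: 1.0 -> 0.6 -> 0.3 in post-primary home, rest dead
    occ = np.zeros((3, 7))
    occ[:, S.POST_PRIMARY_HOME] = [1.0, 0.6, 0.3]
    occ[:, S.DEAD] = [0.0, 0.4, 0.7]
    costs = zero_costs()
    costs.annual_state_costs[S.POST_PRIMARY_HOME] = 1000.0
    out = lifetime_outcomes(
        Trace(occ), UtilityModel(), costs, DiscountSpec(rate=0.035, half_cycle=True)
    )
    # half-cycle occupancies 0.8 and 0.45; spreadsheet arithmetic:
    # qaly = 0.66*(0.8 + 0.45/1.035); cost = 1000*(0.8 + 0.45/1.035)
    assert out.qaly == pytest.approx(0.66 * (0.8 + 0.45 / 1.035), abs=1e-12)
    assert out.cost == pytest.approx(1000.0 * (0.8 + 0.45 / 1.035), abs=1e-9)


def test_discounting_reduces_outcomes():
    trace = full_alive_trace(20)
    costs = zero_costs()
    costs.annual_state_costs[S.POST_PRIMARY_HOME] = 500.0
    disc = lifetime_outcomes(trace, UtilityModel(), costs, DiscountSpec(rate=0.035))
    undisc = lifetime_outcomes(trace, UtilityModel(), costs, DiscountSpec(rate=0.0))
    assert disc.qaly < undisc.qaly
    assert disc.cost < undisc.cost


def test_leasing_accrues_per_life_year_and_purchase_is_irreversible():
    # half the cohort dies immediately at the end of year 1
    occ = np.zeros((7, 7))
    occ[:, S.POST_PRIMARY_HOME] = [1.0] + [0.5] * 6
    occ[:, S.DEAD] = 1.0 - occ[:, S.POST_PRIMARY_HOME]
    disc = DiscountSpec(rate=0.0, half_cycle=True)
    lease = lifetime_outcomes(
        Trace(occ), UtilityModel(), zero_costs(exo_cost_mode="leasing", leasing_fee=1000.0),
        disc, arm="exoskeleton",
    )
    # life-years: 0.75 + 5*0.5 = 3.25
    assert lease.cost == pytest.approx(1000.0 * 3.25)
    buy = lifetime_outcomes(
        Trace(occ), UtilityModel(),
        zero_costs(exo_cost_mode="purchase", purchase_price=10000.0, maintenance=0.0),
        disc, arm="exoskeleton",
    )
    # purchases at cycles 0 (everyone alive) and 5 (half alive), charged in full
    assert buy.cost == pytest.approx(10000.0 * (1.0 + 0.5))


# --- increments, ICER, NMB -------------------------------------------------


def test_printed_per_arm_values_give_printed_increments():
    incr = incremental(
        CEOutcome(104735.0, 7.26, "exoskeleton"), CEOutcome(59588.0, 4.85, "usual_care")
    )
    assert incr.delta_cost == pytest.approx(45147.0)
    assert incr.delta_qaly == pytest.approx(2.41)
    assert incr.flag == "icer"


def test_identical_outcomes_flag_zero_effect():
    incr = incremental(CEOutcome(100.0, 1.0), CEOutcome(100.0, 1.0))
    assert incr.flag == "zero_effect"
    assert (incr.delta_cost, incr.delta_qaly) == (0.0, 0.0)


def test_cheaper_and_better_is_dominant():
    incr = incremental(CEOutcome(100.0, 2.0, "exoskeleton"), CEOutcome(200.0, 1.0))
    assert incr.flag == "dominant"
    assert is_cost_effective(incr)


@settings(derandomize=True, max_examples=200)
@given(dc=st.floats(-1e5, 1e5), de=st.floats(-10, 10))
def test_quadrant_logic_is_exhaustive_and_exclusive(dc, de):
    incr = incremental(CEOutcome(1000.0 + dc, 5.0 + de, "exoskeleton"), CEOutcome(1000.0, 5.0))
    assert incr.flag in ("icer", "dominant", "dominated", "zero_effect")
    if incr.flag == "icer":
        assert np.isfinite(incr.icer)
        assert dc * de > 0  # same strict sign
    else:
        assert np.isnan(incr.icer)


@settings(derandomize=True, max_examples=100)
@given(dc=st.floats(1.0, 1e5), de=st.floats(1e-3, 10.0))
def test_nmb_and_icer_decisions_agree_when_qalys_gained(dc, de):
    lam = 20000.0
    incr = incremental(CEOutcome(dc, de, "exoskeleton"), CEOutcome(0.0, 0.0))
    nmb_positive = lam * de - dc > 0
    assert is_cost_effective(incr, lam) == (incr.icer <= lam)
    if incr.icer != lam:  # knife-edge ties differ only at equality
        assert nmb_positive == (incr.icer < lam)


def test_net_monetary_benefit_values():
    assert net_monetary_benefit(CEOutcome(0.0, 1.0), 20000.0) == 20000.0
    assert net_monetary_benefit(CEOutcome(20000.0, 1.0), 20000.0) == 0.0
    # on the printed increments: 20000 * 2.41 - 45147 = 3053
    assert net_monetary_benefit(CEOutcome(45147.0, 2.41), 20000.0) == pytest.approx(3053.0)


# --- percentile CI ---------------------------------------------------------


def test_percentile_ci_examples():
    assert percentile_ci(np.full(50, 3.7)) == (pytest.approx(3.7), pytest.approx(3.7))
    lo, hi = percentile_ci(np.arange(1, 1001, dtype=float))
    assert lo == pytest.approx(25.975)  # 1 + 0.025*999, order-statistic interpolation
    assert hi == pytest.approx(975.025)
    lo, hi = percentile_ci([5.0, 1.0, 9.0], level=1.0)
    assert (lo, hi) == (1.0, 9.0)
    with pytest.raises(ValueError):
        percentile_ci([])


def brute_force_percentile(sorted_x, q):
    """Linear interpolation between order statistics, written independently."""
    n = len(sorted_x)
    h = q * (n - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return sorted_x[lo] + (h - lo) * (sorted_x[hi] - sorted_x[lo])


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=100))
def test_percentile_ci_matches_sorting_oracle(xs):
    xs_sorted = sorted(xs)
    lo, hi = percentile_ci(xs)
    assert lo == pytest.approx(brute_force_percentile(xs_sorted, 0.025), rel=1e-12, abs=1e-9)
    assert hi == pytest.approx(brute_force_percentile(xs_sorted, 0.975), rel=1e-12, abs=1e-9)


# --- convergence -----------------------------------------------------------


def scan_convergence_oracle(means, tol):
    """Exhaustive scan: smallest 1-based n with all later means in the band."""
    final = means[-1]
    scale = abs(final) if final != 0 else 1.0
    for n in range(1, len(means) + 1):
        if all(abs(m - final) <= tol * scale for m in means[n - 1 :]):
            return n
    return len(means)


def test_constant_sequence_converges_immediately():
    res = check_convergence(np.full(100, 2.5))
    assert res.n_required == 1 and res.converged


def test_perturbed_sequence_matches_scan_oracle(rng):
    limit = 10.0
    n = np.arange(1, 501)
    means = limit + rng.choice([-1, 1], size=500) / n
    res = check_convergence(means, tolerance=0.01)
    assert res.n_required == scan_convergence_oracle(list(means), 0.01)


def test_diverging_sequence_not_converged():
    res = check_convergence(np.arange(1.0, 101.0), tolerance=0.005)
    assert not res.converged
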