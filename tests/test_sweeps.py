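"""Scenario machinery tests: grid cardinalities, frontier extraction against a
brute-force scan, seed isolation, heat-map export and quantile regression
against a grid-search pinball-loss oracle."""

import numpy as np
import pandas as pd
import pytest

from exocea import (
    CohortProfile,
    CostScenario,
    PSASpec,
    ThresholdGrid,
    UncertaintyGrid,
    build_threshold_grid,
    build_uncertainty_grid,
    export_heatmap,
    extract_frontier,
    quantile_regression,
    run_threshold_scenario,
    run_threshold_sweep,
    run_uncertainty_scenario,
)


# --- grids -----------------------------------------------------------------


def test_default_grid_cardinalities():
    grid = ThresholdGrid()
    assert len(grid.hr_values) == 6
    assert len(grid.ur_values) == 17
    assert len(grid.strata) == 12
    assert len(grid.cost_scenarios) == 8
    assert grid.n_scenarios == 6 * 17 * 12 * 8 == 9792


def test_single_point_grid():
    grid = build_threshold_grid(
        hr_values=[0.75],
        ur_values=[1.3],
        strata=[CohortProfile(65, "female", "cvd")],
        cost_scenarios=[CostScenario("leasing", 4000.0)],
    )
    assert grid.n_scenarios == 1
    assert len(list(grid.scenarios())) == 1


def test_per_stratum_cost_block_is_102():
    grid = build_threshold_grid(
        strata=[CohortProfile(65, "female", "cvd")],
        cost_scenarios=[CostScenario("leasing", 3000.0)],
    )
    assert grid.n_scenarios == 102


def test_invalid_grids_rejected():
    from exocea.sweeps import _grid

    with pytest.raises(ValueError):
        _grid(0.5, 1.125, -0.125)
    with pytest.raises(ValueError):
        build_threshold_grid(hr_values=[])


def _fake_frontier(n):
    return pd.DataFrame(
        {
            "stratum": ["s"] * n,
            "cost_mode": ["leasing"] * n,
            "cost_amount": [3000.0] * n,
            "hr": np.linspace(0.5, 1.125, n),
            "ur": [1.3] * n,
        }
    )


def test_uncertainty_grid_counts():
    se_grid = UncertaintyGrid()
    assert len(se_grid.hr_se_values) == 8
    assert len(se_grid.ur_se_values) == 10
    assert se_grid.n_combinations == 80
    assert len(build_uncertainty_grid(_fake_frontier(1))) == 80
    assert len(build_uncertainty_grid(_fake_frontier(286))) == 22880
    assert len(build_uncertainty_grid(_fake_frontier(0))) == 0


# --- frontier extraction ---------------------------------------------------


def _results_from_flags(flag_matrix, hr_values, ur_values):
    rows = []
    for i, hr in enumerate(hr_values):
        for j, ur in enumerate(ur_values):
            rows.append(
                {
                    "stratum": "s",
                    "cost_mode": "leasing",
                    "cost_amount": 3000.0,
                    "hr": hr,
                    "ur": ur,
                    "icer": 15000.0 if flag_matrix[i][j] else 25000.0,
                    "cost_effective": bool(flag_matrix[i][j]),
                    "prob_ce": float(flag_matrix[i][j]),
                }
            )
    return pd.DataFrame(rows)


def brute_force_frontier(flag_matrix, hr_values, ur_values):
    out = {}
    for i, hr in enumerate(hr_values):
        for j, ur in enumerate(ur_values):
            if flag_matrix[i][j]:
                out[hr] = ur
                break
    return out


@pytest.mark.parametrize(
    "flags",
    [
        [[0, 0, 1, 1], [0, 1, 1, 1]],  # monotone
        [[1, 1, 1, 1], [1, 1, 1, 1]],  # all cost-effective
        [[0, 0, 0, 0], [0, 0, 0, 0]],  # none
        [[0, 1, 0, 1], [1, 0, 1, 1]],  # non-monotone Monte-Carlo noise
    ],
)
def test_frontier_matches_exhaustive_scan(flags):
    hr_values = [0.5, 0.625]
    ur_values = [0.9, 0.95, 1.0, 1.05]
    res = _results_from_flags(flags, hr_values, ur_values)
    frontier = extract_frontier(res)
    expected = brute_force_frontier(flags, hr_values, ur_values)
    got = dict(zip(frontier["hr"], frontier["ur"])) if len(frontier) else {}
    assert got == expected
    if all(all(row) for row in flags):
        assert set(frontier["ur"]) == {0.9}
    if len(frontier):
        # minimality: the grid point one UR-step below is not cost-effective
        for _, row in frontier.iterrows():
            j = ur_values.index(row["ur"])
            if j > 0:
                i = hr_values.index(row["hr"])
                assert not flags[i][j - 1]


# --- scenario runs ---------------------------------------------------------


COST = CostScenario("leasing", 4000.0)


def test_null_intervention_with_device_cost_is_dominated(bundle, small_psa):
    res = run_threshold_scenario(bundle, COST, hr=1.0, ur=1.0, psa_spec=small_psa)
    assert res["flag"] == "dominated"
    assert not res["cost_effective"]
    assert res["delta_qaly"] == pytest.approx(0.0, abs=1e-12)
    assert res["delta_cost"] > 0


def test_cost_effectiveness_improves_with_utility_ratio(bundle, small_psa):
    probs = [
        run_threshold_scenario(bundle, COST, hr=0.75, ur=ur, psa_spec=small_psa)["prob_ce"]
        for ur in (1.0, 1.35, 1.70)
    ]
    assert probs[0] <= probs[1] + 0.05 <= probs[2] + 0.10
    assert probs[2] > probs[0]


def test_generous_scenario_is_cost_effective(bundle, small_psa):
    cheap = CostScenario("leasing", 3000.0)
    res = run_threshold_scenario(bundle, cheap, hr=0.5, ur=1.70, psa_spec=small_psa)
    assert res["cost_effective"]


def test_scenario_results_independent_of_sweep_membership(bundle, small_psa):
    """Per-scenario seed derivation: a scenario's result is bit-identical run
    alone or as part of a larger sweep, in any order."""
    grid = build_threshold_grid(
        hr_values=[0.75],
        ur_values=[1.25, 1.30],
        strata=[bundle.profile],
        cost_scenarios=[COST],
    )
    sweep = run_threshold_sweep({bundle.profile.label: bundle}, grid, small_psa)
    solo = run_threshold_scenario(bundle, COST, hr=0.75, ur=1.30, psa_spec=small_psa)
    row = sweep[(sweep["ur"] == 1.30)].iloc[0].to_dict()
    for key in ("delta_cost", "delta_qaly", "icer", "prob_ce", "seed"):
        assert row[key] == solo[key]


def test_uncertainty_scenario_ci_matches_analytic_quantiles(bundle, small_psa):
    psa = PSASpec(n_draws=2000, seed=3)
    res = run_uncertainty_scenario(
        bundle, COST, hr_median=0.75, ur_median=1.30, hr_se=1.05, ur_se=0.25,
        psa_spec=psa, incidence_counts=np.full(10, 1000.0),
    )
    z = 1.959963984540054
    lo = 0.75 * np.exp(-z * np.log(1.05))
    hi = 0.75 * np.exp(z * np.log(1.05))
    assert res["hr_ci_lo"] == pytest.approx(lo, abs=0.01)
    assert res["hr_ci_hi"] == pytest.approx(hi, abs=0.01)
    assert res["population_10yr"] == pytest.approx(10000.0)
    assert res["population_evpi"] >= 0.0


def test_degenerate_standard_errors_pin_the_effects(bundle, small_psa):
    res = run_uncertainty_scenario(
        bundle, COST, hr_median=0.75, ur_median=1.30, hr_se=1.0, ur_se=0.0,
        psa_spec=small_psa, incidence_counts=np.full(10, 1000.0),
    )
    assert res["hr_ci_lo"] == res["hr_ci_hi"] == pytest.approx(0.75)
    assert res["ur_ci_lo"] == res["ur_ci_hi"] == pytest.approx(1.30)


# --- heat map --------------------------------------------------------------


def test_heatmap_shape_bounds_and_missing_cells(bundle, small_psa):
    grid = build_threshold_grid(
        hr_values=[0.5, 1.125],
        ur_values=[0.9, 1.3, 1.7],
        strata=[bundle.profile],
        cost_scenarios=[COST],
    )
    res = run_threshold_sweep({bundle.profile.label: bundle}, grid, small_psa)
    hm = export_heatmap(res, bundle.profile.label, COST)
    assert hm.shape == (2, 3)
    assert ((hm >= 0) & (hm <= 1)).all().all()
    # roughly monotone along UR within each HR row (Monte-Carlo slack)
    vals = hm.to_numpy()
    assert np.all(np.diff(vals, axis=1) >= -0.05)
    with pytest.raises(ValueError, match="missing"):
        export_heatmap(res.iloc[:-1], bundle.profile.label, COST)
    with pytest.raises(ValueError, match="no results"):
        export_heatmap(res, "nonexistent", COST)


def test_all_dominated_grid_yields_zero_matrix():
    res = _results_from_flags([[0, 0], [0, 0]], [0.5, 0.625], [0.9, 0.95])
    hm = export_heatmap(res, "s", CostScenario("leasing", 3000.0))
    assert (hm.to_numpy() == 0).all()


# --- quantile regression ---------------------------------------------------


def pinball_loss(y, yhat, tau):
    r = y - yhat
    return np.sum(np.where(r >= 0, tau * r, (tau - 1) * r))


def test_collinear_points_fit_exactly():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    y = 2.5 + 0.5 * x
    fit = quantile_regression(x, y, tau=0.5)
    assert fit.intercept == pytest.approx(2.5, abs=1e-8)
    assert fit.slope == pytest.approx(0.5, abs=1e-8)
    assert pinball_loss(y, fit.intercept + fit.slope * x, 0.5) == pytest.approx(0.0, abs=1e-8)


def test_five_point_fit_beats_grid_search_oracle():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = np.array([1.0, 1.6, 1.9, 3.2, 3.8])
    fit = quantile_regression(x, y, tau=0.5)
    grid_a = np.arange(0.0, 2.0, 1e-3)
    grid_b = np.arange(0.0, 1.5, 1e-3)
    losses = np.array(
        [[pinball_loss(y, a + b * x, 0.5) for b in grid_b] for a in grid_a]
    )
    best = losses.min()
    assert pinball_loss(y, fit.intercept + fit.slope * x, 0.5) <= best + 1e-6


def test_median_fit_on_symmetric_noise_tracks_lad_line(rng):
    x = np.linspace(0, 10, 200)
    y = 1.0 + 2.0 * x + rng.normal(0, 0.5, size=200)
    fit = quantile_regression(x, y, tau=0.5)
    assert fit.slope == pytest.approx(2.0, abs=0.1)
    assert fit.intercept == pytest.approx(1.0, abs=0.5)


def test_degenerate_x_is_flagged():
    fit = quantile_regression(np.ones(5), np.arange(5.0), tau=0.5)
    assert fit.degenerate
    assert np.isnan(fit.slope)
    assert fit.intercept == pytest.approx(2.0)
    with pytest.raises(ValueError):
        quantile_regression([1.0, 2.0], [1.0, 2.0], tau=0.5)
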