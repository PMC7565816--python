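"""Base-case PSA, threshold analysis and uncertainty analysis drivers.

The threshold analysis freezes the exoskeleton's two effect parameters — the
hazard ratio (HR) of falls leading to second hip fracture and the
quality-of-life utility-ratio (UR) — on a deterministic grid, runs the
probabilistic model for every combination of grid point, stratum and device
cost scenario, and retains per fixed HR the lowest UR that still yields an
ICER at or below the willingness-to-pay threshold (the cost-effectiveness
frontier).  The uncertainty analysis then re-introduces uncertainty around
each frontier scenario on a grid of standard errors, recording the resulting
95% CIs of HR and UR and the population EVPI, which are summarised with
quantile regressions of CI bounds against population EVPI.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bundle import ParameterBundle
from .economics import (
    CEOutcome,
    CostModel,
    Incremental,
    incremental,
    is_cost_effective,
    net_monetary_benefit,
    percentile_ci,
)
from .engine import run_arms, sample_draws
from .psa import (
    EffectDistribution,
    PSASpec,
    base_case_hr_distribution,
    base_case_ur_distribution,
    hr_se_to_log_sd,
    scenario_seed,
    ur_se_to_log_sd,
)
from .states import CohortProfile
from .voi import evpi_per_person, population_evpi

__all__ = [
    "CostScenario",
    "ThresholdGrid",
    "FrontierScenario",
    "UncertaintyGrid",
    "QuantRegFit",
    "default_cost_scenarios",
    "default_strata",
    "build_threshold_grid",
    "run_psa",
    "run_threshold_scenario",
    "run_threshold_sweep",
    "extract_frontier",
    "build_uncertainty_grid",
    "run_uncertainty_scenario",
    "run_uncertainty_sweep",
    "quantile_regression",
    "summarise_ci_vs_evpi",
    "export_heatmap",
]

logger = logging.getLogger(__name__)

LEASING_FEES = (3000.0, 4000.0, 5000.0, 6000.0)
PURCHASE_PRICES = (12500.0, 15000.0, 17500.0, 20000.0)


@dataclass(frozen=True)
class CostScenario:
    """A device cost arrangement: leasing fee/year or irreversible purchase price."""

    mode: str
    amount: float

    def __post_init__(self) -> None:
        if self.mode not in ("leasing", "purchase"):
            raise ValueError(f"unknown cost mode {self.mode!r}")
        if self.amount <= 0:
            raise ValueError("cost must be positive")

    @property
    def label(self) -> str:
        return f"{self.mode}_{int(self.amount)}"

    def apply(self, cost: CostModel) -> CostModel:
        if self.mode == "leasing":
            return replace(cost, exo_cost_mode="leasing", leasing_fee=self.amount)
        return replace(cost, exo_cost_mode="purchase", purchase_price=self.amount)


def default_cost_scenarios() -> tuple:
    """Four leasing fees and four purchase prices (eight scenarios)."""
    return tuple(CostScenario("leasing", f) for f in LEASING_FEES) + tuple(
        CostScenario("purchase", p) for p in PURCHASE_PRICES
    )


def default_strata() -> tuple:
    """Ages 65/75/85 x sex x comorbidity (CVD, dementia): 12 strata."""
    return tuple(
        CohortProfile(age, sex, comorbidity)
        for age in (65, 75, 85)
        for sex in ("female", "male")
        for comorbidity in ("cvd", "dementia")
    )


def _grid(start: float, stop: float, step: float) -> tuple:
    if step <= 0:
        raise ValueError("grid step must be positive")
    n = int(round((stop - start) / step)) + 1
    return tuple(round(start + i * step, 10) for i in range(n))


@dataclass(frozen=True)
class ThresholdGrid:
    """The deterministic (HR, UR) grid crossed with strata and cost scenarios.

    Defaults: HR 0.5..1.125 step 0.125 (6 values), UR 0.90..1.70 step 0.05
    (17 values), 12 strata, 8 cost scenarios — 9792 scenarios in total.
    """

    hr_values: tuple = field(default_factory=lambda: _grid(0.5, 1.125, 0.125))
    ur_values: tuple = field(default_factory=lambda: _grid(0.90, 1.70, 0.05))
    strata: tuple = field(default_factory=default_strata)
    cost_scenarios: tuple = field(default_factory=default_cost_scenarios)

    @property
    def n_scenarios(self) -> int:
        return (
            len(self.hr_values)
            * len(self.ur_values)
            * len(self.strata)
            * len(self.cost_scenarios)
        )

    def scenarios(self) -> Iterable[tuple]:
        for profile in self.strata:
            for cost in self.cost_scenarios:
                for hr in self.hr_values:
                    for ur in self.ur_values:
                        yield profile, cost, hr, ur


def build_threshold_grid(
    hr_values: Sequence[float] | None = None,
    ur_values: Sequence[float] | None = None,
    strata: Sequence[CohortProfile] | None = None,
    cost_scenarios: Sequence[CostScenario] | None = None,
) -> ThresholdGrid:
    """Threshold grid with defaults for any unspecified axis."""
    kwargs = {}
    if hr_values is not None:
        kwargs["hr_values"] = tuple(hr_values)
    if ur_values is not None:
        kwargs["ur_values"] = tuple(ur_values)
    if strata is not None:
        kwargs["strata"] = tuple(strata)
    if cost_scenarios is not None:
        kwargs["cost_scenarios"] = tuple(cost_scenarios)
    grid = ThresholdGrid(**kwargs)
    for name in ("hr_values", "ur_values", "strata", "cost_scenarios"):
        if len(getattr(grid, name)) == 0:
            raise ValueError(f"{name} must be non-empty")
    return grid


@dataclass(frozen=True)
class FrontierScenario:
    """Per fixed HR, the lowest UR that is still cost-effective for a stratum/cost."""

    stratum: str
    cost_scenario: CostScenario
    hr: float
    ur: float
    icer: float


@dataclass(frozen=True)
class UncertaintyGrid:
    """Standard-error grid applied around each frontier scenario (8 x 10 = 80)."""

    hr_se_values: tuple = field(default_factory=lambda: _grid(1.05, 1.40, 0.05))
    ur_se_values: tuple = field(default_factory=lambda: _grid(0.25, 2.50, 0.25))

    @property
    def n_combinations(self) -> int:
        return len(self.hr_se_values) * len(self.ur_se_values)


# ---------------------------------------------------------------------------
# base-case PSA


def run_psa(
    bundle: ParameterBundle,
    psa_spec: PSASpec,
    cost_scenario: CostScenario | None = None,
    hr_dist: EffectDistribution | None = None,
    ur_dist: EffectDistribution | None = None,
) -> dict:
    """Base-case probabilistic sensitivity analysis for one stratum.

    Returns per-draw results (tidy frame: draw_id, arm, cost, qaly), the
    incremental summary with nonparametric 95% CIs, and the per-draw net
    monetary benefit matrix for value-of-information analysis.
    """
    rng = np.random.default_rng(
        scenario_seed(psa_spec.seed, "base_case", bundle.profile.label)
    )
    n = psa_spec.n_draws
    draws = sample_draws(bundle, n, rng)
    hr = (hr_dist or bundle.hr_dist).sample(n, rng)
    ur = (ur_dist or bundle.ur_dist).sample(n, rng)
    cost_model = cost_scenario.apply(bundle.cost) if cost_scenario else None
    out = run_arms(bundle, draws, hr, ur, cost_model=cost_model)

    dc = out["cost_exoskeleton"] - out["cost_usual_care"]
    de = out["qaly_exoskeleton"] - out["qaly_usual_care"]
    incr = incremental(
        CEOutcome(float(out["cost_exoskeleton"].mean()), float(out["qaly_exoskeleton"].mean()), "exoskeleton"),
        CEOutcome(float(out["cost_usual_care"].mean()), float(out["qaly_usual_care"].mean()), "usual_care"),
    )
    nmb = np.column_stack(
        [
            bundle.lam * out["qaly_usual_care"] - out["cost_usual_care"],
            bundle.lam * out["qaly_exoskeleton"] - out["cost_exoskeleton"],
        ]
    )
    per_draw = pd.DataFrame(
        {
            "draw_id": np.tile(np.arange(n), 2),
            "arm": np.repeat(["usual_care", "exoskeleton"], n),
            "cost": np.concatenate([out["cost_usual_care"], out["cost_exoskeleton"]]),
            "qaly": np.concatenate([out["qaly_usual_care"], out["qaly_exoskeleton"]]),
        }
    )
    summary = {
        "stratum": bundle.profile.label,
        "delta_cost": incr.delta_cost,
        "delta_cost_ci": percentile_ci(dc),
        "delta_qaly": incr.delta_qaly,
        "delta_qaly_ci": percentile_ci(de),
        "icer": incr.icer,
        "flag": incr.flag,
        "evpi_per_person": evpi_per_person(nmb),
        "prob_cost_effective": float(np.mean(nmb[:, 1] > nmb[:, 0])),
    }
    return {"per_draw": per_draw, "summary": summary, "nmb": nmb, "incremental": incr}


# ---------------------------------------------------------------------------
# threshold analysis


def run_threshold_scenario(
    bundle: ParameterBundle,
    cost_scenario: CostScenario,
    hr: float,
    ur: float,
    psa_spec: PSASpec,
) -> dict:
    """One deterministic-(HR, UR) scenario: n probabilistic draws, one ICER.

    HR and UR are held constant across draws; every other parameter is drawn
    from its distribution.  The ICER comes from the ratio of mean incremental
    cost to mean incremental QALYs; ``prob_ce`` is the share of draws with a
    positive incremental net benefit at the bundle's willingness-to-pay.
    """
    seed = scenario_seed(
        psa_spec.seed, "threshold", bundle.profile.label, cost_scenario.label, hr, ur
    )
    rng = np.random.default_rng(seed)
    draws = sample_draws(bundle, psa_spec.n_draws, rng)
    out = run_arms(bundle, draws, hr, ur, cost_model=cost_scenario.apply(bundle.cost))
    dc = out["cost_exoskeleton"] - out["cost_usual_care"]
    de = out["qaly_exoskeleton"] - out["qaly_usual_care"]
    incr = incremental(
        CEOutcome(float(out["cost_exoskeleton"].mean()), float(out["qaly_exoskeleton"].mean()), "exoskeleton"),
        CEOutcome(float(out["cost_usual_care"].mean()), float(out["qaly_usual_care"].mean()), "usual_care"),
    )
    inmb = bundle.lam * de - dc
    return {
        "stratum": bundle.profile.label,
        "cost_mode": cost_scenario.mode,
        "cost_amount": cost_scenario.amount,
        "hr": hr,
        "ur": ur,
        "delta_cost": incr.delta_cost,
        "delta_qaly": incr.delta_qaly,
        "icer": incr.icer,
        "flag": incr.flag,
        "cost_effective": is_cost_effective(incr, bundle.lam),
        "prob_ce": float(np.mean(inmb > 0)),
        "n_draws": psa_spec.n_draws,
        "seed": seed,
    }


def run_threshold_sweep(
    bundles: dict,
    grid: ThresholdGrid,
    psa_spec: PSASpec,
) -> pd.DataFrame:
    """Run every scenario of the grid; ``bundles`` maps stratum label -> bundle.

    Per-scenario seeds are derived from ``(master seed, stratum, cost, hr,
    ur)``, so results are reproducible and independent of execution order.
    """
    t0 = time.perf_counter()
    rows = []
    for profile, cost, hr, ur in grid.scenarios():
        bundle = bundles[profile.label]
        rows.append(run_threshold_scenario(bundle, cost, hr, ur, psa_spec))
    logger.info(
        "threshold sweep: %d scenarios x %d draws in %.1fs",
        len(rows), psa_spec.n_draws, time.perf_counter() - t0,
    )
    return pd.DataFrame(rows)


def extract_frontier(grid_results: pd.DataFrame, lam: float = 20000.0) -> pd.DataFrame:
    """Lowest cost-effective UR per (stratum, cost scenario, HR).

    Scans each HR row in increasing UR and keeps the first cost-effective
    scenario; Monte-Carlo noise can make the flag non-monotone along UR, in
    which case the lowest flagged UR is still taken and the row marked.
    Returns an empty frame when nothing is cost-effective.
    """
    frontier_rows = []
    keys = ["stratum", "cost_mode", "cost_amount", "hr"]
    for _, group in grid_results.groupby(keys, sort=True):
        group = group.sort_values("ur")
        flags = group["cost_effective"].to_numpy(dtype=bool)
        if not flags.any():
            continue
        first = int(np.argmax(flags))
        row = group.iloc[first].to_dict()
        row["monotone_ce"] = bool(np.all(flags[first:]))
        frontier_rows.append(row)
    return pd.DataFrame(frontier_rows)


# ---------------------------------------------------------------------------
# uncertainty analysis


def build_uncertainty_grid(
    frontier: pd.DataFrame,
    se_grid: UncertaintyGrid | None = None,
) -> pd.DataFrame:
    """Cross every frontier scenario with the SE grid (80 combinations each)."""
    se_grid = se_grid or UncertaintyGrid()
    if len(frontier) == 0:
        return pd.DataFrame(
            columns=list(frontier.columns) + ["hr_se", "ur_se"]
        )
    se_frame = pd.DataFrame(
        [
            {"hr_se": h, "ur_se": u}
            for h in se_grid.hr_se_values
            for u in se_grid.ur_se_values
        ]
    )
    return frontier.merge(se_frame, how="cross")


def run_uncertainty_scenario(
    bundle: ParameterBundle,
    cost_scenario: CostScenario,
    hr_median: float,
    ur_median: float,
    hr_se: float,
    ur_se: float,
    psa_spec: PSASpec,
    incidence_counts,
) -> dict:
    """One SE combination around a frontier scenario.

    HR and UR are drawn from lognormals centred (median) on the frontier
    values with the scenario's standard errors; the draws' nonparametric 95%
    CIs and the population EVPI of the resulting decision are recorded.
    """
    seed = scenario_seed(
        psa_spec.seed,
        "uncertainty",
        bundle.profile.label,
        cost_scenario.label,
        hr_median,
        ur_median,
        hr_se,
        ur_se,
    )
    rng = np.random.default_rng(seed)
    n = psa_spec.n_draws
    draws = sample_draws(bundle, n, rng)
    hr_dist = EffectDistribution(hr_median, hr_se_to_log_sd(hr_se))
    ur_dist = EffectDistribution(ur_median, ur_se_to_log_sd(ur_se, ur_median))
    hr = hr_dist.sample(n, rng)
    ur = ur_dist.sample(n, rng)
    out = run_arms(bundle, draws, hr, ur, cost_model=cost_scenario.apply(bundle.cost))
    nmb = np.column_stack(
        [
            bundle.lam * out["qaly_usual_care"] - out["cost_usual_care"],
            bundle.lam * out["qaly_exoskeleton"] - out["cost_exoskeleton"],
        ]
    )
    evpi = evpi_per_person(nmb)
    pop = float(np.sum(incidence_counts))
    hr_ci = percentile_ci(hr)
    ur_ci = percentile_ci(ur)
    return {
        "stratum": bundle.profile.label,
        "cost_mode": cost_scenario.mode,
        "cost_amount": cost_scenario.amount,
        "hr_median": hr_median,
        "ur_median": ur_median,
        "hr_se": hr_se,
        "ur_se": ur_se,
        "hr_ci_lo": hr_ci[0],
        "hr_ci_hi": hr_ci[1],
        "ur_ci_lo": ur_ci[0],
        "ur_ci_hi": ur_ci[1],
        "evpi_per_person": evpi,
        "population_10yr": pop,
        "population_evpi": population_evpi(evpi, incidence_counts),
        "n_draws": n,
        "seed": seed,
    }


def run_uncertainty_sweep(
    bundles: dict,
    frontier: pd.DataFrame,
    psa_spec: PSASpec,
    incidence: dict,
    se_grid: UncertaintyGrid | None = None,
) -> pd.DataFrame:
    """All SE combinations for every frontier scenario.

    ``incidence`` maps (sex, comorbidity) to annual incident counts; the
    stratum's counts are summed over the horizon for population EVPI.
    """
    t0 = time.perf_counter()
    scenarios = build_uncertainty_grid(frontier, se_grid)
    rows = []
    for _, s in scenarios.iterrows():
        bundle = bundles[s["stratum"]]
        profile = bundle.profile
        counts = incidence[(profile.sex, profile.comorbidity)]
        rows.append(
            run_uncertainty_scenario(
                bundle,
                CostScenario(s["cost_mode"], s["cost_amount"]),
                float(s["hr"]),
                float(s["ur"]),
                float(s["hr_se"]),
                float(s["ur_se"]),
                psa_spec,
                counts,
            )
        )
    logger.info(
        "uncertainty sweep: %d scenarios x %d draws in %.1fs",
        len(rows), psa_spec.n_draws, time.perf_counter() - t0,
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# summaries


@dataclass(frozen=True)
class QuantRegFit:
    """A straight line fitted at quantile ``tau`` by minimising pinball loss."""

    intercept: float
    slope: float
    tau: float
    degenerate: bool = False


def quantile_regression(x, y, tau: float = 0.5) -> QuantRegFit:
    """Quantile regression of ``y`` on ``x`` (single covariate).

    Used to describe CI bounds of the exoskeleton requirements as a function
    of population EVPI.  Degenerate ``x`` (zero variance) leaves the slope
    undefined; the fit is flagged and the intercept set to the empirical
    ``tau``-quantile of ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 (x, y) points")
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if np.ptp(x) == 0:
        return QuantRegFit(
            intercept=float(np.quantile(y, tau)), slope=float("nan"), tau=tau, degenerate=True
        )
    model = sm.QuantReg(y, sm.add_constant(x))
    res = model.fit(q=tau)
    return QuantRegFit(intercept=float(res.params[0]), slope=float(res.params[1]), tau=tau)


def summarise_ci_vs_evpi(
    uncertainty_results: pd.DataFrame,
    taus=(0.5,),
    bounds=("hr_ci_lo", "hr_ci_hi", "ur_ci_lo", "ur_ci_hi"),
    x_scale: float = 1e-6,
) -> pd.DataFrame:
    """Quantile-regression coefficients of each CI bound vs population EVPI.

    ``x_scale`` rescales the regressor; the default expresses population EVPI
    in GBP millions, which keeps the fit well conditioned and the slopes
    readable.
    """
    rows = []
    x = uncertainty_results["population_evpi"].to_numpy() * x_scale
    for bound in bounds:
        y = uncertainty_results[bound].to_numpy()
        for tau in taus:
            fit = quantile_regression(x, y, tau)
            rows.append(
                {
                    "bound": bound,
                    "tau": tau,
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "degenerate": fit.degenerate,
                }
            )
    return pd.DataFrame(rows)


def export_heatmap(
    grid_results: pd.DataFrame,
    stratum: str,
    cost_scenario: CostScenario,
) -> pd.DataFrame:
    """Cost-effectiveness probability matrix: rows = HR, columns = UR.

    Cell values are the probability (across draws) of a positive incremental
    net benefit at the willingness-to-pay threshold.  Raises if any grid cell
    is missing, listing the absent (hr, ur) pairs.
    """
    sub = grid_results[
        (grid_results["stratum"] == stratum)
        & (grid_results["cost_mode"] == cost_scenario.mode)
        & (grid_results["cost_amount"] == cost_scenario.amount)
    ]
    if sub.empty:
        raise ValueError(f"no results for {stratum} / {cost_scenario.label}")
    table = sub.pivot(index="hr", columns="ur", values="prob_ce")
    missing = [
        (hr, ur)
        for hr in table.index
        for ur in table.columns
        if pd.isna(table.loc[hr, ur])
    ]
    if missing:
        raise ValueError(f"incomplete grid; missing cells: {missing}")
    return table.sort_index().sort_index(axis=1)
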