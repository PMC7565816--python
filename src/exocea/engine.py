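"""Vectorised probabilistic runs of the two-arm decision model.

Monte-Carlo draws of all uncertain parameters are propagated jointly: cycle
matrices are assembled per draw and per cycle, cohorts are iterated with one
batched matrix-vector product per cycle, and lifetime discounted costs and
QALYs come out as per-draw vectors.  Deterministic (point-estimate) runs are
the same code path with a single degenerate draw.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bundle import ParameterBundle, UNCERTAIN_PROBABILITIES
from .economics import (
    CostModel,
    Incremental,
    device_cost,
    incremental,
    CEOutcome,
    state_utilities,
)
from .markov import MAX_AGE, build_cycle_matrix_batch
from .psa import BetaDistribution, GammaDistribution
from .states import HealthState, N_STATES

__all__ = ["ParameterDraws", "sample_draws", "run_arm", "run_arms", "run_deterministic"]

_LIVING = [int(s) for s in HealthState if s is not HealthState.DEAD]


@dataclass
class ParameterDraws:
    """Per-draw parameter values (arrays of length ``n``)."""

    n: int
    transitions: object  # TransitionParameters with array-valued fields
    u_post_primary: np.ndarray
    u_fracture_year: np.ndarray
    state_costs: np.ndarray  # (n, 7)
    event_cost_shf: np.ndarray
    event_cost_major: np.ndarray


def _maybe_beta(mean: float, se: float, n: int, rng) -> np.ndarray:
    if se <= 0:
        return np.full(n, mean)
    return BetaDistribution(mean, se).sample(n, rng)


def _maybe_gamma(mean: float, se: float, n: int, rng) -> np.ndarray:
    if se <= 0 or mean <= 0:
        return np.full(n, mean)
    return GammaDistribution(mean, se).sample(n, rng)


def sample_draws(bundle: ParameterBundle, n: int, rng: np.random.Generator) -> ParameterDraws:
    """Draw ``n`` joint parameter samples (independent across parameters).

    Probabilities and utilities are beta, costs gamma, the comorbidity odds
    ratio lognormal.  Deterministic multipliers (age gradients, mortality
    multipliers) are not varied.
    """
    se = bundle.se
    tr = bundle.transitions
    prob_draws = {
        name: _maybe_beta(getattr(tr, name), se.get(name, 0.0), n, rng)
        for name in UNCERTAIN_PROBABILITIES
    }
    if bundle.or_dist is not None and bundle.or_dist.log_sd > 0:
        or_draws = bundle.or_dist.sample(n, rng)
    else:
        or_draws = np.full(n, tr.or_shf_comorbidity)
    transitions = replace(tr, or_shf_comorbidity=or_draws, **prob_draws)

    u_pp = _maybe_beta(bundle.utility.u_post_primary, se.get("u_post_primary", 0.0), n, rng)
    u_fr = _maybe_beta(bundle.utility.u_fracture_year, se.get("u_fracture_year", 0.0), n, rng)

    state_costs = np.zeros((n, N_STATES))
    for s in _LIVING:
        name = f"cost_{HealthState(s).name.lower()}"
        state_costs[:, s] = _maybe_gamma(
            float(bundle.cost.annual_state_costs[s]), se.get(name, 0.0), n, rng
        )
    ev_shf = _maybe_gamma(bundle.cost.event_cost_shf, se.get("event_cost_shf", 0.0), n, rng)
    ev_major = _maybe_gamma(
        bundle.cost.event_cost_major, se.get("event_cost_major", 0.0), n, rng
    )
    return ParameterDraws(
        n=n,
        transitions=transitions,
        u_post_primary=u_pp,
        u_fracture_year=u_fr,
        state_costs=state_costs,
        event_cost_shf=ev_shf,
        event_cost_major=ev_major,
    )


def _run_traces(draws: ParameterDraws, profile, arm: str, hr) -> np.ndarray:
    """Batched cohort occupancy, shape ``(n, cycles+1, 7)``."""
    cycles = max(int(MAX_AGE - profile.start_age), 1)
    occ = np.zeros((draws.n, cycles + 1, N_STATES))
    occ[:, 0, int(HealthState.POST_PRIMARY_HOME)] = 1.0
    for t in range(cycles):
        M = build_cycle_matrix_batch(draws.transitions, profile, arm, hr, t)
        occ[:, t + 1, :] = np.einsum("ni,nij->nj", occ[:, t, :], M)
    return occ


def run_arm(
    bundle: ParameterBundle,
    draws: ParameterDraws,
    arm: str,
    hr=1.0,
    ur=1.0,
    cost_model: CostModel | None = None,
):
    """Per-draw discounted lifetime (cost, qaly) for one arm.

    ``hr`` and ``ur`` may be scalars (threshold analysis) or per-draw arrays
    (base case / uncertainty analysis); both are ignored on the usual-care
    arm.
    """
    cost = bundle.cost if cost_model is None else cost_model
    disc = bundle.discount
    occ = _run_traces(draws, bundle.profile, arm, hr if arm == "exoskeleton" else 1.0)
    cycles = occ.shape[1] - 1
    occbar = 0.5 * (occ[:, :-1, :] + occ[:, 1:, :]) if disc.half_cycle else occ[:, :-1, :]
    w = disc.weights(cycles)

    U = state_utilities(
        bundle.utility,
        comorbidity=bundle.profile.comorbidity,
        arm=arm,
        exo_utility_ratio=ur,
        u_post_primary=draws.u_post_primary,
        u_fracture_year=draws.u_fracture_year,
    )
    qalys = np.einsum("t,ntj,nj->n", w, occbar, U)

    cvec = draws.state_costs.copy()
    cvec[:, HealthState.SHF_HOME] += draws.event_cost_shf
    cvec[:, HealthState.SHF_CAREHOME] += draws.event_cost_shf
    cvec[:, HealthState.MAJOR_NONHIP_HOME] += draws.event_cost_major
    cvec[:, HealthState.MAJOR_NONHIP_CAREHOME] += draws.event_cost_major
    costs = np.einsum("t,ntj,nj->n", w, occbar, cvec)
    if arm == "exoskeleton":
        alive = 1.0 - occ[:, :, HealthState.DEAD]
        costs = costs + np.array([device_cost(a, cost, disc) for a in alive])
    return costs, qalys


def run_arms(
    bundle: ParameterBundle,
    draws: ParameterDraws,
    hr,
    ur,
    cost_model: CostModel | None = None,
):
    """Both arms on the same draws; returns dict of per-draw cost/qaly arrays."""
    c_uc, q_uc = run_arm(bundle, draws, "usual_care", cost_model=cost_model)
    c_ex, q_ex = run_arm(bundle, draws, "exoskeleton", hr=hr, ur=ur, cost_model=cost_model)
    return {
        "cost_usual_care": c_uc,
        "qaly_usual_care": q_uc,
        "cost_exoskeleton": c_ex,
        "qaly_exoskeleton": q_ex,
    }


def run_deterministic(
    bundle: ParameterBundle,
    hr: float | None = None,
    ur: float | None = None,
    cost_model: CostModel | None = None,
) -> Incremental:
    """Point-estimate incremental result (single degenerate draw, no sampling)."""
    hr = bundle.hr_dist.median if hr is None else hr
    ur = bundle.ur_dist.median if ur is None else ur
    empty = ParameterBundle(
        profile=bundle.profile,
        transitions=bundle.transitions,
        utility=bundle.utility,
        cost=bundle.cost,
        discount=bundle.discount,
        lam=bundle.lam,
        hr_dist=bundle.hr_dist,
        ur_dist=bundle.ur_dist,
        or_dist=None,
        se={},
    )
    draws = sample_draws(empty, 1, np.random.default_rng(0))
    out = run_arms(empty, draws, hr, ur, cost_model=cost_model)
    exo = CEOutcome(float(out["cost_exoskeleton"][0]), float(out["qaly_exoskeleton"][0]), "exoskeleton")
    uc = CEOutcome(float(out["cost_usual_care"][0]), float(out["qaly_usual_care"][0]), "usual_care")
    return incremental(exo, uc)
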