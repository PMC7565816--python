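"""Lifetime costs, QALYs and cost-effectiveness summaries.

Traces from the Markov model are valued with a half-cycle-corrected,
discounted sum of per-state annual utilities and costs (NHS + personal social
services perspective, 2012/13 GBP, 3.5%/year discount on both costs and
QALYs).  Device costs are arm-specific: an annual leasing fee accrued per
life-year lived, or an irreversible purchase re-incurred every device lifespan
plus annual maintenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .states import HealthState, N_STATES, Trace

__all__ = [
    "UtilityModel",
    "CostModel",
    "DiscountSpec",
    "CEOutcome",
    "Incremental",
    "apply_utility_adjustments",
    "state_utilities",
    "lifetime_outcomes",
    "incremental",
    "is_cost_effective",
    "net_monetary_benefit",
    "percentile_ci",
    "check_convergence",
    "ConvergenceResult",
]

logger = logging.getLogger(__name__)

COMORBIDITY_UTILITY_MULTIPLIER = {"cvd": 0.96, "dementia": 0.74, "none": 1.0}

LEASING_FEES = (3000.0, 4000.0, 5000.0, 6000.0)
PURCHASE_PRICES = (12500.0, 15000.0, 17500.0, 20000.0)


def apply_utility_adjustments(base, comorbidity_multiplier=1.0, exo_utility_ratio=1.0):
    """Comorbidity- and intervention-adjusted utility, capped at 1.

    The raw product ``base * comorbidity_multiplier * exo_utility_ratio`` can
    exceed 1 (e.g. 0.66 x 0.96 x 1.70 = 1.077); utilities are capped at full
    health and the capping event is logged.
    """
    base = np.asarray(base, dtype=float)
    if np.any(base <= 0) or np.any(np.asarray(comorbidity_multiplier) <= 0) or np.any(
        np.asarray(exo_utility_ratio) <= 0
    ):
        raise ValueError("utilities and multipliers must be positive")
    raw = base * comorbidity_multiplier * exo_utility_ratio
    if np.any(raw > 1.0):
        logger.info(
            "utility capped at 1 (raw max %.4f)", float(np.max(raw))
        )
    out = np.minimum(raw, 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class UtilityModel:
    """Health-state utilities.

    ``u_post_primary`` (0.66) applies from the second year after any fracture;
    ``u_fracture_year`` (0.44) is shared by the SHF and major non-hip fracture
    tunnel states.  Comorbidity decrements are multiplicative (CVD 4%,
    dementia 26%); the exoskeleton's quality-of-life effect enters as a
    utility ratio (base case 1.70) on the intervention arm only.
    """

    u_post_primary: float = 0.66
    u_fracture_year: float = 0.44
    comorbidity_multiplier: dict = field(
        default_factory=lambda: dict(COMORBIDITY_UTILITY_MULTIPLIER)
    )
    exo_utility_ratio: float = 1.70


def state_utilities(
    utility: UtilityModel,
    comorbidity: str = "none",
    arm: str = "usual_care",
    exo_utility_ratio=None,
    u_post_primary=None,
    u_fracture_year=None,
) -> np.ndarray:
    """Per-state utility vector (shape ``(..., 7)``; dead = 0).

    Scalar model values can be overridden with per-draw arrays for vectorised
    probabilistic runs.
    """
    mult = utility.comorbidity_multiplier[comorbidity]
    ratio = 1.0
    if arm == "exoskeleton":
        ratio = (
            utility.exo_utility_ratio if exo_utility_ratio is None else exo_utility_ratio
        )
    u_pp = utility.u_post_primary if u_post_primary is None else u_post_primary
    u_fr = utility.u_fracture_year if u_fracture_year is None else u_fracture_year
    u_pp = np.asarray(apply_utility_adjustments(u_pp, mult, ratio))
    u_fr = np.asarray(apply_utility_adjustments(u_fr, mult, ratio))
    out = np.zeros(np.broadcast_shapes(u_pp.shape, u_fr.shape) + (N_STATES,))
    for s in HealthState:
        if s is HealthState.DEAD:
            continue
        out[..., int(s)] = u_fr if s.is_fracture_year else u_pp
    return out


@dataclass
class CostModel:
    """Annual state costs, fracture event costs and device cost scenario.

    ``annual_state_costs`` covers primary + secondary care (and care-home
    residence for carehome states); ``event_cost_shf`` / ``event_cost_major``
    are the hospitalisation costs of a new fracture, charged during the
    fracture (tunnel) year.  The device is costed either as an annual leasing
    fee or as an irreversible purchase re-incurred every ``device_lifespan``
    years with annual maintenance.
    """

    annual_state_costs: np.ndarray
    event_cost_shf: float
    event_cost_major: float
    exo_cost_mode: str = "leasing"
    leasing_fee: float = 6000.0
    purchase_price: float = 12500.0
    maintenance: float = 2500.0
    device_lifespan: int = 5

    def __post_init__(self) -> None:
        costs = np.asarray(self.annual_state_costs, dtype=float)
        if costs.shape[-1] != N_STATES:
            raise ValueError(f"annual_state_costs must have {N_STATES} entries")
        if np.any(costs < 0) or self.event_cost_shf < 0 or self.event_cost_major < 0:
            raise ValueError("costs must be non-negative")
        if self.exo_cost_mode not in ("leasing", "purchase"):
            raise ValueError(f"unknown cost mode {self.exo_cost_mode!r}")
        self.annual_state_costs = costs

    def state_cost_vector(self, annual_state_costs=None) -> np.ndarray:
        """Effective annual cost per state: state cost + fracture event cost."""
        costs = np.array(
            self.annual_state_costs if annual_state_costs is None else annual_state_costs,
            dtype=float,
        )
        costs[..., HealthState.SHF_HOME] += self.event_cost_shf
        costs[..., HealthState.SHF_CAREHOME] += self.event_cost_shf
        costs[..., HealthState.MAJOR_NONHIP_HOME] += self.event_cost_major
        costs[..., HealthState.MAJOR_NONHIP_CAREHOME] += self.event_cost_major
        return costs


@dataclass(frozen=True)
class DiscountSpec:
    """Annual discounting applied to both costs and QALYs (base 3.5%)."""

    rate: float = 0.035
    half_cycle: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("discount rate must be non-negative")

    def weights(self, cycles: int) -> np.ndarray:
        return (1.0 + self.rate) ** -np.arange(cycles, dtype=float)


@dataclass(frozen=True)
class CEOutcome:
    """Discounted lifetime cost (GBP) and QALYs for one arm."""

    cost: float
    qaly: float
    arm: str = "usual_care"


def _cycle_occupancy(trace: Trace, half_cycle: bool) -> np.ndarray:
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def device_cost(
    trace_alive: np.ndarray,
    cost: CostModel,
    disc: DiscountSpec,
) -> float:
    """Discounted exoskeleton cost for an alive-probability path.

    Leasing accrues per life-year lived (half-cycle corrected if enabled).
    Purchase is irreversible: the full price is charged at cycles 0, L, 2L,...
    weighted by the probability of being alive at the purchase epoch, with
    maintenance accruing annually while alive.
    """
    alive = np.asarray(trace_alive, dtype=float)
    cycles = alive.shape[0] - 1
    w = disc.weights(cycles)
    alive_bar = 0.5 * (alive[:-1] + alive[1:]) if disc.half_cycle else alive[:-1]
    if cost.exo_cost_mode == "leasing":
        return float(cost.leasing_fee * np.sum(w * alive_bar))
    epochs = np.arange(0, cycles, cost.device_lifespan)
    purchase = cost.purchase_price * np.sum(disc.weights(cycles)[epochs] * alive[epochs])
    maintenance = cost.maintenance * np.sum(w * alive_bar)
    return float(purchase + maintenance)


def lifetime_outcomes(
    trace: Trace,
    utility: UtilityModel,
    cost: CostModel,
    disc: DiscountSpec,
    arm: str = "usual_care",
    comorbidity: str = "none",
) -> CEOutcome:
    """Discounted lifetime cost and QALYs for one arm's trace.

    ``qaly = sum_t d(t) * u . occbar(t)`` and likewise for costs, where
    ``occbar`` is the (optionally half-cycle-corrected) occupancy and
    ``d(t) = (1 + rate)^-t``.  Device costs are added on the exoskeleton arm.
    """
    occbar = _cycle_occupancy(trace, disc.half_cycle)
    w = disc.weights(trace.cycles)
    u = state_utilities(utility, comorbidity=comorbidity, arm=arm)
    if np.any(u < 0):
        raise ValueError("negative utility after adjustment")
    qaly = float(np.sum(w * (occbar @ u)))
    c_vec = cost.state_cost_vector()
    total_cost = float(np.sum(w * (occbar @ c_vec)))
    if arm == "exoskeleton":
        total_cost += device_cost(trace.alive, cost, disc)
    return CEOutcome(cost=total_cost, qaly=qaly, arm=arm)


@dataclass(frozen=True)
class Incremental:
    """Incremental comparison of the exoskeleton vs usual care.

    ``flag`` is exactly one of ``'icer'`` (a meaningful ratio), ``'dominant'``
    (no more costly, more effective — or cheaper, no less effective),
    ``'dominated'`` (the mirror image) or ``'zero_effect'`` (identical
    outcomes).  ``icer`` is NaN unless ``flag == 'icer'``.
    """

    delta_cost: float
    delta_qaly: float
    icer: float
    flag: str


def incremental(exo: CEOutcome, uc: CEOutcome) -> Incremental:
    """Incremental cost, QALYs and ICER (or a dominance flag)."""
    dc = exo.cost - uc.cost
    de = exo.qaly - uc.qaly
    if dc == 0.0 and de == 0.0:
        return Incremental(dc, de, float("nan"), "zero_effect")
    if de >= 0.0 and dc <= 0.0:
        return Incremental(dc, de, float("nan"), "dominant")
    if de <= 0.0 and dc >= 0.0:
        return Incremental(dc, de, float("nan"), "dominated")
    return Incremental(dc, de, dc / de, "icer")


def is_cost_effective(incr: Incremental, lam: float = 20000.0) -> bool:
    """ICER-vs-threshold decision covering every quadrant.

    Cost-effective iff dominant, or the ICER is at or below ``lam`` with a
    QALY gain, or (QALY loss with savings) the savings per QALY forgone are at
    least ``lam``.  Dominated and zero-effect scenarios are never
    cost-effective.
    """
    if incr.flag == "dominant":
        return True
    if incr.flag in ("dominated", "zero_effect"):
        return False
    if incr.delta_qaly > 0:
        return incr.icer <= lam
    return incr.icer >= lam


def net_monetary_benefit(outcome, lam: float = 20000.0) -> float:
    """``lam * qaly - cost`` at willingness-to-pay ``lam`` (GBP/QALY)."""
    if lam <= 0:
        raise ValueError("willingness-to-pay must be positive")
    return float(lam * outcome.qaly - outcome.cost)


def percentile_ci(draws, level: float = 0.95):
    """Nonparametric percentile interval of a Monte-Carlo sample.

    Linear interpolation between order statistics (numpy's default
    ``'linear'`` method).  ``level=0.95`` returns the 2.5th and 97.5th
    empirical percentiles.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("empty sample")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail], method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class ConvergenceResult:
    """Monte-Carlo convergence diagnostic on a running-mean sequence."""

    n_required: int
    converged: bool


def check_convergence(
    cumulative_means,
    tolerance: float = 0.005,
    stability_fraction: float = 0.5,
) -> ConvergenceResult:
    """Smallest n after which all running means stay near the final mean.

    The sequence is a running mean over draws; convergence at n means every
    later running mean stays within ``tolerance`` (relative; absolute if the
    final mean is 0) of the final value.  Because the tail of any finite
    sequence trivially hugs its own endpoint, the estimate is flagged
    not-converged when stabilisation only occurs in the last
    ``1 - stability_fraction`` share of the draws.
    """
    means = np.asarray(cumulative_means, dtype=float)
    if means.size == 0:
        raise ValueError("empty sequence")
    final = means[-1]
    scale = abs(final) if final != 0 else 1.0
    within = np.abs(means - final) <= tolerance * scale
    # smallest index from which the band holds through the end
    ok_tail = np.flip(np.logical_and.accumulate(np.flip(within)))
    n_required = int(np.argmax(ok_tail)) + 1
    converged = n_required <= max(1, int(np.ceil(stability_fraction * means.size)))
    return ConvergenceResult(n_required=n_required, converged=converged)
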