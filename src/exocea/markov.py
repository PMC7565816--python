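"""Transition structure of the hip-fracture natural-history model.

Annual-cycle Markov model with competing events per cycle.  From a
post-primary state a patient may suffer a second hip fracture (SHF), a major
non-hip fracture, be admitted to a care home, die, or remain as they are.  A
new fracture routes the patient through a one-year "tunnel" state; each
fracture event carries a 30-day mortality applied multiplicatively within the
cycle (event probability x death-given-event goes straight to the dead state).
Occupants of a tunnel state return to the post-primary state of the same
setting after one cycle unless they die or move to a care home.  Care-home
admission is absorbing with respect to setting: the six carehome-to-home
entries are structural zeros.

The exoskeleton arm reduces the SHF probability through a hazard ratio applied
on the rate scale, ``1 - (1 - p)**hr``.  Comorbidity (CVD, dementia) raises the
SHF probability through an odds ratio applied on the odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .states import CohortProfile, HealthState, N_STATES, Trace

__all__ = [
    "TransitionParameters",
    "adjust_probability_by_or",
    "apply_hazard_ratio",
    "build_cycle_matrix",
    "build_cycle_matrix_batch",
    "run_cohort",
    "simulate_cohort",
]

#: Probabilities are clamped below this after age scaling.
P_MAX = 0.99
#: Age (years) at which simulation stops; effectively a lifetime horizon.
MAX_AGE = 100
#: Living-occupancy threshold below which further cycles are immaterial.
LIVING_EPS = 1e-6

_ROW_TOL = 1e-9


def adjust_probability_by_or(p, odds_ratio):
    """Update an annual probability with an odds ratio.

    Converts ``p`` to odds, multiplies by ``odds_ratio`` and converts back:
    ``or*p / (1 - p + or*p)``.  Used to raise the second-hip-fracture risk of
    the dementia (OR 1.89) and CVD (OR 1.32) subpopulations relative to the
    non-comorbid baseline.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1) (odds undefined at 1)")
    if np.any(np.asarray(odds_ratio) <= 0):
        raise ValueError("odds ratio must be positive")
    out = odds_ratio * p / (1.0 - p + odds_ratio * p)
    return float(out) if out.ndim == 0 else out


def apply_hazard_ratio(p, hr):
    """Apply a hazard ratio to an annual probability on the rate scale.

    The annual probability is converted to a constant rate, scaled by ``hr``
    and converted back: ``1 - (1 - p)**hr``.  This is how the exoskeleton's
    25% reduction in falls leading to SHFs (HR 0.75) enters the model.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("probability must lie in [0, 1)")
    if np.any(np.asarray(hr) <= 0):
        raise ValueError("hazard ratio must be positive")
    out = 1.0 - np.power(1.0 - p, hr)
    return float(out) if out.ndim == 0 else out


@dataclass
class TransitionParameters:
    """Annual transition probabilities for one stratum.

    Event probabilities are stored at ``reference_age`` and scaled
    multiplicatively per decade of attained age (``age_gradient_events`` for
    fractures and care-home admission, ``age_gradient_mortality`` for
    background mortality), then clamped to ``[0, P_MAX]``.

    ``p_death30`` is the probability of dying within 30 days of a fracture
    event (already adjusted for the stratum's Charlson Comorbidity Index);
    ``or_shf_comorbidity`` multiplies the odds of a second hip fracture
    (1.89 for dementia, 1.32 for CVD, 1.0 for no comorbidity).
    """

    reference_age: float
    p_shf_home: float
    p_shf_carehome: float
    p_major: float
    p_carehome: float
    p_carehome_postfracture: float
    p_death30: float
    p_death: float
    mort_mult_fracture_year: float = 1.5
    mort_mult_carehome: float = 1.8
    or_shf_comorbidity: float = 1.0
    age_gradient_events: float = 1.9
    age_gradient_mortality: float = 2.3

    def __post_init__(self) -> None:
        for name in (
            "p_shf_home",
            "p_shf_carehome",
            "p_major",
            "p_carehome",
            "p_carehome_postfracture",
            "p_death30",
            "p_death",
        ):
            v = getattr(self, name)
            if not (np.all(np.asarray(v) >= 0) and np.all(np.asarray(v) <= 1)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if np.any(np.asarray(self.or_shf_comorbidity) <= 0):
            raise ValueError("odds ratio must be positive")

    def _events_at(self, p, age):
        scale = self.age_gradient_events ** ((age - self.reference_age) / 10.0)
        return np.clip(np.asarray(p, dtype=float) * scale, 0.0, P_MAX)

    def _mortality_at(self, age, multiplier=1.0):
        scale = self.age_gradient_mortality ** ((age - self.reference_age) / 10.0)
        return np.clip(
            np.asarray(self.p_death, dtype=float) * scale * multiplier, 0.0, P_MAX
        )


def _assemble_matrices(
    q_shf_home,
    q_shf_care,
    q_major,
    d30,
    m_home,
    m_frac_home,
    m_care,
    m_frac_care,
    c_plain,
    c_post,
):
    """Assemble row-stochastic cycle matrices from per-draw probability arrays.

    All arguments broadcast to a common shape ``(n,)``; returns ``(n, 7, 7)``.
    Row sums are exact by construction (residual mass is a complement); a
    final check guards against probability leakage from invalid inputs.
    """
    args = np.broadcast_arrays(
        *(
            np.atleast_1d(np.asarray(a, dtype=float))
            for a in (
                q_shf_home,
                q_shf_care,
                q_major,
                d30,
                m_home,
                m_frac_home,
                m_care,
                m_frac_care,
                c_plain,
                c_post,
            )
        )
    )
    (q1h, q1c, q2, d30, mh, mfh, mc, mfc, cp, cpost) = args
    n = q1h.shape[0]
    M = np.zeros((n, N_STATES, N_STATES))

    S = HealthState

    def _post_primary_row(row_state, q1, q2, m, setting_care):
        # Competing events: SHF / major fracture are exclusive; survivors of a
        # fracture enter the tunnel state of the same setting.  Patients with
        # no new fracture face background mortality, then (home only) possible
        # care-home admission.
        tot = q1 + q2
        over = tot > 0.98
        if np.any(over):
            shrink = np.where(over, 0.98 / np.maximum(tot, 1e-300), 1.0)
            q1, q2 = q1 * shrink, q2 * shrink
            tot = q1 + q2
        rest = 1.0 - tot
        i = int(row_state)
        if setting_care:
            M[:, i, S.SHF_CAREHOME] = q1 * (1.0 - d30)
            M[:, i, S.MAJOR_NONHIP_CAREHOME] = q2 * (1.0 - d30)
            M[:, i, S.DEAD] = tot * d30 + rest * m
            M[:, i, i] = rest * (1.0 - m)
        else:
            M[:, i, S.SHF_HOME] = q1 * (1.0 - d30)
            M[:, i, S.MAJOR_NONHIP_HOME] = q2 * (1.0 - d30)
            M[:, i, S.DEAD] = tot * d30 + rest * m
            M[:, i, S.POST_PRIMARY_CAREHOME] = rest * (1.0 - m) * cp
            M[:, i, i] = rest * (1.0 - m) * (1.0 - cp)

    def _tunnel_row(row_state, m, setting_care):
        # Fracture-year tunnel: die, move to (or stay in) care home, or return
        # to the post-primary state of the same setting.
        i = int(row_state)
        M[:, i, S.DEAD] = m
        if setting_care:
            M[:, i, S.POST_PRIMARY_CAREHOME] = 1.0 - m
        else:
            M[:, i, S.POST_PRIMARY_CAREHOME] = (1.0 - m) * cpost
            M[:, i, S.POST_PRIMARY_HOME] = (1.0 - m) * (1.0 - cpost)

    _post_primary_row(S.POST_PRIMARY_HOME, q1h, q2, mh, setting_care=False)
    _tunnel_row(S.SHF_HOME, mfh, setting_care=False)
    _tunnel_row(S.MAJOR_NONHIP_HOME, mfh, setting_care=False)
    _post_primary_row(S.POST_PRIMARY_CAREHOME, q1c, q2, mc, setting_care=True)
    _tunnel_row(S.SHF_CAREHOME, mfc, setting_care=True)
    _tunnel_row(S.MAJOR_NONHIP_CAREHOME, mfc, setting_care=True)
    M[:, S.DEAD, S.DEAD] = 1.0

    rows = M.sum(axis=2)
    if np.any(np.abs(rows - 1.0) > _ROW_TOL):
        raise ValueError("constructed cycle matrix is not row-stochastic")
    return M


def build_cycle_matrix_batch(
    params: TransitionParameters,
    profile: CohortProfile,
    arm: str,
    hr,
    cycle_index: int,
):
    """Vectorised cycle-matrix construction.

    ``params`` fields and ``hr`` may be scalars or per-draw arrays; returns a
    ``(n, 7, 7)`` stack of row-stochastic matrices for the cohort's attained
    age at ``cycle_index``.
    """
    if arm not in ("usual_care", "exoskeleton"):
        raise ValueError(f"unknown arm {arm!r}")
    age = profile.start_age + cycle_index
    q_shf_home = adjust_probability_by_or(
        params._events_at(params.p_shf_home, age), params.or_shf_comorbidity
    )
    q_shf_care = adjust_probability_by_or(
        params._events_at(params.p_shf_carehome, age), params.or_shf_comorbidity
    )
    if arm == "exoskeleton":
        q_shf_home = apply_hazard_ratio(q_shf_home, hr)
        q_shf_care = apply_hazard_ratio(q_shf_care, hr)
    q_major = params._events_at(params.p_major, age)
    return _assemble_matrices(
        q_shf_home,
        q_shf_care,
        q_major,
        np.asarray(params.p_death30, dtype=float),
        params._mortality_at(age),
        params._mortality_at(age, params.mort_mult_fracture_year),
        params._mortality_at(age, params.mort_mult_carehome),
        params._mortality_at(
            age, params.mort_mult_carehome * params.mort_mult_fracture_year
        ),
        params._events_at(params.p_carehome, age),
        params._events_at(params.p_carehome_postfracture, age),
    )


def build_cycle_matrix(
    params: TransitionParameters,
    profile: CohortProfile,
    arm: str = "usual_care",
    hr: float = 1.0,
    cycle_index: int = 0,
) -> np.ndarray:
    """Single 7x7 row-stochastic cycle matrix for one stratum, arm and cycle."""
    return build_cycle_matrix_batch(params, profile, arm, hr, cycle_index)[0]


def run_cohort(
    initial_state: HealthState,
    matrices_per_cycle: Sequence[np.ndarray],
    horizon: int | None = None,
) -> Trace:
    """Iterate a cohort forward through per-cycle transition matrices.

    ``matrices_per_cycle`` is a sequence of 7x7 matrices (one per cycle, or a
    single matrix reused when ``horizon`` is given).  The returned trace has
    ``occupancy[0]`` equal to the unit vector on ``initial_state`` and
    ``occupancy[t] = occupancy[t-1] @ M_t``.
    """
    if initial_state == HealthState.DEAD:
        raise ValueError("initial state must be a living state")
    mats = np.asarray(matrices_per_cycle, dtype=float)
    if mats.ndim == 2:
        if horizon is None or horizon < 1:
            raise ValueError("horizon >= 1 required with a single matrix")
        mats = np.broadcast_to(mats, (horizon, N_STATES, N_STATES))
    if mats.ndim != 3 or mats.shape[1:] != (N_STATES, N_STATES):
        raise ValueError("matrices must be (cycles, 7, 7) or (7, 7)")
    if horizon is not None and mats.shape[0] != horizon:
        mats = mats[:horizon]
    if np.any(np.abs(mats.sum(axis=2) - 1.0) > _ROW_TOL) or np.any(mats < 0):
        raise ValueError("non-stochastic transition matrix")

    occ = np.zeros((mats.shape[0] + 1, N_STATES))
    occ[0, int(initial_state)] = 1.0
    for t in range(mats.shape[0]):
        occ[t + 1] = occ[t] @ mats[t]
    return Trace(occ)


def simulate_cohort(
    params: TransitionParameters,
    profile: CohortProfile,
    arm: str = "usual_care",
    hr: float = 1.0,
    initial_state: HealthState = HealthState.POST_PRIMARY_HOME,
) -> Trace:
    """Simulate one stratum from its start age to the lifetime horizon.

    Cycles run until attained age ``MAX_AGE`` or until living occupancy drops
    below ``LIVING_EPS``, whichever comes first.
    """
    max_cycles = max(int(MAX_AGE - profile.start_age), 1)
    occ = np.zeros((max_cycles + 1, N_STATES))
    occ[0, int(initial_state)] = 1.0
    used = 0
    for t in range(max_cycles):
        M = build_cycle_matrix(params, profile, arm, hr, cycle_index=t)
        occ[t + 1] = occ[t] @ M
        used = t + 1
        if 1.0 - occ[t + 1, HealthState.DEAD] < LIVING_EPS:
            break
    return Trace(occ[: used + 1])
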