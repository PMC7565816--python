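"""One stratum's complete parameter set for the decision model.

A :class:`ParameterBundle` carries everything needed to simulate both arms for
one cohort profile: transition probabilities, utilities, costs, discounting,
the willingness-to-pay threshold, the exoskeleton effect distributions and the
standard errors that drive the probabilistic sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .economics import CostModel, DiscountSpec, UtilityModel
from .markov import TransitionParameters
from .psa import EffectDistribution, base_case_hr_distribution, base_case_ur_distribution
from .states import CohortProfile

__all__ = ["ParameterBundle", "UNCERTAIN_PROBABILITIES", "UNCERTAIN_UTILITIES"]

#: TransitionParameters fields treated as uncertain (beta-distributed in PSA).
UNCERTAIN_PROBABILITIES = (
    "p_shf_home",
    "p_shf_carehome",
    "p_major",
    "p_carehome",
    "p_carehome_postfracture",
    "p_death30",
    "p_death",
)
UNCERTAIN_UTILITIES = ("u_post_primary", "u_fracture_year")


@dataclass
class ParameterBundle:
    """All model parameters for one stratum (age, sex, comorbidity).

    ``se`` maps uncertain parameter names (transition probabilities,
    utilities, ``cost_<state>`` annual costs, ``event_cost_shf``/``_major``)
    to standard errors; ``or_dist`` is the lognormal for the comorbidity odds
    ratio on second hip fracture; ``hr_dist``/``ur_dist`` are the base-case
    exoskeleton effect distributions.
    """

    profile: CohortProfile
    transitions: TransitionParameters
    utility: UtilityModel
    cost: CostModel
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    lam: float = 20000.0
    hr_dist: EffectDistribution = field(default_factory=base_case_hr_distribution)
    ur_dist: EffectDistribution = field(default_factory=base_case_ur_distribution)
    or_dist: EffectDistribution | None = None
    se: dict = field(default_factory=dict)

    def with_cost_model(self, cost: CostModel) -> "ParameterBundle":
        return replace(self, cost=cost)
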