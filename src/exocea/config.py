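"""YAML round-trip of parameter bundles.

A configuration file carries one nested section per stratum, so a run driven
by synthetic parameters and a run driven by user-supplied parameters are the
same code path.  Files written from synthetic bundles carry a provenance note
in their header so their outputs cannot be mistaken for estimates derived
from real cohort data.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import yaml

from .bundle import ParameterBundle
from .economics import CostModel, DiscountSpec, UtilityModel
from .markov import TransitionParameters
from .psa import EffectDistribution
from .states import CohortProfile, HealthState

__all__ = [
    "bundle_to_dict",
    "bundle_from_dict",
    "save_bundles",
    "load_bundles",
]

SYNTHETIC_NOTE = (
    "synthetic stand-in parameters generated by exocea.synthetic; "
    "not estimates from patient-level data"
)


def _dist_to_dict(dist: EffectDistribution | None):
    if dist is None:
        return None
    return {"median": float(dist.median), "log_sd": float(dist.log_sd)}


def _dist_from_dict(d):
    if d is None:
        return None
    return EffectDistribution(median=float(d["median"]), log_sd=float(d["log_sd"]))


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    cost = asdict(bundle.cost)
    cost["annual_state_costs"] = {
        s.name.lower(): float(bundle.cost.annual_state_costs[int(s)]) for s in HealthState
    }
    return {
        "profile": asdict(bundle.profile),
        "transitions": {k: float(v) for k, v in asdict(bundle.transitions).items()},
        "utility": asdict(bundle.utility),
        "cost": cost,
        "discount": asdict(bundle.discount),
        "lam": float(bundle.lam),
        "hr_dist": _dist_to_dict(bundle.hr_dist),
        "ur_dist": _dist_to_dict(bundle.ur_dist),
        "or_dist": _dist_to_dict(bundle.or_dist),
        "se": {k: float(v) for k, v in bundle.se.items()},
    }


def bundle_from_dict(d: dict) -> ParameterBundle:
    cost_d = dict(d["cost"])
    costs = np.zeros(len(HealthState))
    for s in HealthState:
        costs[int(s)] = cost_d["annual_state_costs"][s.name.lower()]
    cost_d["annual_state_costs"] = costs
    return ParameterBundle(
        profile=CohortProfile(**d["profile"]),
        transitions=TransitionParameters(**d["transitions"]),
        utility=UtilityModel(**d["utility"]),
        cost=CostModel(**cost_d),
        discount=DiscountSpec(**d["discount"]),
        lam=float(d["lam"]),
        hr_dist=_dist_from_dict(d["hr_dist"]),
        ur_dist=_dist_from_dict(d["ur_dist"]),
        or_dist=_dist_from_dict(d.get("or_dist")),
        se=dict(d.get("se", {})),
    )


def save_bundles(bundles: dict, path, note: str | None = SYNTHETIC_NOTE) -> None:
    """Write a dict of stratum label -> bundle as one YAML file."""
    doc = {"note": note, "strata": {label: bundle_to_dict(b) for label, b in bundles.items()}}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_bundles(path) -> dict:
    """Read a configuration file back into {stratum label: ParameterBundle}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return {label: bundle_from_dict(d) for label, d in doc["strata"].items()}
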