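"""Expected value of perfect information (EVPI).

Per-person EVPI is the expected opportunity loss of deciding under current
uncertainty: the mean over probabilistic draws of the best achievable net
monetary benefit, minus the net benefit of the strategy that is best on
average.  Population EVPI scales this by the cumulative number of incident
patients affected by the decision over a 10-year horizon (undiscounted simple
product; discounting of future cohorts is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VOIResult", "evpi_per_person", "population_evpi"]


@dataclass(frozen=True)
class VOIResult:
    """Per-person and population-level EVPI for one stratum/cost scenario."""

    evpi_per_person: float
    population_size_10yr: float
    population_evpi: float


def evpi_per_person(nmb_draws) -> float:
    """EVPI from a (draws x arms) matrix of net monetary benefit.

    ``E[max_arm NMB] - max_arm E[NMB]``; non-negative by Jensen's inequality
    (tiny negative floating-point residue is clamped to 0).
    """
    nmb = np.asarray(nmb_draws, dtype=float)
    if nmb.ndim != 2:
        raise ValueError("nmb_draws must be a (draws, arms) matrix")
    if nmb.shape[0] < 1 or nmb.shape[1] < 2:
        raise ValueError("need at least 1 draw and 2 arms")
    if not np.all(np.isfinite(nmb)):
        raise ValueError("non-finite net-benefit entries")
    value = float(np.mean(np.max(nmb, axis=1)) - np.max(np.mean(nmb, axis=0)))
    return max(value, 0.0)


def population_evpi(evpi: float, incidence_counts, discount_rate: float = 0.0) -> float:
    """Scale per-person EVPI by cumulative incident patients.

    ``incidence_counts`` are annual incident-patient counts over the decision
    horizon (10 values for the 10-year base case).  The default is a simple
    undiscounted product; ``discount_rate > 0`` discounts future cohorts.
    """
    counts = np.asarray(incidence_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("incidence counts must be non-negative")
    if evpi < 0:
        raise ValueError("EVPI must be non-negative")
    if discount_rate > 0:
        weights = (1.0 + discount_rate) ** -np.arange(counts.size, dtype=float)
        return float(evpi * np.sum(counts * weights))
    return float(evpi * np.sum(counts))
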