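"""Health-state space and cohort bookkeeping for the hip-fracture Markov model.

The natural history of a patient with a primary hip fracture is described by
seven states: living states cross a clinical status (post-primary fracture,
second hip fracture [SHF] year, major non-hip fracture year) with a residential
setting (own home vs care home), plus an absorbing death state.  Care-home
admission is one-way: there are no transitions back to any home state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd

__all__ = ["HealthState", "CohortProfile", "Trace", "LIVING_STATES"]


class HealthState(IntEnum):
    """The seven-state natural-history state space (annual cycles)."""

    POST_PRIMARY_HOME = 0
    SHF_HOME = 1
    MAJOR_NONHIP_HOME = 2
    POST_PRIMARY_CAREHOME = 3
    SHF_CAREHOME = 4
    MAJOR_NONHIP_CAREHOME = 5
    DEAD = 6

    @property
    def is_carehome(self) -> bool:
        return self in (
            HealthState.POST_PRIMARY_CAREHOME,
            HealthState.SHF_CAREHOME,
            HealthState.MAJOR_NONHIP_CAREHOME,
        )

    @property
    def is_fracture_year(self) -> bool:
        """True for the tunnel states occupied during the year of a new fracture."""
        return self in (
            HealthState.SHF_HOME,
            HealthState.MAJOR_NONHIP_HOME,
            HealthState.SHF_CAREHOME,
            HealthState.MAJOR_NONHIP_CAREHOME,
        )


N_STATES = len(HealthState)
LIVING_STATES = tuple(s for s in HealthState if s is not HealthState.DEAD)

#: Pairs (carehome_state, home_state) that must carry exactly zero probability.
CAREHOME_TO_HOME = tuple(
    (c, h)
    for c in HealthState
    if c.is_carehome
    for h in HealthState
    if not h.is_carehome and h is not HealthState.DEAD
)


@dataclass(frozen=True)
class CohortProfile:
    """A simulated stratum: starting age, sex and comorbidity.

    ``comorbidity='none'`` is a non-comorbid baseline used for testing; the
    analysis proper targets the CVD and dementia subpopulations.  The Charlson
    Comorbidity Index score enters the 30-day post-fracture mortality; both
    comorbid groups are assigned a score of 2.2.
    """

    start_age: int
    sex: str
    comorbidity: str = "none"
    cci_score: float = 2.2

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.comorbidity not in ("cvd", "dementia", "none"):
            raise ValueError(f"unknown comorbidity {self.comorbidity!r}")
        if self.cci_score <= 0:
            raise ValueError("cci_score must be positive")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.comorbidity}_{self.start_age}"


@dataclass
class Trace:
    """Cohort occupancy over annual cycles.

    ``occupancy[t, s]`` is the probability of being in state ``s`` at the start
    of cycle ``t``; row 0 is the initial distribution.  A trace with ``cycles``
    annual cycles has ``cycles + 1`` rows.
    """

    occupancy: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"occupancy must be (cycles+1, {N_STATES})")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError("occupancy entries must lie in [0, 1]")
        sums = occ.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-12):
            raise ValueError("occupancy rows must each sum to 1")
        dead = occ[:, HealthState.DEAD]
        if np.any(np.diff(dead) < -1e-12):
            raise ValueError("dead occupancy must be non-decreasing")
        self.occupancy = occ

    @property
    def cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        """Probability of being alive at the start of each cycle."""
        return 1.0 - self.occupancy[:, HealthState.DEAD]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.occupancy,
            columns=[s.name.lower() for s in HealthState],
            index=pd.RangeIndex(self.occupancy.shape[0], name="cycle"),
        )

    def to_csv(self, path) -> None:
        """One row per cycle, one column per state, header = state labels."""
        self.to_frame().to_csv(path)
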