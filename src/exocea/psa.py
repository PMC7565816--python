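"""Probabilistic distributions and seeded Monte-Carlo sampling.

Standard health-technology-assessment families: beta for probabilities and
utilities (method of moments from mean and standard error), gamma for costs,
lognormal for ratio parameters (hazard ratio, odds ratios, utility ratio).

The exoskeleton's effects are elicited quantities.  The hazard ratio of
falling is lognormal with median 0.75 and a log-scale standard deviation of
40% of |ln 0.75|, which places its 95% interval at (0.60, 0.94).  The
utility-ratio is lognormal with median 1.70; its log-scale SD defaults to the
value that gives the interval width (1.46, 1.93) on the log scale, about
0.0712 — the "40% inflation" description of this uncertainty does not pin
down a unique scale, so the SD is exposed as configuration (see the methods
note).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EffectDistribution",
    "BetaDistribution",
    "GammaDistribution",
    "PSASpec",
    "base_case_hr_distribution",
    "base_case_ur_distribution",
    "lognormal_from_ci",
    "hr_se_to_log_sd",
    "ur_se_to_log_sd",
    "draw",
    "scenario_seed",
]

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class EffectDistribution:
    """Lognormal distribution for a ratio parameter, parameterised by median.

    ``log_sd = 0`` degenerates to a point mass at the median.
    """

    median: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError("median must be positive")
        if self.log_sd < 0:
            raise ValueError("log_sd must be non-negative")

    def ppf(self, q) -> float:
        if self.log_sd == 0:
            return self.median * np.ones_like(np.asarray(q, dtype=float))
        out = np.exp(np.log(self.median) + self.log_sd * stats.norm.ppf(q))
        return float(out) if np.ndim(out) == 0 else out

    def ci(self, level: float = 0.95):
        tail = (1.0 - level) / 2.0
        return float(np.atleast_1d(self.ppf(tail))[0]), float(
            np.atleast_1d(self.ppf(1.0 - tail))[0]
        )

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.log_sd == 0:
            return np.full(n, self.median)
        return rng.lognormal(mean=np.log(self.median), sigma=self.log_sd, size=n)


@dataclass(frozen=True)
class BetaDistribution:
    """Beta distribution from mean and standard error (method of moments)."""

    mean: float
    se: float
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        m, s = self.mean, self.se
        if not 0 < m < 1:
            raise ValueError("beta mean must lie in (0, 1)")
        if s <= 0 or s * s >= m * (1 - m):
            raise ValueError("beta SE must satisfy se^2 < mean(1-mean)")
        nu = m * (1 - m) / (s * s) - 1.0
        object.__setattr__(self, "alpha", m * nu)
        object.__setattr__(self, "beta", (1 - m) * nu)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.beta(self.alpha, self.beta, size=n)


@dataclass(frozen=True)
class GammaDistribution:
    """Gamma distribution from mean and standard error (method of moments)."""

    mean: float
    se: float
    shape: float = field(init=False)
    scale: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mean <= 0 or self.se <= 0:
            raise ValueError("gamma mean and SE must be positive")
        object.__setattr__(self, "shape", (self.mean / self.se) ** 2)
        object.__setattr__(self, "scale", self.se**2 / self.mean)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.gamma(self.shape, self.scale, size=n)


@dataclass(frozen=True)
class PSASpec:
    """Monte-Carlo settings for a probabilistic sensitivity analysis.

    The base case uses 1000 draws (the model's running means of cost and QALY
    stabilise by then; see ``economics.check_convergence``).
    """

    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def base_case_hr_distribution() -> EffectDistribution:
    """Elicited hazard ratio of falls leading to SHF: median 0.75, log-SD 40% of |ln 0.75|."""
    median = 0.75
    return EffectDistribution(median=median, log_sd=0.40 * abs(np.log(median)))


def base_case_ur_distribution() -> EffectDistribution:
    """Elicited utility-ratio: median 1.70, log-SD matching a (1.46, 1.93) interval width."""
    log_sd = (np.log(1.93) - np.log(1.46)) / (2.0 * Z975)
    return EffectDistribution(median=1.70, log_sd=float(log_sd))


def lognormal_from_ci(lo: float, hi: float) -> EffectDistribution:
    """Lognormal with the given central 95% interval (median = geometric midpoint)."""
    if not 0 < lo < hi:
        raise ValueError("need 0 < lo < hi")
    log_sd = (np.log(hi) - np.log(lo)) / (2.0 * Z975)
    median = float(np.sqrt(lo * hi))
    return EffectDistribution(median=median, log_sd=float(log_sd))


def hr_se_to_log_sd(se: float) -> float:
    """Hazard-ratio uncertainty-grid value -> log-scale SD.

    Grid values 1.05..1.40 are read as multiplicative standard errors, so
    ``log_sd = ln(se)``; 1.0 means no uncertainty.
    """
    if se < 1.0:
        raise ValueError("multiplicative SE must be >= 1")
    return float(np.log(se))


def ur_se_to_log_sd(se: float, median: float) -> float:
    """Utility-ratio uncertainty-grid value -> log-scale SD.

    Grid values 0.25..2.5 are read as natural-scale standard errors and
    converted through the lognormal moment relation
    ``log_sd = sqrt(ln(1 + (se/median)^2))``; 0 means no uncertainty.
    """
    if se < 0 or median <= 0:
        raise ValueError("need se >= 0 and median > 0")
    return float(np.sqrt(np.log1p((se / median) ** 2)))


def draw(dist, n: int, seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Seeded, reproducible sample of size ``n`` from any distribution above."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    return dist.sample(n, rng)


def scenario_seed(master_seed: int, *tokens) -> int:
    """Stable per-scenario seed derived from the master seed and identifiers.

    Hashing (rather than a running counter) makes every scenario's stream
    independent of which other scenarios run, and of execution order.  The
    result is a non-negative 31-bit integer.
    """
    h = hashlib.sha256(repr((int(master_seed),) + tuple(tokens)).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
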