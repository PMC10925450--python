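"""Model constants and probabilistic parameter specifications.

The model is parameterised by two static prevalences (baseline opioid
misuse among U.S. young adults, baseline past-year anxiety), two
hypothetical risk ratios used by the exploratory scenarios, and two
probabilistic parameters propagated through the Monte Carlo run:

* the odds ratio for opioid misuse given fire-related anxiety, modelled
  as a lognormal distribution, and
* the post-wildfire anxiety prevalence, modelled as a beta distribution.

Published lognormal parameterisations are ambiguous: "mean m, sd s" may
refer to the natural scale or the log scale.  The default here treats
them as natural-scale moments and inverts them in closed form
(:func:`lognormal_from_moments`); the log-scale reading is available via
``dialect="log_scale"`` for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "DistributionSpec",
    "ModelParameters",
    "ParameterDraw",
    "lognormal_from_moments",
    "beta_moments",
    "sample_draw",
    "sample_draws",
]

SCENARIOS = ("S1", "S2", "S3")


def lognormal_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Convert natural-scale mean/sd of a lognormal to (mu, sigma) on the log scale.

    Closed-form inversion: ``sigma^2 = ln(1 + sd^2/mean^2)`` and
    ``mu = ln(mean) - sigma^2/2``.  The ``sd -> 0`` limit degenerates to a
    point mass at ``mean`` (``sigma -> 0``, ``mu -> ln(mean)``).

    Parameters
    ----------
    mean, sd
        Natural-scale mean (> 0) and standard deviation (>= 0).

    Returns
    -------
    (mu, sigma)
        Log-scale location and scale of the matching lognormal.
    """
    if mean <= 0:
        raise ValueError(f"lognormal mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"lognormal sd must be non-negative, got {sd}")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def beta_moments(alpha: float, beta: float) -> tuple[float, float]:
    """Mean and standard deviation of a Beta(alpha, beta) distribution."""
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"beta shape parameters must be positive, got ({alpha}, {beta})")
    s = alpha + beta
    mean = alpha / s
    var = alpha * beta / (s * s * (s + 1.0))
    return mean, math.sqrt(var)


@dataclass(frozen=True)
class DistributionSpec:
    """Specification of one probabilistic model input.

    ``family`` is one of ``"lognormal"`` (``a`` = mean, ``b`` = sd, with
    ``dialect`` selecting whether those are natural- or log-scale),
    ``"beta"`` (``a`` = alpha, ``b`` = beta) or ``"point"`` (``a`` = the
    constant; ``b`` unused), the last being the degenerate case used for
    what-if runs with one parameter pinned.
    """

    family: str
    a: float
    b: float = 0.0
    dialect: str = "natural_moments"

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "beta", "point"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "lognormal":
            if self.dialect not in ("natural_moments", "log_scale"):
                raise ValueError(f"unknown lognormal dialect {self.dialect!r}")
            if self.dialect == "natural_moments" and (self.a <= 0 or self.b < 0):
                raise ValueError("natural-scale lognormal needs mean > 0 and sd >= 0")
            if self.dialect == "log_scale" and self.b < 0:
                raise ValueError("log-scale lognormal needs sigma >= 0")
        elif self.family == "beta":
            if self.a <= 0 or self.b <= 0:
                raise ValueError("beta needs alpha > 0 and beta > 0")
        elif self.family == "point":
            if not np.isfinite(self.a):
                raise ValueError("point mass needs a finite value")

    def log_params(self) -> tuple[float, float]:
        """(mu, sigma) on the log scale; lognormal family only."""
        if self.family != "lognormal":
            raise ValueError("log_params is defined for the lognormal family only")
        if self.dialect == "log_scale":
            return self.a, self.b
        return lognormal_from_moments(self.a, self.b)

    def mean(self) -> float:
        if self.family == "point":
            return self.a
        if self.family == "beta":
            return beta_moments(self.a, self.b)[0]
        mu, sigma = self.log_params()
        return math.exp(mu + sigma * sigma / 2.0)

    def sd(self) -> float:
        if self.family == "point":
            return 0.0
        if self.family == "beta":
            return beta_moments(self.a, self.b)[1]
        mu, sigma = self.log_params()
        m = math.exp(mu + sigma * sigma / 2.0)
        return m * math.sqrt(math.expm1(sigma * sigma))

    def sample(self, rng: np.random.Generator, size: int | None = None) -> np.ndarray | float:
        """Draw from the distribution using ``rng``."""
        if self.family == "point":
            return self.a if size is None else np.full(size, self.a)
        if self.family == "beta":
            return rng.beta(self.a, self.b, size)
        mu, sigma = self.log_params()
        if sigma == 0.0:
            value = math.exp(mu)
            return value if size is None else np.full(size, value)
        return rng.lognormal(mu, sigma, size)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


@dataclass(frozen=True)
class ModelParameters:
    """All model constants, distribution specs and run settings.

    Defaults reproduce the published parameter table: baseline opioid
    misuse prevalence 5.3% (U.S. ages 18-25), baseline anxiety prevalence
    6.6%, lognormal OR with natural mean 3.04 / sd 1.07, Beta(10.5, 70)
    post-fire anxiety prevalence, hypothetical risk ratio 5 for both the
    incident-anxiety stratum (S2/S3) and the worsened pre-existing
    stratum (S3), and 50,000 Monte Carlo iterations.
    """

    baseline_misuse_prev: float = 0.053
    baseline_anxiety_prev: float = 0.066
    or_misuse_given_anxiety: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("lognormal", 3.04, 1.07)
    )
    anxiety_prev_post_fire: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("beta", 10.5, 70.0)
    )
    rr_incident_fire_anxiety: float = 5.0
    rr_worsened_preexisting: float = 5.0
    or_as_rr: bool = False
    n_iterations: int = 50_000
    seed: int = 1

    def __post_init__(self) -> None:
        _check_prob("baseline_misuse_prev", self.baseline_misuse_prev)
        _check_prob("baseline_anxiety_prev", self.baseline_anxiety_prev)
        if self.rr_incident_fire_anxiety < 1.0:
            raise ValueError("rr_incident_fire_anxiety must be >= 1")
        if self.rr_worsened_preexisting < 1.0:
            raise ValueError("rr_worsened_preexisting must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be a positive integer")

    @property
    def dialect(self) -> str:
        """Association dialect used in calibration."""
        return "risk_ratio" if self.or_as_rr else "odds_ratio"

    def with_(self, **kwargs) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ParameterDraw:
    """One Monte Carlo realisation of the two probabilistic parameters."""

    or_value: float
    p_anx_fire: float

    def __post_init__(self) -> None:
        if self.or_value <= 0:
            raise ValueError("or_value must be positive")
        if not (0.0 < self.p_anx_fire < 1.0):
            raise ValueError("p_anx_fire must lie strictly in (0, 1)")


def sample_draw(params: ModelParameters, rng: np.random.Generator) -> ParameterDraw:
    """Draw one (OR, post-fire anxiety prevalence) pair from a shared generator.

    Consumes the generator in a fixed order — OR first, then anxiety
    prevalence — so a loop over this function is a pure function of the
    generator's seed.
    """
    or_value = float(params.or_misuse_given_anxiety.sample(rng))
    p_anx = float(params.anxiety_prev_post_fire.sample(rng))
    return ParameterDraw(or_value=or_value, p_anx_fire=p_anx)


def sample_draws(
    params: ModelParameters, n: int, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised draw of ``n`` (OR, anxiety) pairs.

    Each probabilistic parameter gets its own generator, spawned from the
    seed via :class:`numpy.random.SeedSequence`, so the draw stream is
    identical whether it is produced in one batch or many — batching
    never changes the results for a given seed.

    Returns
    -------
    (or_values, p_anx_fire)
        Two float arrays of length ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = params.seed
    ss_or, ss_anx = np.random.SeedSequence(seed).spawn(2)
    or_values = np.asarray(
        params.or_misuse_given_anxiety.sample(np.random.default_rng(ss_or), n), dtype=float
    )
    p_anx = np.asarray(
        params.anxiety_prev_post_fire.sample(np.random.default_rng(ss_anx), n), dtype=float
    )
    return or_values, p_anx


def iter_draws(params: ModelParameters, n: int, seed: int | None = None) -> Iterator[ParameterDraw]:
    """Iterate over the same draw stream :func:`sample_draws` produces."""
    or_values, p_anx = sample_draws(params, n, seed)
    for o, p in zip(or_values, p_anx):
        yield ParameterDraw(or_value=float(o), p_anx_fire=float(p))
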