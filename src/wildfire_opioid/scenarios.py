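"""Post-wildfire population strata and per-draw scenario outcomes.

Each scenario partitions the exposed population into anxiety strata and
assigns each stratum a misuse probability:

* **S1** (base case) — wildfire only raises anxiety *incidence*: an
  anxiety stratum at the drawn post-fire prevalence with the
  OR-calibrated risk ``p1``, and the remainder at ``p0``.
* **S2** — incident fire-related anxiety is a distinct phenotype with a
  greater tendency for misuse: pre-existing anxiety (baseline
  prevalence) keeps ``p1``; the incident stratum (post-fire minus
  baseline anxiety, floored at 0) gets the hypothetical risk ratio
  applied to ``p0``; the remainder keeps ``p0``.
* **S3** — additionally, wildfire worsens pre-existing anxiety: the
  pre-existing stratum is also raised to the risk-ratio-scaled risk.

The risk ratio multiplies the calibrated *no-anxiety* risk ``p0``
(capped at 1); incident-anxiety proportions are floored at zero because
the framework models anxiety incidence, not remission.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calibration import CalibratedRisks
from .parameters import SCENARIOS, ModelParameters, ParameterDraw

__all__ = [
    "Stratum",
    "StratumSet",
    "DrawResult",
    "build_strata",
    "stratum_prevalence",
    "prevalence_ratio",
    "evaluate_draw",
]

_PROPORTION_TOL = 1e-12


@dataclass(frozen=True)
class Stratum:
    label: str  #: one of no_anxiety / preexisting_anxiety / incident_fire_anxiety
    proportion: float
    misuse_prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion <= 1.0):
            raise ValueError(f"stratum proportion out of [0, 1]: {self.proportion}")
        if not (0.0 <= self.misuse_prob <= 1.0):
            raise ValueError(f"stratum misuse_prob out of [0, 1]: {self.misuse_prob}")


@dataclass(frozen=True)
class StratumSet:
    strata: tuple[Stratum, ...]
    scenario: str

    def __post_init__(self) -> None:
        total = sum(s.proportion for s in self.strata)
        if abs(total - 1.0) > _PROPORTION_TOL:
            raise ValueError(f"stratum proportions sum to {total}, not 1")


@dataclass(frozen=True)
class DrawResult:
    scenario: str
    post_prevalence: float
    prevalence_ratio: float


def build_strata(
    draw: ParameterDraw,
    risks: CalibratedRisks,
    params: ModelParameters,
    scenario: str,
) -> StratumSet:
    """Assemble the post-wildfire strata for one draw and scenario."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")
    p0, p1 = risks.p0, risks.p1
    p_anx = draw.p_anx_fire
    if scenario == "S1":
        strata = (
            Stratum("preexisting_anxiety", p_anx, p1),
            Stratum("no_anxiety", 1.0 - p_anx, p0),
        )
        return StratumSet(strata=strata, scenario=scenario)

    p_base = params.baseline_anxiety_prev
    incident = max(p_anx - p_base, 0.0)
    rr_risk_incident = min(params.rr_incident_fire_anxiety * p0, 1.0)
    if scenario == "S2":
        preexisting_risk = p1
    else:  # S3: worsened pre-existing anxiety shares the elevated risk
        preexisting_risk = min(params.rr_worsened_preexisting * p0, 1.0)
    strata = (
        Stratum("preexisting_anxiety", p_base, preexisting_risk),
        Stratum("incident_fire_anxiety", incident, rr_risk_incident),
        Stratum("no_anxiety", 1.0 - p_base - incident, p0),
    )
    return StratumSet(strata=strata, scenario=scenario)


def stratum_prevalence(strata: StratumSet) -> float:
    """Population misuse prevalence implied by a stratum set (mixture mean)."""
    return sum(s.proportion * s.misuse_prob for s in strata.strata)


def prevalence_ratio(post: float, baseline: float) -> float:
    """Post-exposure prevalence over baseline; exact quotient, never clamped."""
    if baseline <= 0:
        raise ZeroDivisionError("baseline prevalence must be positive")
    return post / baseline


def evaluate_draw(
    draw: ParameterDraw,
    risks: CalibratedRisks,
    params: ModelParameters,
    scenario: str,
) -> DrawResult:
    """Post-wildfire prevalence and prevalence ratio for one draw/scenario."""
    post = stratum_prevalence(build_strata(draw, risks, params, scenario))
    pr = prevalence_ratio(post, params.baseline_misuse_prev)
    return DrawResult(scenario=scenario, post_prevalence=post, prevalence_ratio=pr)
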