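"""Relative-risk adjustment of the population-average fracture hazard.

Risk factors act as multipliers on the fracture hazard only — the death
hazard is never modified. Prior fracture contributes a per-outcome scalar
relative risk; a femoral-neck T-score contributes ``gradient^(t_ref - t)``
per outcome; further factors enter as user-supplied multipliers. All
multipliers compose multiplicatively.

The default gradients of risk (hip 3.7, MOF 1.6 per SD) and the default
prior-fracture relative risk (1.8) are literature-typical placeholders, not
calibrated coefficients; supply your own for any substantive use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hazard_engine import (
    HazardFunction,
    ProbabilityResult,
    ten_year_probability,
    to_hazard,
)
from .model import CountryModel


@dataclass(frozen=True)
class RiskProfile:
    """One individual's covariates.

    ``extra_rr`` holds additional labelled hazard multipliers (e.g. a BMI
    effect, which has no built-in curve here).
    """

    age: float
    sex: str
    bmi: float | None = None
    prior_fracture: bool = False
    t_score: float | None = None
    extra_rr: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.bmi is not None and not (10.0 <= self.bmi <= 60.0):
            raise ValueError(f"bmi={self.bmi} outside plausible range [10, 60]")
        object.__setattr__(self, "extra_rr", tuple(self.extra_rr))
        for label, rr in self.extra_rr:
            if not rr > 0:
                raise ValueError(f"relative risk for {label!r} must be > 0, got {rr}")


@dataclass(frozen=True)
class RiskFactorConfig:
    """User-supplied stand-ins for the risk-factor coefficients.

    rr_prior_fracture maps outcome ('hip'/'mof') to the prior-fracture
    relative risk; gradient_hip / gradient_mof are the per-SD gradients of
    risk for femoral-neck BMD; t_ref maps age to the reference mean T-score
    (constant callable default: 0.0 at every age).
    """

    rr_prior_fracture: dict = field(
        default_factory=lambda: {"hip": 1.8, "mof": 1.8}
    )
    gradient_hip: float = 3.7
    gradient_mof: float = 1.6
    t_ref: dict = field(default_factory=dict)  # age -> reference T-score

    def __post_init__(self) -> None:
        for outcome, rr in self.rr_prior_fracture.items():
            if not rr > 0:
                raise ValueError(
                    f"prior-fracture relative risk for {outcome!r} must be > 0"
                )
        if not self.gradient_hip > 1 or not self.gradient_mof > 1:
            raise ValueError("gradients of risk must exceed 1")

    def reference_tscore(self, age: float) -> float:
        if not self.t_ref:
            return 0.0
        ages = np.asarray(sorted(self.t_ref), dtype=float)
        vals = np.asarray([self.t_ref[a] for a in sorted(self.t_ref)], dtype=float)
        return float(np.interp(age, ages, vals))

    def gradient(self, outcome: str) -> float:
        return {"hip": self.gradient_hip, "mof": self.gradient_mof}[outcome]


def apply_relative_risk(phi: HazardFunction, rr: float) -> HazardFunction:
    """Pointwise hazard multiplication phi'(a) = rr * phi(a); rr > 0."""
    if not rr > 0:
        raise ValueError(f"relative risk must be > 0, got {rr}")
    return phi.scaled(rr)


def rr_from_tscore(t: float, t_ref: float, gradient: float) -> float:
    """gradient^(t_ref - t): each SD below the reference multiplies risk by
    the gradient of risk. Requires gradient > 1."""
    if not gradient > 1:
        raise ValueError(
            f"gradient of risk must exceed 1, got {gradient} "
            "(a non-informative or inverted gradient is a configuration fault)"
        )
    return float(gradient ** (t_ref - t))


def combined_relative_risk(
    profile: RiskProfile, config: RiskFactorConfig, outcome: str
) -> float:
    """Product of all applicable hazard multipliers for one outcome."""
    rr = 1.0
    if profile.prior_fracture:
        try:
            rr *= config.rr_prior_fracture[outcome]
        except KeyError:
            raise KeyError(
                f"no prior-fracture relative risk configured for {outcome!r}"
            ) from None
    if profile.t_score is not None:
        rr *= rr_from_tscore(
            profile.t_score,
            config.reference_tscore(profile.age),
            config.gradient(outcome),
        )
    for _, extra in profile.extra_rr:
        rr *= extra
    return rr


def profile_probability(
    model: CountryModel,
    profile: RiskProfile,
    config: RiskFactorConfig | None = None,
    horizon: float = 10.0,
) -> ProbabilityResult:
    """Hip and MOF probabilities for one individual under a country model.

    Composes schedule-to-hazard conversion, the multiplicative risk-factor
    adjustment of the fracture hazard, and the competing-risk probability
    integral. The death hazard is never adjusted.
    """
    config = config or RiskFactorConfig()
    start = profile.age
    end = profile.age + horizon
    mu = to_hazard(model.schedule(profile.sex, "mortality"), start, end)
    probs: dict[str, float] = {}
    for outcome in ("hip", "mof"):
        phi = to_hazard(model.schedule(profile.sex, outcome), start, end)
        rr = combined_relative_risk(profile, config, outcome)
        phi = apply_relative_risk(phi, rr) if rr != 1.0 else phi
        probs[outcome] = ten_year_probability(phi, mu, profile.age, horizon)
    return ProbabilityResult(
        age=profile.age,
        sex=profile.sex,
        horizon=horizon,
        p_hip=probs["hip"],
        p_mof=probs["mof"],
    )
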