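"""Synthetic incidence/mortality schedules and fully synthetic countries.

Real hip-fracture incidence inputs are register-derived and not bundled
here, so every pipeline stage is exercised against Gompertz(-Makeham)
schedules whose true hazards are known in closed form: event rates grow
exponentially with age, with an optional age-constant additive term for
mortality. Event counts are Poisson given rate and exposure; a single
global seed deterministically derives one stream per age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import CountryModel
from .rate_tables import AgeRateSchedule, RatioSchedule
from .surrogate_mof import derive_mof_schedule

DEFAULT_AGES = tuple(float(a) for a in range(50, 101, 5))


@dataclass(frozen=True)
class GompertzParams:
    """Exponential-in-age rate model, per 100,000 person-years.

    rate(a) = base_rate * exp(slope * (a - anchor_age)) + makeham * 100000
    """

    base_rate: float
    anchor_age: float = 50.0
    slope: float = 0.0
    makeham: float = 0.0

    def __post_init__(self) -> None:
        if self.base_rate < 0:
            raise ValueError("base_rate must be non-negative")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")
        if self.makeham < 0:
            raise ValueError("makeham term must be non-negative")

    def rate(self, age: float | np.ndarray) -> np.ndarray:
        a = np.asarray(age, dtype=float)
        return self.base_rate * np.exp(self.slope * (a - self.anchor_age)) + (
            self.makeham * 100000.0
        )


def gompertz_schedule(
    params: GompertzParams,
    ages: np.ndarray | list[float] = DEFAULT_AGES,
    kind: str = "hip_incidence",
    *,
    sex: str = "female",
    population_label: str = "synthetic",
) -> AgeRateSchedule:
    """Deterministic rate schedule evaluated from Gompertz parameters."""
    ages = tuple(float(a) for a in ages)
    return AgeRateSchedule(
        population_label=population_label,
        sex=sex,
        age_points=ages,
        rates=tuple(params.rate(np.asarray(ages))),
        kind=kind,
    )


def sample_counts(
    schedule: AgeRateSchedule,
    person_years: float | np.ndarray,
    seed: int,
) -> np.ndarray:
    """Per-age Poisson event counts with mean rate/100000 * person_years.

    Per-age generators are spawned deterministically from the one seed, so
    counts at age i do not change when other ages are added or removed.
    """
    py = np.broadcast_to(
        np.asarray(person_years, dtype=float), schedule.ages.shape
    )
    if np.any(py <= 0):
        raise ValueError("person-years of exposure must be positive")
    means = schedule.values / 100000.0 * py
    streams = np.random.SeedSequence(seed).spawn(len(means))
    return np.asarray(
        [np.random.default_rng(s).poisson(m) for s, m in zip(streams, means)],
        dtype=np.int64,
    )


@dataclass(frozen=True)
class RateEstimate:
    """Estimated rates with exact (Garwood) Poisson 95% intervals."""

    schedule: AgeRateSchedule
    ci_lower: tuple[float, ...]
    ci_upper: tuple[float, ...]


def poisson_exact_ci(
    count: int, person_years: float, level: float = 0.95
) -> tuple[float, float]:
    """Garwood exact CI for a Poisson rate, per 100,000 person-years."""
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2
    scale = 100000.0 / person_years
    return lo * scale, hi * scale


def estimate_rates(
    counts: np.ndarray | list[int],
    person_years: float | np.ndarray,
    ages: np.ndarray | list[float],
    kind: str = "hip_incidence",
    *,
    sex: str = "female",
    population_label: str = "estimated",
) -> RateEstimate:
    """rate = count / person_years * 100000 per age, with exact 95% CIs."""
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(ages, dtype=float)
    py = np.broadcast_to(np.asarray(person_years, dtype=float), counts.shape)
    if np.any(py <= 0):
        raise ValueError("person-years of exposure must be positive")
    rates = counts / py * 100000.0
    cis = [poisson_exact_ci(int(c), p) for c, p in zip(counts, py)]
    schedule = AgeRateSchedule(
        population_label=population_label,
        sex=sex,
        age_points=tuple(ages),
        rates=tuple(rates),
        kind=kind,
    )
    return RateEstimate(
        schedule=schedule,
        ci_lower=tuple(lo for lo, _ in cis),
        ci_upper=tuple(hi for _, hi in cis),
    )


def fit_log_slope(
    ages: np.ndarray | list[float],
    rates: np.ndarray | list[float],
    weights: np.ndarray | list[float] | None = None,
) -> tuple[float, float]:
    """Slope and standard error of log-rate regressed linearly on age.

    Ages with zero estimated rate are dropped (their log is undefined).
    ``weights`` are inverse variances of the log-rates; for rates estimated
    from Poisson counts, pass the counts themselves (var(log rate) ~
    1/count), which calibrates the standard error under the count
    heteroskedasticity. Unweighted, this is plain OLS.
    """
    ages = np.asarray(ages, dtype=float)
    rates = np.asarray(rates, dtype=float)
    keep = rates > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 positive rates to fit a slope")
    if weights is None:
        res = stats.linregress(ages[keep], np.log(rates[keep]))
        return float(res.slope), float(res.stderr)
    w = np.asarray(weights, dtype=float)[keep]
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    x = ages[keep]
    y = np.log(rates[keep])
    design = np.column_stack([np.ones_like(x), x])
    normal = (design.T * w) @ design
    beta = np.linalg.solve(normal, (design.T * w) @ y)
    cov = np.linalg.inv(normal)
    return float(beta[1]), float(np.sqrt(cov[1, 1]))


def make_synthetic_country(
    incidence_params: GompertzParams | dict[str, GompertzParams],
    mortality_params: GompertzParams | dict[str, GompertzParams],
    ratio_constant: float = 3.0,
    seed: int | None = None,
    *,
    ages: np.ndarray | list[float] = DEFAULT_AGES,
    person_years: float | None = None,
    population_label: str = "synthetic-country",
) -> CountryModel:
    """End-to-end buildable model with closed-form true hazards.

    With ``person_years`` unset the model carries the exact Gompertz rates;
    with it set, hip rates are re-estimated from seeded Poisson counts at
    that exposure per age (``seed`` then required), exercising the full
    count -> rate -> model path. MOF incidence is hip incidence times
    ``ratio_constant`` at every age.
    """
    if ratio_constant < 1:
        raise ValueError("ratio_constant must be >= 1")

    def per_sex(params, sex):
        return params[sex] if isinstance(params, dict) else params

    schedules: dict[str, dict[str, AgeRateSchedule]] = {}
    for sex in ("female", "male"):
        inc = per_sex(incidence_params, sex)
        mort = per_sex(mortality_params, sex)
        hip = gompertz_schedule(
            inc, ages, "hip_incidence", sex=sex, population_label=population_label
        )
        if person_years is not None:
            if seed is None:
                raise ValueError("seed is required when sampling counts")
            sex_seed = seed + (0 if sex == "female" else 1)
            counts = sample_counts(hip, person_years, sex_seed)
            hip = estimate_rates(
                counts,
                person_years,
                hip.ages,
                "hip_incidence",
                sex=sex,
                population_label=population_label,
            ).schedule
        ratios = RatioSchedule(
            sex=sex,
            age_points=(min(ages), max(ages)),
            ratios=(ratio_constant, ratio_constant),
        )
        schedules[sex] = {
            "hip": hip,
            "mof": derive_mof_schedule(hip, ratios),
            "mortality": gompertz_schedule(
                mort, ages, "mortality", sex=sex, population_label=population_label
            ),
        }
    return CountryModel(
        population_label=population_label,
        schedules=schedules,
        metadata={
            "synthetic": True,
            "ratio_constant": ratio_constant,
            "seed": seed,
            "person_years": person_years,
        },
    )


# Botswana-like magnitudes (hip probability of order 0.2-1.5% over ages
# 50-90 for women) so tests run in the realistic low-probability regime.
# These values are synthetic and are not estimates for any real population.
LOW_INCIDENCE_PRESET = {
    "incidence": GompertzParams(base_rate=15.0, anchor_age=50.0, slope=0.085),
    "mortality": GompertzParams(
        base_rate=900.0, anchor_age=50.0, slope=0.095, makeham=0.002
    ),
    "ratio_constant": 4.0,
}

# Steep late-age mortality: exhibits the non-monotone hip-probability tail
# (probability falling at the oldest ages) that competing mortality causes.
HIGH_MORTALITY_PRESET = {
    "incidence": GompertzParams(base_rate=20.0, anchor_age=50.0, slope=0.105),
    "mortality": GompertzParams(
        base_rate=900.0, anchor_age=50.0, slope=0.108, makeham=0.002
    ),
    "ratio_constant": 3.5,
}

PRESETS = {
    "low-incidence": LOW_INCIDENCE_PRESET,
    "high-mortality": HIGH_MORTALITY_PRESET,
}
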