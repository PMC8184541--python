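"""Piecewise-constant hazards and competing-risk fracture probabilities.

A rate schedule (events per 100,000 person-years at a handful of exact ages)
is converted to a continuous-time hazard that is constant on one-year age
intervals. The 10-year first-fracture probability under the competing risk
of death is then accumulated interval by interval with the exact
constant-hazard closed form, so the result carries no quadrature tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rate_tables import AGE_MAX, AGE_MIN, AgeRateSchedule

_LOG_FLOOR = 1e-12  # zero rates are floored here before log-interpolation


@dataclass(frozen=True)
class HazardFunction:
    """Hazard per person-year, piecewise-constant on one-year age intervals.

    ``values[i]`` is the hazard on ``[start_age + i, start_age + i + 1)``.
    """

    start_age: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_age", float(self.start_age))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        arr = np.asarray(self.values, dtype=float)
        if arr.size == 0:
            raise ValueError("hazard function must cover at least one interval")
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("hazard values must be non-negative and finite")

    @property
    def end_age(self) -> float:
        return self.start_age + len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def covers(self, lo: float, hi: float) -> bool:
        return self.start_age <= lo and hi <= self.end_age + 1e-9

    def at(self, age: float) -> float:
        """Hazard at an exact age (right-open intervals)."""
        if not (self.start_age <= age < self.end_age):
            raise ValueError(
                f"age {age:g} outside hazard coverage "
                f"[{self.start_age:g}, {self.end_age:g})"
            )
        return self.values[int(np.floor(age - self.start_age))]

    def scaled(self, factor: float) -> "HazardFunction":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return HazardFunction(self.start_age, tuple(v * factor for v in self.values))


def log_linear_rate(schedule: AgeRateSchedule, age: float | np.ndarray) -> np.ndarray:
    """Rate per 100,000 PY at arbitrary ages, log-linearly interpolated
    between the schedule's age points and clamped beyond its range.

    Zero rates are floored at 1e-12 for the interpolation; an interval whose
    both endpoints are zero interpolates back to exactly zero.
    """
    ages = schedule.ages
    rates = schedule.values
    floored = np.maximum(rates, _LOG_FLOOR)
    out = np.exp(np.interp(np.asarray(age, dtype=float), ages, np.log(floored)))
    # restore exact zeros where both bracketing endpoints are zero
    zero = rates == 0.0
    if zero.any():
        a = np.asarray(age, dtype=float)
        idx = np.clip(np.searchsorted(ages, a, side="right") - 1, 0, len(ages) - 2)
        both_zero = zero[idx] & zero[idx + 1]
        both_zero |= (a <= ages[0]) & zero[0]
        both_zero |= (a >= ages[-1]) & zero[-1]
        out = np.where(both_zero, 0.0, out)
    return out


def to_hazard(
    schedule: AgeRateSchedule, start_age: float, end_age: float
) -> HazardFunction:
    """Discretise a rate schedule to a one-year piecewise-constant hazard.

    hazard(a) = rate(a) / 100000 per year, with the rate evaluated at each
    one-year interval's midpoint age via :func:`log_linear_rate`.
    """
    if end_age <= start_age:
        raise ValueError("end_age must exceed start_age")
    if end_age <= AGE_MIN or start_age >= AGE_MAX:
        raise ValueError(
            f"requested range [{start_age:g}, {end_age:g}] lies entirely "
            f"outside the supported ages [{AGE_MIN:g}, {AGE_MAX:g}]"
        )
    n = int(np.ceil(end_age - start_age - 1e-9))
    midpoints = start_age + np.arange(n) + 0.5
    values = log_linear_rate(schedule, midpoints) / 100000.0
    return HazardFunction(start_age=start_age, values=tuple(values))


def _aligned_values(h: HazardFunction, age: float, horizon: float) -> np.ndarray:
    """Hazard values on consecutive one-year intervals starting at ``age``.

    ``age`` need not sit on the hazard's own knots; the value at each
    shifted interval's midpoint is used (exact when the shift is integral).
    """
    n = int(np.ceil(horizon - 1e-9))
    mids = age + np.arange(n) + 0.5
    mids = np.minimum(mids, h.end_age - 1e-9)
    return np.asarray([h.at(m) for m in mids], dtype=float)


def ten_year_probability(
    phi: HazardFunction,
    mu: HazardFunction,
    age: float,
    horizon: float = 10.0,
) -> float:
    """Probability of a first fracture before death within ``horizon`` years.

    Computes P = integral over [0, H) of phi(a+t) * exp(-int_0^t (phi+mu))
    dt, exactly on each one-year interval:

        P_i = phi_i / (phi_i + mu_i) * S * (1 - exp(-(phi_i + mu_i) * d))

    with the survival S carried between intervals.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    hi = age + horizon
    for name, h in (("fracture", phi), ("death", mu)):
        if not h.covers(age, hi):
            raise ValueError(
                f"{name} hazard covers [{h.start_age:g}, {h.end_age:g}] but "
                f"[{age:g}, {hi:g}] is required"
            )
    phi_vals = _aligned_values(phi, age, horizon)
    mu_vals = _aligned_values(mu, age, horizon)
    n = len(phi_vals)
    widths = np.ones(n)
    if horizon < n:  # fractional final interval
        widths[-1] = horizon - (n - 1)

    prob = 0.0
    survival = 1.0
    for p, m, d in zip(phi_vals, mu_vals, widths):
        lam = p + m
        if lam > 0.0:
            decay = -np.expm1(-lam * d)  # 1 - exp(-lam*d), accurate for small lam
            prob += survival * (p / lam) * decay
            survival *= np.exp(-lam * d)
    return float(prob)


def probability_curve(
    phi: HazardFunction,
    mu: HazardFunction,
    ages: np.ndarray | list[float],
    horizon: float = 10.0,
) -> np.ndarray:
    """10-year probabilities at each age, in percent."""
    return np.asarray(
        [100.0 * ten_year_probability(phi, mu, a, horizon) for a in ages], dtype=float
    )


@dataclass(frozen=True)
class ProbabilityResult:
    """Hip and MOF fracture probabilities for one person and horizon."""

    age: float
    sex: str
    horizon: float
    p_hip: float
    p_mof: float

    def __post_init__(self) -> None:
        for label, p in (("p_hip", self.p_hip), ("p_mof", self.p_mof)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label}={p} outside [0, 1]")
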