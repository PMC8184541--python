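"""Age-standardisation and cross-population comparison statistics."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .model import CountryModel
from .rate_tables import ProbabilityGrid, StandardPopulation, normalise
from .risk_adjustment import RiskFactorConfig, RiskProfile, profile_probability


def round_half_up(x: float, dp: int) -> float:
    """Deterministic half-up decimal rounding (3.25 -> 3.3 at 1 dp)."""
    q = Decimal(1).scaleb(-dp)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ComparisonStats:
    """Derived cross-population statistics of a probability grid.

    ratio_80_50: population -> probability at 80 / probability at 50.
    spread_by_age: age -> max/min ratio across populations.
    column_range: population -> (min, max) over ages.
    min_spread: minimum of spread_by_age over ages.
    """

    ratio_80_50: dict[str, float]
    spread_by_age: dict[float, float]
    column_range: dict[str, tuple[float, float]]
    min_spread: float


def age_standardise(
    ages: np.ndarray | list[float],
    probabilities_pct: np.ndarray | list[float],
    pop: StandardPopulation,
) -> float:
    """Weighted sum of the probability curve at band midpoints, in percent.

    The curve is linearly interpolated between its supplied ages; every band
    midpoint must lie within the curve's age range. Weights are normalised
    first, so pre-scaled and raw weights give identical results.
    """
    ages = np.asarray(ages, dtype=float)
    probs = np.asarray(probabilities_pct, dtype=float)
    if ages.size != probs.size or ages.size == 0:
        raise ValueError("curve ages and probabilities must be same nonzero length")
    if not np.all(np.diff(ages) > 0):
        raise ValueError("curve ages must be strictly increasing")
    pop = normalise(pop)
    mids = pop.midpoints
    if mids.min() < ages[0] - 1e-9 or mids.max() > ages[-1] + 1e-9:
        raise ValueError(
            f"curve covers ages [{ages[0]:g}, {ages[-1]:g}] but band midpoints "
            f"span [{mids.min():g}, {mids.max():g}]"
        )
    return float(np.sum(pop.weight_array * np.interp(mids, ages, probs)))


def age_ratio(
    grid: ProbabilityGrid,
    population: str,
    age_num: float,
    age_den: float,
    round_dp: int | None = 1,
) -> float:
    """value(population, age_num) / value(population, age_den), rounded
    half-up to ``round_dp`` decimals (pass ``None`` to skip rounding)."""
    num = grid.value(population, age_num)
    den = grid.value(population, age_den)
    if den == 0:
        raise ZeroDivisionError(
            f"zero probability at denominator age {age_den:g} for {population!r}"
        )
    ratio = num / den
    return ratio if round_dp is None else round_half_up(ratio, round_dp)


def cross_population_spread(grid: ProbabilityGrid) -> tuple[dict[float, float], float]:
    """Per-age max/min ratio across populations, and its minimum over ages."""
    m = grid.matrix
    if np.any(m == 0):
        raise ValueError("grid contains zero cells; spread undefined")
    per_age = m.max(axis=0) / m.min(axis=0)
    by_age = {float(a): float(r) for a, r in zip(grid.age_points, per_age)}
    return by_age, float(per_age.min())


def column_range(grid: ProbabilityGrid, population: str) -> tuple[float, float]:
    """(min, max) of one population's probabilities over all grid ages."""
    col = grid.column(population)
    return float(col.min()), float(col.max())


def comparison_stats(grid: ProbabilityGrid) -> ComparisonStats:
    """All derived statistics for one grid in a single pass."""
    spread_by_age, min_spread = cross_population_spread(grid)
    has_80_50 = all(any(np.isclose(grid.age_points, a)) for a in (50, 80))
    ratios = (
        {p: age_ratio(grid, p, 80, 50) for p in grid.populations}
        if has_80_50
        else {}
    )
    ranges = {p: column_range(grid, p) for p in grid.populations}
    return ComparisonStats(
        ratio_80_50=ratios,
        spread_by_age=spread_by_age,
        column_range=ranges,
        min_spread=min_spread,
    )


def intervention_thresholds(
    model: CountryModel,
    config: RiskFactorConfig | None = None,
    ages: np.ndarray | list[float] = tuple(range(50, 91, 5)),
    horizon: float = 10.0,
) -> tuple[dict[float, float], tuple[float, float]]:
    """Age-specific intervention thresholds in percent MOF probability.

    The threshold at each age is the 10-year MOF probability of a woman of
    that age with a prior fracture and no other risk factors (anyone at or
    above the probability of a same-age woman with prior fracture qualifies
    for treatment). Returns the age-indexed thresholds and their (min, max).
    """
    config = config or RiskFactorConfig()
    thresholds: dict[float, float] = {}
    for age in ages:
        profile = RiskProfile(age=float(age), sex="female", prior_fracture=True)
        res = profile_probability(model, profile, config, horizon=horizon)
        thresholds[float(age)] = 100.0 * res.p_mof
    vals = np.asarray(list(thresholds.values()))
    return thresholds, (float(vals.min()), float(vals.max()))
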