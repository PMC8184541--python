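"""Typed ingestion, validation and serialisation of age-structured rate inputs.

All event rates are expressed per 100,000 person-years. Ages are exact ages
in years (suppliers of banded data are responsible for choosing band
midpoints). CSV files are comma-delimited with a dot decimal separator and a
mandatory header row.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AGE_MIN = 40.0
AGE_MAX = 110.0

RATE_KINDS = ("hip_incidence", "mof_incidence", "mortality")
SEXES = ("female", "male")

_FIXTURE_NAME = "probability_grid_prior_fracture_women.csv"


class SchemaError(ValueError):
    """Raised when an input table violates the documented CSV schema."""


@dataclass(frozen=True)
class AgeRateSchedule:
    """Age-gridded event rates per 100,000 person-years for one sex.

    Parameters
    ----------
    population_label:
        Free-text label for the population the rates describe.
    sex:
        ``"female"`` or ``"male"``.
    age_points:
        Strictly increasing ages in years, all within [40, 110].
    rates:
        Non-negative, finite event rates per 100,000 person-years, one per
        age point.
    kind:
        One of ``"hip_incidence"``, ``"mof_incidence"`` or ``"mortality"``.
    """

    population_label: str
    sex: str
    age_points: tuple[float, ...]
    rates: tuple[float, ...]
    kind: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.kind not in RATE_KINDS:
            raise ValueError(f"kind must be one of {RATE_KINDS}, got {self.kind!r}")
        object.__setattr__(self, "age_points", tuple(float(a) for a in self.age_points))
        object.__setattr__(self, "rates", tuple(float(r) for r in self.rates))
        ages = np.asarray(self.age_points, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        if ages.size == 0:
            raise ValueError("schedule must contain at least one age point")
        if ages.size != rates.size:
            raise ValueError(
                f"length mismatch: {ages.size} ages vs {rates.size} rates"
            )
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages not increasing")
        if ages[0] < AGE_MIN or ages[-1] > AGE_MAX:
            raise ValueError(
                f"ages must lie within [{AGE_MIN:g}, {AGE_MAX:g}], "
                f"got [{ages[0]:g}, {ages[-1]:g}]"
            )
        if not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        if np.any(rates < 0):
            raise ValueError("negative rate")

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.age_points, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.rates, dtype=float)

    def scaled(self, factor: float) -> "AgeRateSchedule":
        """Return a copy with every rate multiplied by ``factor`` (>= 0)."""
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return replace(self, rates=tuple(r * factor for r in self.rates))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.age_points, "rate": self.rates})


@dataclass(frozen=True)
class RatioSchedule:
    """Age-gridded MOF:hip rate multipliers (>= 1) for one sex."""

    sex: str
    age_points: tuple[float, ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        object.__setattr__(self, "age_points", tuple(float(a) for a in self.age_points))
        object.__setattr__(self, "ratios", tuple(float(r) for r in self.ratios))
        ages = np.asarray(self.age_points, dtype=float)
        ratios = np.asarray(self.ratios, dtype=float)
        if ages.size == 0:
            raise ValueError("ratio schedule must contain at least one age point")
        if ages.size != ratios.size:
            raise ValueError("length mismatch between ages and ratios")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("ages not increasing")
        if not np.all(np.isfinite(ratios)):
            raise ValueError("ratios must be finite")
        if np.any(ratios < 1):
            raise ValueError("ratio below 1: MOF incidence cannot fall below hip incidence")

    @property
    def ages(self) -> np.ndarray:
        return np.asarray(self.age_points, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.ratios, dtype=float)

    def at(self, age: float | np.ndarray) -> np.ndarray:
        """Ratio at ``age``, linearly interpolated, clamped at both ends."""
        return np.interp(np.asarray(age, dtype=float), self.ages, self.values)


@dataclass(frozen=True)
class StandardPopulation:
    """Contiguous [lower, upper) age bands with non-negative weights."""

    age_bands: tuple[tuple[float, float], ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        bands = tuple((float(lo), float(hi)) for lo, hi in self.age_bands)
        object.__setattr__(self, "age_bands", bands)
        object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
        if len(bands) == 0:
            raise ValueError("standard population must contain at least one band")
        if len(bands) != len(self.weights):
            raise ValueError("length mismatch between bands and weights")
        for lo, hi in bands:
            if not hi > lo:
                raise ValueError(f"empty or inverted band [{lo:g}, {hi:g})")
        for (_, hi), (lo2, _) in zip(bands, bands[1:]):
            if abs(hi - lo2) > 1e-9:
                raise ValueError("bands must be contiguous and non-overlapping")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be non-negative and finite")

    @property
    def midpoints(self) -> np.ndarray:
        return np.asarray([(lo + hi) / 2 for lo, hi in self.age_bands], dtype=float)

    @property
    def weight_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class ProbabilityGrid:
    """Populations x ages grid of 10-year probabilities in percent."""

    outcome: str
    populations: tuple[str, ...]
    age_points: tuple[float, ...]
    values: tuple[tuple[float, ...], ...] = field(repr=False)

    def __post_init__(self) -> None:
        if self.outcome not in ("hip", "mof"):
            raise ValueError(f"outcome must be 'hip' or 'mof', got {self.outcome!r}")
        object.__setattr__(self, "populations", tuple(self.populations))
        object.__setattr__(self, "age_points", tuple(float(a) for a in self.age_points))
        vals = tuple(tuple(float(v) for v in row) for row in self.values)
        object.__setattr__(self, "values", vals)
        arr = np.asarray(vals, dtype=float)
        if arr.shape != (len(self.populations), len(self.age_points)):
            raise ValueError(
                f"values shape {arr.shape} does not match "
                f"{len(self.populations)} populations x {len(self.age_points)} ages"
            )
        if np.any(arr < 0) or np.any(arr > 100):
            raise ValueError("probabilities must lie in [0, 100] percent")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    def value(self, population: str, age: float) -> float:
        """Single cell lookup; raises ``KeyError`` on a missing cell."""
        try:
            i = self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in grid") from None
        ages = np.asarray(self.age_points)
        hits = np.nonzero(np.isclose(ages, float(age)))[0]
        if hits.size == 0:
            raise KeyError(f"age {age!r} not in grid")
        return self.matrix[i, hits[0]]

    def column(self, population: str) -> np.ndarray:
        """All ages for one population, in grid age order."""
        try:
            i = self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not in grid") from None
        return self.matrix[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.populations), columns=list(self.age_points)
        )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_two_column_csv(path: str | Path, value_col: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: could not parse CSV: {exc}") from exc
    missing = {"age", value_col} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("age", value_col):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise SchemaError(
                f"{path}: malformed value in column {col!r} at row {bad[0] + 2}"
            )
        df[col] = parsed
    return df


def read_rate_schedule(
    path: str | Path,
    kind: str,
    *,
    sex: str = "female",
    population_label: str = "unspecified",
) -> AgeRateSchedule:
    """Read an ``age,rate`` CSV into a validated :class:`AgeRateSchedule`.

    Metadata (population, sex, kind) is not stored in the file and must be
    supplied by the caller.
    """
    df = _read_two_column_csv(path, "rate")
    ages = df["age"].to_numpy(dtype=float)
    if np.unique(ages).size != ages.size:
        raise SchemaError(f"{path}: duplicate ages")
    if not np.all(np.diff(ages) > 0):
        raise SchemaError(f"{path}: ages not increasing")
    if np.any(df["rate"].to_numpy() < 0):
        row = int(df.index[df["rate"] < 0][0]) + 2
        raise SchemaError(f"{path}: negative rate at row {row}")
    return AgeRateSchedule(
        population_label=population_label,
        sex=sex,
        age_points=tuple(ages),
        rates=tuple(df["rate"].to_numpy(dtype=float)),
        kind=kind,
    )


def write_rate_schedule(schedule: AgeRateSchedule, path: str | Path) -> None:
    """Write a schedule back to the ``age,rate`` CSV format."""
    schedule.to_frame().to_csv(path, index=False)


def read_ratio_schedule(path: str | Path, *, sex: str = "female") -> RatioSchedule:
    """Read an ``age,ratio`` CSV into a validated :class:`RatioSchedule`."""
    df = _read_two_column_csv(path, "ratio")
    ages = df["age"].to_numpy(dtype=float)
    if not np.all(np.diff(ages) > 0):
        raise SchemaError(f"{path}: ages not increasing")
    return RatioSchedule(
        sex=sex, age_points=tuple(ages), ratios=tuple(df["ratio"].to_numpy(dtype=float))
    )


def read_standard_population(path: str | Path) -> StandardPopulation:
    """Read an ``age_lower,age_upper,weight`` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"age_lower", "age_upper", "weight"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    bands = tuple(
        (float(lo), float(hi)) for lo, hi in zip(df["age_lower"], df["age_upper"])
    )
    return StandardPopulation(age_bands=bands, weights=tuple(df["weight"].astype(float)))


def normalise(pop: StandardPopulation) -> StandardPopulation:
    """Rescale weights to sum to 1; the band structure is unchanged."""
    total = float(np.sum(pop.weight_array))
    if total <= 0:
        raise ValueError("cannot normalise: all weights are zero")
    return StandardPopulation(
        age_bands=pop.age_bands, weights=tuple(w / total for w in pop.weights)
    )


# ---------------------------------------------------------------------------
# Packaged comparison-grid fixture
# ---------------------------------------------------------------------------

def _grid_from_long(df: pd.DataFrame, outcome: str) -> ProbabilityGrid:
    sub = df[df["outcome"] == outcome]
    populations = list(dict.fromkeys(sub["population"]))
    ages = sorted(set(sub["age"].astype(float)))
    pivot = sub.pivot(index="population", columns="age", values="probability_pct")
    pivot = pivot.loc[populations, ages]
    return ProbabilityGrid(
        outcome=outcome,
        populations=tuple(populations),
        age_points=tuple(ages),
        values=tuple(tuple(row) for row in pivot.to_numpy(dtype=float)),
    )


def load_table1_fixture() -> tuple[ProbabilityGrid, ProbabilityGrid]:
    """Load the packaged published comparison grids (women, prior fracture,
    BMI 25): 10-year MOF and hip probabilities for six populations at ages
    50-90 in 5-year steps, values exactly as printed.

    Returns ``(mof_grid, hip_grid)``.
    """
    resource = importlib.resources.files("fracrisk").joinpath(
        "data", _FIXTURE_NAME
    )
    with importlib.resources.as_file(resource) as f:
        df = pd.read_csv(f)
    return _grid_from_long(df, "mof"), _grid_from_long(df, "hip")


def read_probability_grid_csv(path: str | Path) -> tuple[ProbabilityGrid, ...]:
    """Read a long-format ``outcome,population,age,probability_pct`` CSV,
    returning one grid per outcome present (mof first when both exist)."""
    df = pd.read_csv(path)
    missing = {"outcome", "population", "age", "probability_pct"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    outcomes = [o for o in ("mof", "hip") if o in set(df["outcome"])]
    return tuple(_grid_from_long(df, o) for o in outcomes)
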