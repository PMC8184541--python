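"""The buildable, serialisable country model: hip, MOF and death schedules."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .rate_tables import AgeRateSchedule

_OUTCOME_KINDS = {"hip": "hip_incidence", "mof": "mof_incidence"}


@dataclass(frozen=True)
class CountryModel:
    """Bundle of hip-incidence, MOF-incidence and mortality schedules.

    ``schedules`` maps sex -> outcome -> :class:`AgeRateSchedule`, where the
    outcome keys are ``"hip"``, ``"mof"`` and ``"mortality"``. Not every sex
    needs to be present, but each present sex must carry all three
    schedules.
    """

    population_label: str
    schedules: dict[str, dict[str, AgeRateSchedule]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sex, per_sex in self.schedules.items():
            missing = {"hip", "mof", "mortality"} - set(per_sex)
            if missing:
                raise ValueError(
                    f"model for sex {sex!r} is missing schedules {sorted(missing)}"
                )
            for outcome, kind in _OUTCOME_KINDS.items():
                if per_sex[outcome].kind != kind:
                    raise ValueError(
                        f"{sex}/{outcome} schedule has kind "
                        f"{per_sex[outcome].kind!r}, expected {kind!r}"
                    )
            if per_sex["mortality"].kind != "mortality":
                raise ValueError(
                    f"{sex}/mortality schedule has kind "
                    f"{per_sex['mortality'].kind!r}, expected 'mortality'"
                )
            for outcome, sched in per_sex.items():
                if sched.sex != sex:
                    raise ValueError(
                        f"schedule sex {sched.sex!r} filed under {sex!r}"
                    )

    def schedule(self, sex: str, outcome: str) -> AgeRateSchedule:
        try:
            return self.schedules[sex][outcome]
        except KeyError:
            raise KeyError(
                f"model {self.population_label!r} has no {outcome!r} schedule "
                f"for sex {sex!r}"
            ) from None

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "fracrisk-country-model",
            "version": 1,
            "population_label": self.population_label,
            "metadata": self.metadata,
            "schedules": {
                sex: {
                    outcome: {
                        "population_label": s.population_label,
                        "sex": s.sex,
                        "kind": s.kind,
                        "age_points": list(s.age_points),
                        "rates": list(s.rates),
                    }
                    for outcome, s in per_sex.items()
                }
                for sex, per_sex in self.schedules.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "CountryModel":
        if payload.get("format") != "fracrisk-country-model":
            raise ValueError("not a fracrisk country-model document")
        schedules = {
            sex: {
                outcome: AgeRateSchedule(
                    population_label=s["population_label"],
                    sex=s["sex"],
                    age_points=tuple(s["age_points"]),
                    rates=tuple(s["rates"]),
                    kind=s["kind"],
                )
                for outcome, s in per_sex.items()
            }
            for sex, per_sex in payload["schedules"].items()
        }
        return cls(
            population_label=payload["population_label"],
            schedules=schedules,
            metadata=payload.get("metadata", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "CountryModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
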