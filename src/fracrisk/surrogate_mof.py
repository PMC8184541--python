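"""Surrogate MOF incidence from hip incidence via an age/sex ratio schedule.

Where direct incidence of the non-hip major osteoporotic fractures is
unavailable, MOF incidence is approximated by multiplying hip incidence by
an age- and sex-specific MOF:hip ratio schedule. Ratios are applied to
rates, interpolate linearly in age, and are clamped beyond their own age
range. No published ratio values ship with this package — the example file
written by the CLI is synthetic and labelled as such.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .rate_tables import AgeRateSchedule, RatioSchedule


def derive_mof_schedule(hip: AgeRateSchedule, ratios: RatioSchedule) -> AgeRateSchedule:
    """mof_rate(a) = hip_rate(a) * ratio(a) at each hip age point.

    The output keeps the hip schedule's age grid and carries
    ``kind="mof_incidence"``.
    """
    if hip.kind != "hip_incidence":
        raise ValueError(f"expected a hip_incidence schedule, got kind {hip.kind!r}")
    if hip.sex != ratios.sex:
        raise ValueError(
            f"sex mismatch: hip schedule is {hip.sex!r}, ratios are {ratios.sex!r}"
        )
    multipliers = ratios.at(hip.ages)
    return replace(
        hip,
        rates=tuple(np.asarray(hip.rates) * multipliers),
        kind="mof_incidence",
    )


def validate_mof_dominance(
    hip: AgeRateSchedule, mof: AgeRateSchedule
) -> list[float]:
    """Ages at which the MOF rate falls below the hip rate (empty = OK).

    Violations are reported, not raised, so hand-edited inputs can be
    inspected without aborting a pipeline.
    """
    if hip.sex != mof.sex:
        raise ValueError("sex mismatch between hip and MOF schedules")
    if hip.age_points != mof.age_points:
        raise ValueError("hip and MOF schedules must share the same age grid")
    mask = mof.values < hip.values
    return [float(a) for a in hip.ages[mask]]
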