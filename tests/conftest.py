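import numpy as np
import pytest

from fracrisk.hazard_engine import HazardFunction
from fracrisk.rate_tables import AgeRateSchedule, RatioSchedule
from fracrisk.synthetic import GompertzParams, make_synthetic_country


@pytest.fixture
def hip_schedule() -> AgeRateSchedule:
    return AgeRateSchedule(
        population_label="testland",
        sex="female",
        age_points=(50, 55, 60, 65, 70, 75, 80, 85, 90),
        rates=(10, 15, 25, 40, 65, 105, 170, 270, 430),
        kind="hip_incidence",
    )


@pytest.fixture
def mortality_schedule() -> AgeRateSchedule:
    return AgeRateSchedule(
        population_label="testland",
        sex="female",
        age_points=(50, 55, 60, 65, 70, 75, 80, 85, 90),
        rates=(600, 900, 1400, 2100, 3200, 4900, 7500, 11500, 17500),
        kind="mortality",
    )


@pytest.fixture
def ratio_schedule() -> RatioSchedule:
    return RatioSchedule(
        sex="female",
        age_points=(50, 60, 70, 80, 90),
        ratios=(5.0, 4.5, 4.0, 3.2, 2.4),
    )


@pytest.fixture
def synthetic_model():
    return make_synthetic_country(
        GompertzParams(base_rate=15.0, anchor_age=50.0, slope=0.085),
        GompertzParams(base_rate=900.0, anchor_age=50.0, slope=0.095, makeham=0.002),
        ratio_constant=4.0,
        population_label="synthetic-test",
    )


def constant_hazard(value: float, start: float = 50.0, years: int = 30) -> HazardFunction:
    return HazardFunction(start_age=start, values=(value,) * years)


def daily_step_probability(phi_vals, mu_vals, horizon=None, steps_per_year=365):
    """Independent fine-step oracle for the competing-risk integral.

    Midpoint Riemann accumulation of phi(t) * exp(-cumhaz(t)) with daily
    steps over consecutive one-year intervals; shares no code with the
    package's closed-form accumulation.
    """
    phi_vals = np.asarray(phi_vals, dtype=float)
    mu_vals = np.asarray(mu_vals, dtype=float)
    n_years = len(phi_vals) if horizon is None else int(horizon)
    h = 1.0 / steps_per_year
    prob = 0.0
    cum = 0.0
    for i in range(n_years):
        lam = phi_vals[i] + mu_vals[i]
        k = np.arange(steps_per_year)
        mid = cum + lam * h * (k + 0.5)
        prob += float(np.sum(phi_vals[i] * np.exp(-mid) * h))
        cum += lam
    return prob
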