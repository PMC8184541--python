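import json

import numpy as np
import pytest

from fracrisk.hazard_engine import ten_year_probability, to_hazard
from fracrisk.risk_adjustment import RiskProfile, profile_probability
from fracrisk.synthetic import (
    GompertzParams,
    RateEstimate,
    estimate_rates,
    fit_log_slope,
    gompertz_schedule,
    make_synthetic_country,
    poisson_exact_ci,
    sample_counts,
)


class TestGompertzSchedule:
    def test_flat_when_slope_zero(self):
        s = gompertz_schedule(GompertzParams(base_rate=10.0), ages=(50, 60, 70))
        assert s.rates == (10.0, 10.0, 10.0)

    def test_doubling_every_five_years(self):
        p = GompertzParams(base_rate=10.0, anchor_age=50.0, slope=np.log(2) / 5)
        s = gompertz_schedule(p, ages=(50, 55, 60))
        assert s.rates == pytest.approx((10.0, 20.0, 40.0), rel=1e-12)

    def test_closed_form_at_90(self):
        p = GompertzParams(base_rate=10.0, anchor_age=50.0, slope=np.log(2) / 5)
        s = gompertz_schedule(p, ages=tuple(range(50, 91, 5)))
        assert s.rates[-1] == pytest.approx(10.0 * 2**8, rel=1e-12)

    def test_makeham_term_additive(self):
        p = GompertzParams(base_rate=100.0, slope=0.0, makeham=0.001)
        s = gompertz_schedule(p, ages=(50,), kind="mortality")
        assert s.rates == (200.0,)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GompertzParams(base_rate=-1.0)
        with pytest.raises(ValueError):
            GompertzParams(base_rate=1.0, slope=-0.1)


class TestSampleCounts:
    def test_zero_rate_gives_zero_counts(self):
        s = gompertz_schedule(GompertzParams(base_rate=0.0), ages=(50, 60))
        assert np.all(sample_counts(s, 1e6, seed=1) == 0)

    def test_seed_determinism(self, hip_schedule):
        a = sample_counts(hip_schedule, 1e5, seed=42)
        b = sample_counts(hip_schedule, 1e5, seed=42)
        assert np.array_equal(a, b)
        c = sample_counts(hip_schedule, 1e5, seed=43)
        assert not np.array_equal(a, c)

    def test_poisson_moments(self):
        # rate 100 per 100k at PY 100k -> mean 100, variance 100
        s = gompertz_schedule(GompertzParams(base_rate=100.0), ages=(50,))
        draws = np.array(
            [sample_counts(s, 1e5, seed=seed)[0] for seed in range(1500)], dtype=float
        )
        assert draws.mean() == pytest.approx(100.0, abs=3 * 10 / np.sqrt(1500))
        assert draws.var() == pytest.approx(100.0, rel=0.15)

    def test_non_positive_exposure_rejected(self, hip_schedule):
        with pytest.raises(ValueError, match="positive"):
            sample_counts(hip_schedule, 0.0, seed=1)


class TestEstimateRates:
    def test_rate_arithmetic(self):
        est = estimate_rates([5], 50000.0, [60])
        assert est.schedule.rates == (10.0,)

    def test_zero_events_boundary(self):
        est = estimate_rates([0], 100000.0, [60])
        assert est.schedule.rates == (0.0,)
        assert est.ci_lower == (0.0,)
        assert est.ci_upper[0] > 0.0

    def test_garwood_interval(self):
        # 10 events in 100,000 PY -> 95% CI (4.80, 18.39) per 100,000
        lo, hi = poisson_exact_ci(10, 100000.0)
        assert lo == pytest.approx(4.7954, abs=1e-3)
        assert hi == pytest.approx(18.3904, abs=1e-3)

    def test_interval_attached_per_age(self):
        est = estimate_rates([10, 20], 100000.0, [60, 70])
        assert isinstance(est, RateEstimate)
        assert len(est.ci_lower) == len(est.ci_upper) == 2
        assert all(
            lo <= r <= hi
            for lo, r, hi in zip(est.ci_lower, est.schedule.rates, est.ci_upper)
        )


class TestFitLogSlope:
    def test_exact_recovery_on_noiseless_rates(self):
        p = GompertzParams(base_rate=20.0, anchor_age=50.0, slope=0.08)
        s = gompertz_schedule(p, ages=tuple(range(50, 91, 5)))
        slope, _ = fit_log_slope(s.ages, s.values)
        assert slope == pytest.approx(0.08, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_log_slope([50, 60], [1, 2])


class TestMakeSyntheticCountry:
    def test_zero_mortality_matches_pure_fracture_integral(self):
        model = make_synthetic_country(
            GompertzParams(base_rate=50.0, anchor_age=50.0, slope=0.05),
            GompertzParams(base_rate=0.0),
            ratio_constant=2.0,
        )
        res = profile_probability(model, RiskProfile(age=60, sex="female"))
        phi = to_hazard(model.schedule("female", "hip"), 60, 70)
        expected = 1 - np.exp(-phi.array.sum())
        assert res.p_hip == pytest.approx(expected, rel=1e-12)

    def test_small_hazard_probability_ratio_approaches_scale(self):
        mort = GompertzParams(base_rate=500.0, anchor_age=50.0, slope=0.09)
        base = GompertzParams(base_rate=0.01, anchor_age=50.0, slope=0.05)
        c = 3.0
        scaled = GompertzParams(base_rate=0.01 * c, anchor_age=50.0, slope=0.05)
        m1 = make_synthetic_country(base, mort, 2.0)
        m2 = make_synthetic_country(scaled, mort, 2.0)
        p1 = profile_probability(m1, RiskProfile(age=60, sex="female")).p_hip
        p2 = profile_probability(m2, RiskProfile(age=60, sex="female")).p_hip
        assert p2 / p1 == pytest.approx(c, rel=1e-4)

    def test_seeded_sampling_serialisation_deterministic(self, tmp_path):
        kwargs = dict(
            incidence_params=GompertzParams(base_rate=100.0, slope=0.08),
            mortality_params=GompertzParams(base_rate=1000.0, slope=0.09),
            ratio_constant=3.0,
            seed=7,
            person_years=1e5,
        )
        a, b = make_synthetic_country(**kwargs), make_synthetic_country(**kwargs)
        pa, pb = tmp_path / "a.json", tmp_path / "b.json"
        a.save(pa)
        b.save(pb)
        assert pa.read_text() == pb.read_text()

    def test_sampling_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            make_synthetic_country(
                GompertzParams(base_rate=10.0),
                GompertzParams(base_rate=100.0),
                person_years=1e5,
            )

    def test_both_sexes_present(self, synthetic_model):
        for sex in ("female", "male"):
            for outcome in ("hip", "mof", "mortality"):
                assert synthetic_model.schedule(sex, outcome).sex == sex

    def test_default_magnitudes_are_botswana_like(self, synthetic_model):
        # hip probabilities of order 0.2-1.5% over ages 50-90 for women
        probs = [
            100 * profile_probability(synthetic_model, RiskProfile(age=a, sex="female")).p_hip
            for a in range(50, 91, 5)
        ]
        assert 0.1 < min(probs) < 0.5
        assert 0.5 < max(probs) < 2.0


class TestPipelineRecovery:
    def test_probabilities_converge_to_truth_at_large_exposure(self):
        truth_inc = GompertzParams(base_rate=30.0, anchor_age=50.0, slope=0.08)
        mort = GompertzParams(base_rate=900.0, anchor_age=50.0, slope=0.09)
        exact = make_synthetic_country(truth_inc, mort, 3.0)
        sampled = make_synthetic_country(
            truth_inc, mort, 3.0, seed=11, person_years=1e7
        )
        for age in (55, 65, 75):
            p_true = profile_probability(exact, RiskProfile(age=age, sex="female")).p_mof
            p_est = profile_probability(sampled, RiskProfile(age=age, sex="female")).p_mof
            assert p_est == pytest.approx(p_true, rel=0.02)
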