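"""One-generation maps: closed form, special cases, multi-pulse, Beverton-Holt."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hormesis_ricker import (
    ModelParams,
    PulseSchedule,
    ebhm_step,
    hrm_step,
    multi_pulse_step,
    ricker_step,
    special_case_step,
    within_generation_trajectory,
)

positive_r = st.floats(min_value=0.0, max_value=5.0)
survival = st.floats(min_value=0.05, max_value=0.999)
timing = st.floats(min_value=0.0, max_value=1.0)
population = st.floats(min_value=1e-6, max_value=3.0)


class TestModelParams:
    @pytest.mark.parametrize("kwargs", [
        dict(r=-0.1, p=0.5, theta=0.5, K=1),
        dict(r=1, p=0.0, theta=0.5, K=1),
        dict(r=1, p=1.2, theta=0.5, K=1),
        dict(r=1, p=0.5, theta=1.5, K=1),
        dict(r=1, p=0.5, theta=0.5, K=0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParams(**kwargs)

    def test_dose_is_one_minus_survival(self):
        assert ModelParams(r=1, p=0.7, theta=0.2).q == pytest.approx(0.3)
        assert ModelParams.from_dose(1, 0.3, 0.2).p == pytest.approx(0.7)

    def test_r_zero_degenerates_to_pure_kill(self):
        p = ModelParams(r=0.0, p=0.6, theta=0.5, K=1)
        assert hrm_step(2.0, p) == pytest.approx(1.2)


class TestPulseSchedule:
    def test_unsorted_timings_rejected(self):
        with pytest.raises(ValueError):
            PulseSchedule(((0.5, 0.9), (0.3, 0.9)))

    def test_duplicate_timings_rejected(self):
        with pytest.raises(ValueError):
            PulseSchedule(((0.5, 0.9), (0.5, 0.8)))

    def test_empty_schedule_is_plain_ricker(self):
        assert multi_pulse_step(0.4, 1.7, 1.0, PulseSchedule()) == \
            pytest.approx(ricker_step(0.4, 1.7), rel=1e-15)


class TestHrmStep:
    def test_hand_value_at_theta_zero(self):
        # 0.5 * e^{0.5} for N=1, r=1, p=0.5, K=1
        p = ModelParams(r=1, p=0.5, theta=0, K=1)
        assert hrm_step(1.0, p) == pytest.approx(0.5 * math.exp(0.5), rel=1e-12)

    def test_carrying_capacity_is_fixed_point_without_dose(self):
        for th in (0.0, 0.3, 0.7, 1.0):
            p = ModelParams(r=2.3, p=1.0, theta=th, K=1.7)
            assert hrm_step(1.7, p) == pytest.approx(1.7, rel=1e-14)

    def test_end_of_generation_pulse_at_capacity(self):
        p = ModelParams(r=3.1, p=0.4, theta=1.0, K=2.0)
        assert hrm_step(2.0, p) == pytest.approx(0.8, rel=1e-14)

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            hrm_step(-0.1, ModelParams(r=1, p=0.5, theta=0.5))

    def test_zero_maps_to_zero(self):
        assert hrm_step(0.0, ModelParams(r=2, p=0.5, theta=0.5)) == 0.0

    def test_boundary_timings_match_printed_special_cases(self, rng):
        """theta=0 / theta=1 collapse to the printed maps within 4 ulp."""
        for _ in range(10_000):
            r = rng.uniform(0, 5)
            p = rng.uniform(0.05, 0.999)
            K = rng.uniform(0.1, 10)
            N = rng.uniform(0, 3) * K
            start = hrm_step(N, ModelParams(r=r, p=p, theta=0.0, K=K))
            end = hrm_step(N, ModelParams(r=r, p=p, theta=1.0, K=K))
            ref_s = special_case_step(N, ModelParams(r=r, p=p, theta=0.0, K=K), "start")
            ref_e = special_case_step(N, ModelParams(r=r, p=p, theta=1.0, K=K), "end")
            assert abs(start - ref_s) <= 4 * math.ulp(max(ref_s, 1e-300))
            assert abs(end - ref_e) <= 4 * math.ulp(max(ref_e, 1e-300))

    @given(r=positive_r, p=survival, theta=timing, N=population)
    @settings(max_examples=200, derandomize=True)
    def test_positivity(self, r, p, theta, N):
        assert hrm_step(N, ModelParams(r=r, p=p, theta=theta)) > 0

    @given(r=positive_r, p=survival, theta=timing, N=population,
           c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=200, derandomize=True)
    def test_scale_covariance(self, r, p, theta, N, c):
        """K is a pure scale: f(cN; cK) = c f(N; K)."""
        a = hrm_step(c * N, ModelParams(r=r, p=p, theta=theta, K=c))
        b = c * hrm_step(N, ModelParams(r=r, p=p, theta=theta, K=1.0))
        assert a == pytest.approx(b, rel=1e-10)

    @given(r=positive_r, theta=timing, N=population)
    @settings(max_examples=200, derandomize=True)
    def test_zero_dose_is_classic_ricker(self, r, theta, N):
        assert hrm_step(N, ModelParams(r=r, p=1.0, theta=theta)) == \
            pytest.approx(ricker_step(N, r), rel=1e-14)


class TestSpecialCaseStep:
    def test_start_hand_value(self):
        p = ModelParams(r=1, p=0.5, theta=0, K=1)
        assert special_case_step(1.0, p, "start") == \
            pytest.approx(0.5 * math.exp(0.5), rel=1e-14)

    def test_end_without_growth(self):
        p = ModelParams(r=0, p=0.7, theta=1, K=1)
        assert special_case_step(2.0, p, "end") == pytest.approx(1.4)

    def test_unknown_case_rejected(self):
        with pytest.raises(ValueError):
            special_case_step(1.0, ModelParams(r=1, p=0.5, theta=0), "middle")


class TestMultiPulseStep:
    @given(r=positive_r, p=survival,
           theta=st.floats(min_value=0.01, max_value=0.99), N=population)
    @settings(max_examples=300, derandomize=True)
    def test_single_pulse_equals_closed_form(self, r, p, theta, N):
        """The segment recursion at k=1 pins the closed-form parenthesization."""
        sched = PulseSchedule.single(theta, p)
        a = multi_pulse_step(N, r, 1.0, sched)
        b = hrm_step(N, ModelParams(r=r, p=p, theta=theta))
        assert a == pytest.approx(b, rel=1e-12)

    def test_example_single_pulse(self):
        sched = PulseSchedule.single(0.3, 0.6)
        assert multi_pulse_step(1.0, 2.0, 1.0, sched) == \
            pytest.approx(hrm_step(1.0, ModelParams(r=2, p=0.6, theta=0.3)), rel=1e-13)

    @given(r=positive_r, N=population)
    @settings(max_examples=100, derandomize=True)
    def test_all_unit_survivals_reduce_to_ricker(self, r, N):
        sched = PulseSchedule(((0.25, 1.0), (0.5, 1.0), (0.75, 1.0)))
        assert multi_pulse_step(N, r, 1.0, sched) == \
            pytest.approx(ricker_step(N, r), rel=1e-14)

    def test_three_early_equal_doses_rise_faster_than_one(self):
        """More low-dose stimulations accelerate the equilibrium rise in q."""
        from hormesis_ricker import find_equilibria, GenerationMap
        r, q = 2.5, 0.05

        def level(timings):
            sched = PulseSchedule.equal_doses(timings, 1.0 - q)
            gm = GenerationMap.schedule(r, 1.0, sched)
            eqs = find_equilibria(gm, search_max=4)
            return min(eqs.levels, key=lambda x: abs(x - 1.0))

        assert level([0.1, 0.2, 0.3]) > level([0.1]) > 1.0


class TestWithinGenerationTrajectory:
    def test_empty_schedule_endpoint_is_ricker(self):
        states = within_generation_trajectory(0.7, 1.3, 1.0, PulseSchedule(), [0.0, 1.0])
        assert states[-1].N == pytest.approx(ricker_step(0.7, 1.3), rel=1e-14)

    def test_pulse_is_multiplicative_drop(self):
        sched = PulseSchedule.single(0.5, 0.25)
        eps = 1e-9
        before, after = within_generation_trajectory(
            1.0, 2.0, 1.0, sched, [0.5 - eps, 0.5 + eps])
        # post/pre ratio ~ p (growth over 2 eps is negligible)
        assert after.N / before.N == pytest.approx(0.25, rel=1e-6)

    def test_endpoint_matches_multi_pulse_step(self, rng):
        for _ in range(200):
            r = rng.uniform(0, 4)
            k = rng.integers(0, 4)
            ths = np.sort(rng.uniform(0.05, 0.95, k))
            if len(set(ths)) < k:
                continue
            sched = PulseSchedule(tuple((t, rng.uniform(0.2, 1.0)) for t in ths))
            N = rng.uniform(0.05, 2.5)
            end = within_generation_trajectory(N, r, 1.0, sched, [1.0])[-1].N
            ref = multi_pulse_step(N, r, 1.0, sched)
            assert end == pytest.approx(ref, rel=1e-12)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError):
            within_generation_trajectory(1.0, 1.0, 1.0, PulseSchedule(), [0.5, 0.2])


class TestEbhmStep:
    def test_capacity_fixed_point_without_dose(self):
        assert ebhm_step(1.0, ModelParams(r=2, p=1, theta=0.5)) == pytest.approx(1.0)

    def test_pulse_after_full_growth(self):
        p = ModelParams(r=1.5, p=0.6, theta=1.0, K=1.0)
        e = math.exp(1.5)
        logistic_end = 0.5 * e / (1 + 0.5 * (e - 1))
        assert ebhm_step(0.5, p) == pytest.approx(0.6 * logistic_end, rel=1e-12)

    def test_equilibrium_never_increases_with_dose(self):
        """Compensatory logistic growth admits no hormetic dose response."""
        from hormesis_ricker import GenerationMap, find_equilibria
        for r in (0.5, 1, 2, 4):
            for th in (0.2, 0.5, 0.8):
                prev = None
                for q in np.linspace(0.0, 0.9, 19):
                    gm = GenerationMap.ebhm(ModelParams(r=r, p=1 - q, theta=th))
                    eqs = find_equilibria(gm, search_max=3)
                    level = eqs.levels[-1] if len(eqs) else 0.0
                    if prev is not None:
                        assert level <= prev + 1e-9
                    prev = level
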