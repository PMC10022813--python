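"""Intensity, compensator, and likelihood correctness against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from kyujo import (
    Cohort,
    EventHistory,
    HawkesParams,
    PoissonParams,
    compensator,
    intensity,
    log_likelihood_direct,
    log_likelihood_recursive,
    poisson_log_likelihood,
)
from conftest import (
    REFERENCE_PARAMS,
    quadrature_log_likelihood,
    random_micro_cohort,
    reduction_params,
)

EMPTY = EventHistory("empty", np.array([]), 2.0)


class TestIntensity:
    def test_baseline_before_first_event(self):
        assert intensity(REFERENCE_PARAMS, EMPTY, 0.2) == pytest.approx(2.685)
        h = EventHistory("x", np.array([0.5]), 1.0)
        assert intensity(REFERENCE_PARAMS, h, 0.4) == pytest.approx(2.685)

    def test_poisson_reduction(self):
        params = reduction_params(2.685)
        h = EventHistory("x", np.array([0.2, 0.5]), 1.0)
        for t in (0.1, 0.3, 0.9, 2.0):
            assert intensity(params, h, t) == pytest.approx(2.685, rel=1e-12)

    def test_term_by_term_after_one_event(self):
        # independent term-by-term arithmetic for history {0.5} at t = 0.6
        p = REFERENCE_PARAMS
        expected = (
            p.lambda0
            + p.a * p.b * 0.1 ** (p.b - 1.0)
            + p.alpha * math.exp(-0.1 * p.beta)
        )
        h = EventHistory("x", np.array([0.5]), 1.0)
        assert intensity(p, h, 0.6) == pytest.approx(expected, rel=1e-15)

    def test_jump_at_event_equals_alpha(self):
        p = REFERENCE_PARAMS
        h = EventHistory("x", np.array([0.3, 0.7]), 1.0)
        eps = 1e-9
        below = intensity(p, h, 0.7)
        above = intensity(p, h, 0.7 + eps)
        assert above - below == pytest.approx(p.alpha, rel=1e-5)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            intensity(REFERENCE_PARAMS, EMPTY, -0.1)
        with pytest.raises(ValueError):
            HawkesParams(lambda0=-1.0, a=1.0, b=2.0, alpha=1.0, beta=1.0)


class TestCompensator:
    def test_empty_interval_is_zero(self):
        h = EventHistory("x", np.array([0.3]), 1.0)
        assert compensator(REFERENCE_PARAMS, h, 0.5, 0.5) == 0.0

    def test_poisson_reduction_closed_form(self):
        params = reduction_params(3.0)
        h = EventHistory("x", np.array([0.2]), 1.0)
        assert compensator(params, h, 0.1, 0.9) == pytest.approx(3.0 * 0.8)

    def test_matches_quadrature(self):
        h = EventHistory("x", np.array([0.3, 0.7]), 1.0)
        value = compensator(REFERENCE_PARAMS, h, 0.7, 1.0)
        oracle = quad(
            lambda s: intensity(REFERENCE_PARAMS, h, s), 0.7, 1.0, limit=200
        )[0]
        assert value == pytest.approx(oracle, abs=1e-8)

    @pytest.mark.parametrize(
        "times, s, t",
        [
            ([], 0.0, 1.3),
            ([0.4], 0.0, 0.4),
            ([0.4], 0.2, 1.1),
            ([0.1, 0.5, 0.9], 0.3, 1.4),
        ],
    )
    def test_matches_quadrature_varied(self, times, s, t):
        h = EventHistory("x", np.array(times), 1.5)
        value = compensator(REFERENCE_PARAMS, h, s, t)
        pieces = [s, *[x for x in times if s < x < t], t]
        oracle = sum(
            quad(lambda u: intensity(REFERENCE_PARAMS, h, u), lo, hi, limit=200)[0]
            for lo, hi in zip(pieces[:-1], pieces[1:])
        )
        assert value == pytest.approx(oracle, abs=1e-8)

    @settings(deadline=None, derandomize=True)
    @given(
        points=st.tuples(
            st.floats(0.0, 1.5), st.floats(0.0, 1.5), st.floats(0.0, 1.5)
        )
    )
    def test_additive_over_abutting_intervals(self, points):
        s, u, t = sorted(points)
        h = EventHistory("x", np.array([0.25, 0.8]), 1.5)
        whole = compensator(REFERENCE_PARAMS, h, s, t)
        split = compensator(REFERENCE_PARAMS, h, s, u) + compensator(
            REFERENCE_PARAMS, h, u, t
        )
        assert whole == pytest.approx(split, abs=1e-10)

    def test_nondecreasing_in_t(self):
        h = EventHistory("x", np.array([0.25, 0.8]), 1.5)
        values = [compensator(REFERENCE_PARAMS, h, 0.0, t) for t in np.linspace(0, 1.5, 40)]
        assert np.all(np.diff(values) >= 0)

    def test_reversed_interval_rejected(self):
        with pytest.raises(ValueError):
            compensator(REFERENCE_PARAMS, EMPTY, 1.0, 0.5)


class TestLogLikelihood:
    def test_single_event_closed_form(self):
        cohort = Cohort(
            (EventHistory("solo", np.array([0.5]), 0.5, retirement_as_event=True),)
        )
        p = REFERENCE_PARAMS
        expected = math.log(p.lambda0) - p.lambda0 * 0.5
        assert log_likelihood_recursive(p, cohort) == pytest.approx(expected)
        assert log_likelihood_direct(p, cohort) == pytest.approx(expected)

    def test_two_athlete_fixture_matches_quadrature(self, fixture_suite):
        cohort = fixture_suite["two_athlete"]
        oracle = quadrature_log_likelihood(REFERENCE_PARAMS, cohort)
        assert log_likelihood_recursive(REFERENCE_PARAMS, cohort) == pytest.approx(
            oracle, abs=1e-6
        )

    def test_recursive_equals_direct_on_random_cohorts(self):
        rng = np.random.default_rng(12345)
        for _ in range(200):
            cohort = random_micro_cohort(rng)
            params = HawkesParams(
                lambda0=rng.uniform(0.5, 5.0),
                a=rng.uniform(0.1, 3.0),
                b=rng.uniform(0.5, 4.0),
                alpha=rng.uniform(0.1, 5.0),
                beta=rng.uniform(0.5, 15.0),
            )
            lr = log_likelihood_recursive(params, cohort)
            ld = log_likelihood_direct(params, cohort)
            assert lr == pytest.approx(ld, abs=1e-6)

    def test_poisson_reduction(self):
        rng = np.random.default_rng(3)
        cohort = random_micro_cohort(rng)
        lam = 2.5
        expected = sum(h.nu * math.log(lam) - lam * h.exposure_end for h in cohort)
        params = reduction_params(lam)
        assert log_likelihood_recursive(params, cohort) == pytest.approx(expected)
        assert log_likelihood_direct(params, cohort) == pytest.approx(expected)
        assert poisson_log_likelihood(PoissonParams(lam), cohort) == pytest.approx(
            expected
        )

    def test_empty_cohort_rejected(self, fixture_suite):
        empty = fixture_suite["empty"]
        with pytest.raises(ValueError):
            log_likelihood_recursive(REFERENCE_PARAMS, empty)
        with pytest.raises(ValueError):
            poisson_log_likelihood(PoissonParams(1.0), empty)


class TestPoissonLogLikelihood:
    def test_unit_case(self):
        cohort = Cohort(
            (EventHistory("x", np.array([1.0]), 1.0, retirement_as_event=True),)
        )
        assert poisson_log_likelihood(PoissonParams(1.0), cohort) == pytest.approx(-1.0)

    def test_maximized_at_closed_form_rate(self, fixture_suite):
        cohort = fixture_suite["two_athlete"]
        total_events = cohort.total_events
        exposure = sum(h.exposure_end for h in cohort)
        mle = total_events / exposure
        grid = np.linspace(0.01, 20.0, 400)
        values = [poisson_log_likelihood(PoissonParams(lam), cohort) for lam in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(mle, abs=0.05)

    def test_moving_away_from_mle_lowers_likelihood(self, fixture_suite):
        cohort = fixture_suite["two_athlete"]
        mle = cohort.total_events / sum(h.exposure_end for h in cohort)
        at_mle = poisson_log_likelihood(PoissonParams(mle), cohort)
        assert poisson_log_likelihood(PoissonParams(mle * 1.5), cohort) < at_mle
        assert poisson_log_likelihood(PoissonParams(mle * 0.5), cohort) < at_mle
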