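import numpy as np
import pytest
from scipy.integrate import quad

from kyujo import (
    Cohort,
    EventHistory,
    HawkesParams,
    intensity,
    make_fixture_suite,
)

# reference parameterization used throughout: the fitted change-point Hawkes
# model (lambda0, a, b, alpha, beta) and the fitted Poisson baseline rate
REFERENCE_PARAMS = HawkesParams(
    lambda0=2.685, a=1.399, b=2.689, alpha=2.866, beta=7.626
)
POISSON_RATE = 4.671

# near-zero trend/excitation: the Poisson-reduction limit of the model
REDUCTION_EPS = 1e-300


def reduction_params(lambda0: float, b: float = 2.0) -> HawkesParams:
    """Hawkes parameters numerically indistinguishable from an HPP."""
    return HawkesParams(lambda0=lambda0, a=REDUCTION_EPS, b=b,
                        alpha=REDUCTION_EPS, beta=1.0)


def quadrature_log_likelihood(params: HawkesParams, cohort: Cohort) -> float:
    """Independent counting-process log-likelihood with numerical integration."""
    total = 0.0
    for history in cohort:
        end = history.exposure_end
        for t_j in history.event_times:
            total += np.log(intensity(params, history, float(t_j)))
        breakpoints = [0.0, *history.event_times[history.event_times < end], end]
        integral = 0.0
        for lo, hi in zip(breakpoints[:-1], breakpoints[1:]):
            if hi > lo:
                integral += quad(
                    lambda s: intensity(params, history, s), lo, hi, limit=200
                )[0]
        total -= integral
    return total


def random_micro_cohort(rng: np.random.Generator, max_events: int = 5) -> Cohort:
    """Small random cohort (1-4 athletes, 0-max_events events each)."""
    histories = []
    for a in range(rng.integers(1, 5)):
        nu = int(rng.integers(0, max_events + 1))
        times = np.sort(rng.uniform(0.05, 1.4, nu))
        times = np.unique(times)
        end = float(times[-1]) if times.size else float(rng.uniform(0.4, 1.5))
        histories.append(
            EventHistory(f"m{a}", times, end, retirement_as_event=bool(times.size))
        )
    return Cohort(tuple(histories))


@pytest.fixture(scope="session")
def reference_params() -> HawkesParams:
    return REFERENCE_PARAMS


@pytest.fixture(scope="session")
def fixture_suite():
    return make_fixture_suite(seed=0)
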