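"""Synthetic cohorts with the statistical structure the analysis assumes.

Careers are simulated independently from the change-point Hawkes process
(one shared thinning engine with :mod:`kyujo.simulate`).  Three career
models cover the ways a career can end:

* ``fixed_horizon``  — every career observed for the same exposure
  (horizon-censored, retirement not an event);
* ``random_horizon`` — careers censored at uniform exposures, emulating a
  staggered-retirement cohort;
* ``event_count_stop`` — the k-th occurrence ends the career and is marked
  as the retirement event, reproducing the retirement-as-event convention
  at a stopping time of the process.

Division tiers for calibration are assigned by labelling an early fraction
of each career as lower-division exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .events import Cohort, EventHistory, merge_ties
from .process import HawkesParams
from .simulate import _simulate_times

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "make_fixture_suite",
    "early_career_division_labels",
]

# reference parameterization of the fitted model, used across examples
DEFAULT_PARAMS = HawkesParams(
    lambda0=2.685, a=1.399, b=2.689, alpha=2.866, beta=7.626
)

DEFAULT_RANDOM_HORIZON = (0.2, 1.6)  # staggered career lengths, player hours


@dataclass
class GeneratorConfig:
    """Configuration of a synthetic cohort.

    ``career_model`` is one of ``{"fixed_horizon": L}``,
    ``{"random_horizon": (low, high)}`` or ``{"event_count_stop": k}``.
    ``division_mix`` is the fraction of each career's early exposure
    labelled lower-division (tournament window 0.007 instead of 0.015).
    """

    params: HawkesParams = DEFAULT_PARAMS
    n_athletes: int = 209
    career_model: dict = field(
        default_factory=lambda: {"random_horizon": DEFAULT_RANDOM_HORIZON}
    )
    retirement_as_event: bool = True
    division_mix: float = 0.3
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.n_athletes < 1:
            raise ValueError("n_athletes must be at least 1")
        if len(self.career_model) != 1:
            raise ValueError("career_model must have exactly one entry")
        kind, value = next(iter(self.career_model.items()))
        if kind == "fixed_horizon":
            if float(value) <= 0:
                raise ValueError("fixed horizon must be positive")
        elif kind == "random_horizon":
            low, high = map(float, value)
            if not (0 < low <= high):
                raise ValueError("random horizon bounds must satisfy 0 < low <= high")
        elif kind == "event_count_stop":
            if int(value) < 1:
                raise ValueError("event_count_stop must be at least 1")
        else:
            raise ValueError(f"unknown career model {kind!r}")
        if not 0.0 <= self.division_mix <= 1.0:
            raise ValueError("division_mix must lie in [0, 1]")


_MAX_STOP_EXPOSURE = 50.0  # safety cap for event_count_stop careers


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Simulate ``n_athletes`` independent careers under the configured model."""
    rng = np.random.default_rng(config.seed)
    kind, value = next(iter(config.career_model.items()))
    histories = []
    width = len(str(config.n_athletes))
    for i in range(config.n_athletes):
        athlete_id = f"ath{i:0{width}d}"
        if kind == "fixed_horizon":
            horizon = float(value)
            times = np.asarray(
                _simulate_times(config.params, 0.0, horizon, np.empty(0), rng)
            )
            history = EventHistory(
                athlete_id, times, horizon, retirement_as_event=False
            )
        elif kind == "random_horizon":
            low, high = map(float, value)
            horizon = float(rng.uniform(low, high))
            times = np.asarray(
                _simulate_times(config.params, 0.0, horizon, np.empty(0), rng)
            )
            history = EventHistory(
                athlete_id, times, horizon, retirement_as_event=False
            )
        else:  # event_count_stop: the k-th occurrence is the retirement
            k = int(value)
            times: list[float] = []
            t = 0.0
            while len(times) < k and t < _MAX_STOP_EXPOSURE:
                chunk_end = t + 1.0
                times.extend(
                    _simulate_times(
                        config.params, t, chunk_end, np.asarray(times), rng
                    )
                )
                t = chunk_end
            times = np.asarray(times[:k])
            if times.size < k:  # pragma: no cover - cap never binds in practice
                raise RuntimeError("event_count_stop career exceeded exposure cap")
            history = EventHistory(
                athlete_id,
                times,
                float(times[-1]),
                retirement_as_event=config.retirement_as_event,
            )
        histories.append(merge_ties(history))
    return Cohort(tuple(histories))


def early_career_division_labels(
    cohort: Cohort, lower_fraction: float
) -> Callable[[str, float], str]:
    """Tier labeller: the first ``lower_fraction`` of each career is lower-division."""
    cutoffs = {h.athlete_id: lower_fraction * h.career_end for h in cohort}
    return lambda athlete_id, t: "lower" if t < cutoffs[athlete_id] else "top"


def make_fixture_suite(seed: int = 0) -> dict[str, Cohort]:
    """Deterministic micro-cohorts with hand-checkable likelihood values."""
    rng = np.random.default_rng(seed)
    suite: dict[str, Cohort] = {
        "single_event": Cohort(
            (EventHistory("solo", np.array([0.5]), 0.5, retirement_as_event=True),)
        ),
        "two_athlete": Cohort(
            (
                EventHistory("a", np.array([0.3]), 0.3, retirement_as_event=True),
                EventHistory(
                    "b", np.array([0.2, 0.6, 0.9]), 0.9, retirement_as_event=True
                ),
            )
        ),
        "empty": Cohort(()),
    }
    for idx in range(3):
        histories = []
        for a in range(rng.integers(2, 5)):
            nu = int(rng.integers(0, 5))
            times = np.sort(rng.uniform(0.05, 1.4, nu))
            end = float(times[-1]) if nu else float(rng.uniform(0.5, 1.5))
            histories.append(
                EventHistory(
                    f"r{idx}_{a}",
                    times,
                    end,
                    retirement_as_event=bool(nu),
                )
            )
        suite[f"random_{idx}"] = Cohort(tuple(histories))
    return suite
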