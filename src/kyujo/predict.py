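"""Forward risk: per-athlete next-event probability and team count distribution.

The probability that athlete i's next (j-th) absence occurs within a window
of w player hours from current exposure t is

    p_ij(w|t) = 1 - exp(-lambda0*w)          if the athlete has no history
              = 1 - exp(-Lambda(t, t+w))     otherwise,

with the compensator conditioned on the frozen history H_t (no hypothetical
events inside the window add excitation).  One top-division tournament is
w = 0.015 player hours; a lower-division tournament is w = 0.007.

Summing independent per-athlete Bernoulli risks gives the number of absent
athletes in a tournament, a Poisson-binomial random variable whose pmf is
computed exactly by convolution and whose moments are sum(p) and
sum(p*(1-p)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import EventHistory
from .process import HawkesParams, compensator

__all__ = [
    "WindowMap",
    "CountDistribution",
    "next_event_probability",
    "expected_first_event_time",
    "count_distribution",
    "TOP_DIVISION_WINDOW",
    "LOWER_DIVISION_WINDOW",
]

TOP_DIVISION_WINDOW = 0.015
LOWER_DIVISION_WINDOW = 0.007


@dataclass(frozen=True)
class WindowMap:
    """Tournament length in player hours per division tier."""

    top: float = TOP_DIVISION_WINDOW
    lower: float = LOWER_DIVISION_WINDOW

    def __post_init__(self) -> None:
        if self.top <= 0 or self.lower <= 0:
            raise ValueError("tournament windows must be positive")

    def __getitem__(self, tier: str) -> float:
        if tier == "top":
            return self.top
        if tier == "lower":
            return self.lower
        raise KeyError(f"unknown division tier {tier!r}")


def next_event_probability(
    params: HawkesParams,
    history: EventHistory | None,
    t: float,
    w: float,
) -> float:
    """Probability of the next absence within (t, t+w] given history H_t.

    For an athlete with no prior events the probability is
    1 - exp(-lambda0*w), independent of t.  Otherwise it is the survival
    complement 1 - exp(-Lambda(t, t+w)) of the first post-t event under the
    frozen history; nondecreasing in w, zero at w = 0.
    """
    w = float(w)
    if w < 0:
        raise ValueError("window length must be nonnegative")
    if history is None or history.nu == 0:
        return float(-np.expm1(-params.lambda0 * w))
    t = float(t)
    last = float(history.event_times[-1])
    if t < last - 1e-12:
        raise ValueError(
            f"prediction time {t} precedes the last recorded event {last}"
        )
    t = max(t, last)
    lam = compensator(params, history, t, t + w)
    return float(-np.expm1(-lam))


def expected_first_event_time(params: HawkesParams) -> float:
    """Mean exposure to the first absence, 1/lambda0 (stage-I process is HPP)."""
    return 1.0 / params.lambda0


@dataclass
class CountDistribution:
    """Poisson-binomial distribution of the number of absent athletes."""

    pmf: np.ndarray
    expectation: float
    variance: float

    def __post_init__(self) -> None:
        self.pmf = np.asarray(self.pmf, dtype=float)
        total = self.pmf.sum()
        if not np.isclose(total, 1.0, atol=1e-10):
            raise ValueError(f"pmf sums to {total}, not 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.pmf.size)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.pmf)

    def interval(self, level: float = 0.95) -> tuple[int, int]:
        """Central interval by the (1-level)/2 and 1-(1-level)/2 pmf percentiles."""
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
        tail = (1.0 - level) / 2.0
        cdf = self.cdf()
        lower = int(np.searchsorted(cdf, tail))
        upper = int(np.searchsorted(cdf, 1.0 - tail))
        return lower, upper


def count_distribution(probabilities: Sequence[float]) -> CountDistribution:
    """Exact Poisson-binomial pmf of a sum of independent Bernoulli risks.

    Computed by iterative convolution (O(n^2)), which is exact and replaces
    the defining 2^n subset sum.  Moments use the closed forms
    E[X] = sum(p_i), V[X] = sum(p_i*(1-p_i)).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1:
        raise ValueError("probabilities must be a flat sequence")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.ones(1)
    for pi in p:
        new = np.zeros(pmf.size + 1)
        new[: pmf.size] += pmf * (1.0 - pi)
        new[1:] += pmf * pi
        pmf = new
    return CountDistribution(
        pmf=pmf,
        expectation=float(p.sum()),
        variance=float(np.sum(p * (1.0 - p))),
    )
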