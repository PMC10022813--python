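"""Change-point Hawkes intensity, compensator, and log-likelihoods.

The conditional intensity of one athlete's absence process is

    lambda(t | H_t) = lambda0                                    for t <= T_1
                    = lambda0 + a*b*(t - T_1)^(b-1)
                      + sum_{T_j < t} alpha * exp(-beta*(t - T_j))  for t > T_1

where T_1 is the first occurrence (the change point separating the stable
"random failure" stage from the wear-out stage), a, b shape the power-law
wear-out trend and alpha, beta are the self-excitation jump and decay.
Setting a = alpha = 0 recovers the homogeneous Poisson process with rate
lambda0.

The compensator Lambda(s, t) = int_s^t lambda(u|H) du has a closed form,
which drives the likelihood, forward prediction and residual analysis.
The log-likelihood is available both in the direct counting-process form
and in Ogata's recursive form; the two agree to floating-point accuracy
and the recursion is the one used for fitting.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .events import Cohort, EventHistory

__all__ = [
    "HawkesParams",
    "PoissonParams",
    "intensity",
    "compensator",
    "log_likelihood_recursive",
    "log_likelihood_direct",
    "poisson_log_likelihood",
]


@dataclass(frozen=True)
class HawkesParams:
    """The five parameters of the change-point Hawkes intensity.

    All rates are per player hour (1,000 bouts).

    lambda0 : baseline rate before the first occurrence (> 0)
    a, b    : scale and shape of the power-law trend a*b*(t-T_1)^(b-1) (> 0)
    alpha   : excitation jump added at each occurrence (> 0)
    beta    : exponential decay rate of the excitation (> 0)
    """

    lambda0: float
    a: float
    b: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {value}")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda0, self.a, self.b, self.alpha, self.beta])

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "HawkesParams":
        lam, a, b, alpha, beta = map(float, theta)
        return cls(lam, a, b, alpha, beta)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "HawkesParams":
        path = Path(source)
        data = json.loads(path.read_text() if path.exists() else str(source))
        return cls(**{k: float(data[k]) for k in ("lambda0", "a", "b", "alpha", "beta")})


@dataclass(frozen=True)
class PoissonParams:
    """Homogeneous Poisson baseline: constant intensity lambda0 > 0."""

    lambda0: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.lambda0) or self.lambda0 <= 0:
            raise ValueError(f"lambda0 must be finite and > 0, got {self.lambda0}")


def _check_time(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def intensity(
    params: HawkesParams, history: EventHistory, t: float | np.ndarray
) -> float | np.ndarray:
    """Conditional intensity at time(s) ``t`` given the events before ``t``.

    Left-continuous: events at exactly ``t`` do not contribute, so the value
    just after an occurrence exceeds the value at it by exactly ``alpha``
    (plus the vanishing trend increment when b > 1).
    """
    t_arr = np.atleast_1d(_check_time(t))
    times = history.event_times
    out = np.full(t_arr.shape, params.lambda0)
    if times.size:
        t1 = times[0]
        after = t_arr > t1
        if np.any(after):
            dt1 = t_arr[after] - t1
            trend = params.a * params.b * np.power(dt1, params.b - 1.0)
            # excitation from events strictly before each evaluation time
            diffs = t_arr[after, None] - times[None, :]
            exc = np.where(diffs > 0, np.exp(-params.beta * diffs), 0.0).sum(axis=1)
            out[after] = params.lambda0 + trend + params.alpha * exc
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out[0])
    return out


def compensator(
    params: HawkesParams, history: EventHistory, s: float, t: float
) -> float:
    """Expected number of events on (s, t] given the frozen history.

    Closed form:

        lambda0*(t-s) + a*[((t-T_1)_+)^b - ((s-T_1)_+)^b]
        + sum_{T_j < t} (alpha/beta) * [exp(-beta*(max(s,T_j)-T_j))
                                        - exp(-beta*(t-T_j))]

    The history is held fixed: events of ``history`` lying inside (s, t]
    excite only from their own occurrence time onward, and no hypothetical
    new events are added.  Additive over abutting intervals.
    """
    s = float(s)
    t = float(t)
    if s < 0:
        raise ValueError("interval start must be nonnegative")
    if s > t:
        raise ValueError(f"interval start {s} exceeds end {t}")
    if s == t:
        return 0.0
    total = params.lambda0 * (t - s)
    times = history.event_times
    if times.size:
        t1 = times[0]
        total += params.a * (
            max(t - t1, 0.0) ** params.b - max(s - t1, 0.0) ** params.b
        )
        active = times[times < t]
        if active.size:
            start = np.maximum(s, active)
            total += (params.alpha / params.beta) * np.sum(
                np.exp(-params.beta * (start - active))
                - np.exp(-params.beta * (t - active))
            )
    return float(total)


def _history_terms(
    params: HawkesParams, times: np.ndarray, end: float
) -> float:
    """Log-likelihood contribution of one athlete via Ogata's recursion.

    ``times`` are the merged occurrence times, ``end`` the exposure end
    (final event under retirement-as-event, otherwise the censoring time).
    """
    lam0, a, b, alpha, beta = (
        params.lambda0,
        params.a,
        params.b,
        params.alpha,
        params.beta,
    )
    if times.size == 0:
        return -lam0 * end
    t1 = times[0]
    # h(t_j): baseline + trend, the no-excitation part of the intensity
    h = np.full(times.shape, lam0)
    if times.size > 1:
        h[1:] += a * b * np.power(times[1:] - t1, b - 1.0)
    # R(j) = sum_{k<j} exp(-beta*(t_j - t_k)), computed in log space so that
    # large beta*t never overflows
    r = np.zeros(times.shape)
    if times.size > 1:
        c = beta * times
        acc = np.logaddexp.accumulate(c)
        r[1:] = np.exp(acc[:-1] - c[1:])
    event_term = float(np.sum(np.log(h + alpha * r)))
    trend_integral = lam0 * end + a * (end - t1) ** b
    excitation_integral = float(
        (alpha / beta) * np.sum(1.0 - np.exp(-beta * (end - times)))
    )
    return event_term - trend_integral - excitation_integral


def log_likelihood_recursive(params: HawkesParams, cohort: Cohort) -> float:
    """Cohort log-likelihood via Ogata's recursive formula.

    Each athlete contributes

        sum_j log(h(t_j) + alpha*R(j)) - int_0^T h(s) ds
        - sum_j (alpha/beta)*(1 - exp(-beta*(T - t_j)))

    with h(t) = lambda0 for t <= t_1, lambda0 + a*b*(t-t_1)^(b-1) after, and
    R(1) = 0, R(j) = exp(-beta*(t_j - t_{j-1}))*(1 + R(j-1)).  T is the
    athlete's exposure end.  Zero-event (censored) athletes contribute the
    pure survival term -lambda0*T.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    return float(
        sum(
            _history_terms(params, h.event_times, h.exposure_end)
            for h in cohort
        )
    )


def log_likelihood_direct(params: HawkesParams, cohort: Cohort) -> float:
    """Cohort log-likelihood in the direct counting-process form.

    sum_i { sum_j log lambda(t_ij | events before t_ij) - Lambda(0, T_i) },
    evaluated with :func:`intensity` and the closed-form :func:`compensator`.
    Serves as the cross-check for :func:`log_likelihood_recursive`.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    total = 0.0
    for history in cohort:
        end = history.exposure_end
        for t_j in history.event_times:
            total += np.log(intensity(params, history, t_j))
        total -= compensator(params, history, 0.0, end)
    return float(total)


def poisson_log_likelihood(params: PoissonParams, cohort: Cohort) -> float:
    """Homogeneous-Poisson log-likelihood sum_i (nu_i log lambda0 - lambda0*T_i)."""
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    lam = params.lambda0
    return float(
        sum(h.nu * np.log(lam) - lam * h.exposure_end for h in cohort)
    )
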