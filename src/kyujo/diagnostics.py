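"""Model checking: empirical failure rate, time-rescaling residuals, calibration.

Three complementary views of fit quality:

* the empirical failure rate r(t) — per time bin, the fraction of athletes
  active at t who have an event in (t, t+dt]; its two-stage shape (flat
  until the mean first-event time tau, then increasing) is the feature the
  change-point model encodes;
* time-rescaling residuals — transformed arrival times tau_j accumulated
  through the fitted compensator; if the model is right, the durations
  tau_j - tau_{j-1} are unit-exponential and u = 1 - exp(-duration) is
  Uniform[0,1], checked with a one-sample Kolmogorov-Smirnov test;
* calibration — predicted per-tournament absence probabilities binned on
  [0, 0.3] in steps of 0.05 against the observed event fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .events import Cohort, EventHistory
from .predict import WindowMap
from .process import HawkesParams, compensator

__all__ = [
    "FailureRateSeries",
    "ResidualSeries",
    "CalibrationTable",
    "empirical_failure_rate",
    "rescaled_residuals",
    "uniformity_test",
    "calibrate",
]

CALIBRATION_EDGES = np.arange(0.0, 0.30001, 0.05)


@dataclass
class FailureRateSeries:
    """Binned empirical failure rate with at-risk denominators."""

    bin_starts: np.ndarray
    rates: np.ndarray  # NaN where no athlete is at risk
    at_risk: np.ndarray
    dt: float
    tau: float  # mean first-event time (stage boundary)


@dataclass
class ResidualSeries:
    """Rescaled arrival times and their probability-integral transforms."""

    athlete_id: str
    tau_values: np.ndarray
    durations: np.ndarray
    u_values: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.tau_values) < -1e-12):
            raise ValueError("rescaled times must be nondecreasing")
        if np.any((self.u_values < 0) | (self.u_values > 1)):
            raise ValueError("u values must lie in [0, 1]")


@dataclass
class CalibrationTable:
    """Predicted-vs-observed absence probabilities per probability bin."""

    bin_edges: np.ndarray
    predicted: np.ndarray  # NaN for empty bins
    observed: np.ndarray
    sample_sizes: np.ndarray
    overflow_predicted: float
    overflow_observed: float
    overflow_size: int


def empirical_failure_rate(cohort: Cohort, dt: float = 0.05) -> FailureRateSeries:
    """Empirical failure rate r(t) on bins [0, dt), [dt, 2dt), ...

    r(t) = #{athletes active at t with an event in (t, t+dt]} /
           #{athletes active at t},  active meaning career_end >= t.
    Bins with an empty denominator carry NaN.  tau is the mean first-event
    time over athletes with at least one event.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    t_max = max(h.career_end for h in cohort)
    n_bins = int(np.ceil(t_max / dt))
    starts = np.arange(n_bins) * dt
    at_risk = np.zeros(n_bins, dtype=np.int64)
    hits = np.zeros(n_bins, dtype=np.int64)
    for history in cohort:
        active = starts <= history.career_end
        at_risk += active
        if history.nu:
            # bins whose (start, start+dt] contains at least one event;
            # an athlete counts once per bin however many events fall in it
            event_bins = np.unique(np.ceil(history.event_times / dt).astype(int) - 1)
            event_bins = event_bins[(event_bins >= 0) & (event_bins < n_bins)]
            hits[event_bins] += active[event_bins]
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(at_risk > 0, hits / np.maximum(at_risk, 1), np.nan)
    first_times = [h.event_times[0] for h in cohort if h.nu > 0]
    tau = float(np.mean(first_times)) if first_times else float("nan")
    return FailureRateSeries(
        bin_starts=starts, rates=rates, at_risk=at_risk, dt=float(dt), tau=tau
    )


def rescaled_residuals(
    params: HawkesParams, history: EventHistory
) -> ResidualSeries:
    """Random-time-change residuals of one athlete under given parameters.

    tau_1 = Lambda(0, t_1), tau_j = tau_{j-1} + Lambda(t_{j-1}, t_j).  Under
    the true model the durations are iid Exp(1), and u = 1 - exp(-duration)
    is the exact probability-integral transform to Uniform[0,1].
    """
    if history.nu < 1:
        raise ValueError("residuals require at least one event")
    times = history.event_times
    bounds = np.concatenate([[0.0], times])
    durations = np.array(
        [
            compensator(params, history, bounds[j], bounds[j + 1])
            for j in range(times.size)
        ]
    )
    tau = np.cumsum(durations)
    u = -np.expm1(-durations)
    return ResidualSeries(
        athlete_id=history.athlete_id,
        tau_values=tau,
        durations=durations,
        u_values=u,
    )


def uniformity_test(u_values: Sequence[float]) -> dict[str, float | bool]:
    """One-sample Kolmogorov-Smirnov test of u values against Uniform[0,1]."""
    u = np.asarray(u_values, dtype=float)
    if u.size < 1:
        raise ValueError("at least one value is required")
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u values must lie in [0, 1]")
    result = stats.kstest(u, "uniform")
    return {
        "statistic": float(result.statistic),
        "p_value": float(result.pvalue),
        "reject_at_5pct": bool(result.pvalue < 0.05),
    }


def _predicted_probabilities(
    params: HawkesParams, history: EventHistory, grid: np.ndarray, w: float
) -> np.ndarray:
    """Vectorized p(w|t) over a grid of evaluation times, frozen history.

    At each t, only events at or before t condition the prediction; the
    trend is active only once the first event lies in the past.
    """
    lam0, a, b, alpha, beta = (
        params.lambda0,
        params.a,
        params.b,
        params.alpha,
        params.beta,
    )
    times = history.event_times
    lam = np.full(grid.shape, lam0 * w)
    if times.size:
        t1 = times[0]
        started = grid >= t1
        if np.any(started):
            g = grid[started]
            lam[started] += a * (
                np.power(g + w - t1, b) - np.power(np.maximum(g - t1, 0.0), b)
            )
            diffs = g[:, None] - times[None, :]
            mask = diffs >= 0
            lam[started] += (alpha / beta) * np.sum(
                np.where(mask, np.exp(-beta * np.maximum(diffs, 0.0)), 0.0)
                - np.where(mask, np.exp(-beta * (np.maximum(diffs, 0.0) + w)), 0.0),
                axis=1,
            )
    return -np.expm1(-lam)


def calibrate(
    params: HawkesParams,
    cohort: Cohort,
    windows: WindowMap | None = None,
    division_labels: Callable[[str, float], str] | None = None,
) -> CalibrationTable:
    """Predicted versus observed per-tournament absence probabilities.

    For every athlete, tournaments start at t = 0, w, 2w, ... up to the
    career end, with w the tier window (0.015 for the top two divisions,
    0.007 otherwise; tiers via ``division_labels(athlete_id, t)``, default
    all top).  Predictions are binned on [0, 0.3] in 0.05 steps; larger
    predictions go to a reported overflow bin.
    """
    if windows is None:
        windows = WindowMap()
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    preds: list[np.ndarray] = []
    obs: list[np.ndarray] = []
    for history in cohort:
        t = 0.0
        grid = []
        grid_w = []
        while t < history.career_end:
            tier = (
                "top"
                if division_labels is None
                else division_labels(history.athlete_id, t)
            )
            w = windows[tier]
            grid.append(t)
            grid_w.append(w)
            t += w
        grid = np.asarray(grid)
        grid_w = np.asarray(grid_w)
        for w in np.unique(grid_w):
            sel = grid_w == w
            g = grid[sel]
            preds.append(_predicted_probabilities(params, history, g, float(w)))
            times = history.event_times
            hit = (
                (times[None, :] > g[:, None]) & (times[None, :] <= (g + w)[:, None])
            ).any(axis=1)
            obs.append(hit.astype(float))
    predicted = np.concatenate(preds)
    observed = np.concatenate(obs)

    edges = CALIBRATION_EDGES
    n_bins = edges.size - 1
    mean_pred = np.full(n_bins, np.nan)
    mean_obs = np.full(n_bins, np.nan)
    sizes = np.zeros(n_bins, dtype=np.int64)
    idx = np.digitize(predicted, edges[1:-1], right=False)
    in_range = predicted < edges[-1]
    for k in range(n_bins):
        sel = in_range & (idx == k)
        sizes[k] = int(sel.sum())
        if sizes[k]:
            mean_pred[k] = float(predicted[sel].mean())
            mean_obs[k] = float(observed[sel].mean())
    over = ~in_range
    return CalibrationTable(
        bin_edges=edges,
        predicted=mean_pred,
        observed=mean_obs,
        sample_sizes=sizes,
        overflow_predicted=float(predicted[over].mean()) if over.any() else float("nan"),
        overflow_observed=float(observed[over].mean()) if over.any() else float("nan"),
        overflow_size=int(over.sum()),
    )
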