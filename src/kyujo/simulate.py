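"""Exact simulation by thinning, Monte-Carlo count bands, rest scenarios.

The change-point Hawkes process is simulated exactly with Ogata's thinning:
on each lookahead window the intensity is dominated by a piecewise bound
(the power-law trend is nondecreasing for b >= 1, the excitation is
nonincreasing between events), candidate points are drawn from the bounding
homogeneous process and accepted with probability lambda(t)/M.  The bound
is asserted at run time.  b < 1 would make the trend singular at the change
point and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventHistory, merge_ties
from .process import HawkesParams

__all__ = [
    "SimulationSummary",
    "ScenarioResult",
    "simulate_history",
    "simulate_count_bands",
    "scenario_rest",
]

_LOOKAHEAD = 0.1  # player hours per thinning window


@dataclass
class SimulationSummary:
    """Pointwise Monte-Carlo summary of cumulative event counts."""

    time_grid: np.ndarray
    mean_count: np.ndarray
    lower_band: np.ndarray
    upper_band: np.ndarray
    level: float
    n_reps: int
    seed: int | None

    def __post_init__(self) -> None:
        if np.any(self.lower_band > self.mean_count + 1e-9) or np.any(
            self.mean_count > self.upper_band + 1e-9
        ):
            raise ValueError("percentile bands must bracket the mean")


@dataclass
class ScenarioResult:
    """Distribution of additional events after a prescribed rest period."""

    count_pmf: dict[int, float]
    mean_count: float
    prob_at_least: dict[int, float]
    n_reps: int
    seed: int | None

    def __post_init__(self) -> None:
        total = sum(self.count_pmf.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"count pmf sums to {total}, not 1")


def _simulate_times(
    params: HawkesParams,
    t_start: float,
    horizon: float,
    init_times: np.ndarray,
    rng: np.random.Generator,
) -> list[float]:
    """New event times on (t_start, horizon] by thinning, given past events."""
    if params.b < 1.0:
        raise ValueError(
            "simulation requires b >= 1 (the trend bound is invalid for b < 1)"
        )
    lam0, a, b, alpha, beta = (
        params.lambda0,
        params.a,
        params.b,
        params.alpha,
        params.beta,
    )
    t1 = float(init_times[0]) if init_times.size else None
    # running excitation sum A(s) = sum_j exp(-beta*(s - T_j)) at current time s
    s = float(t_start)
    if init_times.size:
        exc = float(np.sum(np.exp(-beta * (s - init_times))))
    else:
        exc = 0.0
    new_times: list[float] = []

    def trend(t: float) -> float:
        if t1 is None or t <= t1:
            return 0.0
        return a * b * (t - t1) ** (b - 1.0)

    while s < horizon:
        window_end = min(s + _LOOKAHEAD, horizon)
        # dominating rate on (s, window_end]: trend evaluated at the window
        # end (nondecreasing for b >= 1), excitation at the window start
        bound = lam0 + trend(window_end) + alpha * exc
        wait = rng.exponential(1.0 / bound)
        if s + wait > window_end:
            exc *= np.exp(-beta * (window_end - s))
            s = window_end
            continue
        t_prop = s + wait
        exc *= np.exp(-beta * wait)
        lam = lam0 + trend(t_prop) + alpha * exc
        assert lam <= bound * (1.0 + 1e-9), "thinning bound violated"
        s = t_prop
        if rng.random() * bound <= lam:
            new_times.append(t_prop)
            if t1 is None:
                t1 = t_prop
            exc += 1.0
    return new_times


def simulate_history(
    params: HawkesParams,
    horizon: float,
    seed: int | np.random.Generator | None = None,
    initial_history: EventHistory | None = None,
    t_start: float | None = None,
    athlete_id: str = "sim",
) -> EventHistory:
    """Draw one trajectory of the process on (t_start, horizon].

    The baseline is constant until the first event; afterwards the power-law
    trend and exponentially decaying excitation are active.  With an
    ``initial_history`` the simulation continues that athlete's process
    forward from ``t_start`` (default: the last recorded event).
    """
    if params.b < 1.0:
        raise ValueError(
            "simulation requires b >= 1 (the trend bound is invalid for b < 1)"
        )
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    init = (
        initial_history.event_times
        if initial_history is not None
        else np.empty(0)
    )
    if t_start is None:
        t_start = float(init[-1]) if init.size else 0.0
    if init.size and t_start < init[-1]:
        raise ValueError("t_start precedes the last event of the initial history")
    if t_start > horizon:
        raise ValueError("t_start exceeds the horizon")
    new = _simulate_times(params, t_start, horizon, init, rng)
    times = np.concatenate([init, np.asarray(new)])
    return EventHistory(
        athlete_id=athlete_id,
        event_times=times,
        career_end=float(horizon),
        retirement_as_event=False,
    )


def simulate_count_bands(
    params: HawkesParams,
    horizon: float,
    n_reps: int = 10_000,
    grid: np.ndarray | None = None,
    level: float = 0.05,
    seed: int | None = None,
) -> SimulationSummary:
    """Mean cumulative count and pointwise percentile bands over replicates.

    The 100*(1-c)% band at each grid point is the c/2 and 1-c/2 percentile
    of the replicate cumulative counts, with c = ``level``.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be at least 100 for percentile bands")
    if grid is None:
        grid = np.linspace(0.0, horizon, 51)[1:]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid is empty")
    rng = np.random.default_rng(seed)
    counts = np.empty((n_reps, grid.size), dtype=np.int64)
    for rep in range(n_reps):
        times = np.asarray(
            _simulate_times(params, 0.0, float(horizon), np.empty(0), rng)
        )
        counts[rep] = np.searchsorted(times, grid, side="right")
    lower = np.percentile(counts, 100.0 * (level / 2.0), axis=0)
    upper = np.percentile(counts, 100.0 * (1.0 - level / 2.0), axis=0)
    return SimulationSummary(
        time_grid=grid,
        mean_count=counts.mean(axis=0),
        lower_band=lower,
        upper_band=upper,
        level=level,
        n_reps=n_reps,
        seed=seed if not isinstance(seed, np.random.Generator) else None,
    )


def scenario_rest(
    params: HawkesParams,
    history: EventHistory,
    rest_start: float,
    rest_length: float,
    eval_end: float,
    n_reps: int = 10_000,
    seed: int | None = None,
    thresholds: tuple[int, ...] | None = None,
) -> ScenarioResult:
    """Distribution of additional events after an enforced rest period.

    The rest itself is an absence beginning at ``rest_start`` and, under the
    tie convention, merges with any recorded event at that time; during
    [rest_start, rest_start + rest_length] no bouts are played so no new
    events can occur, while the excitation keeps decaying.  Events are then
    simulated and counted on (rest_start + rest_length, eval_end].
    """
    rest_start = float(rest_start)
    rest_length = float(rest_length)
    eval_end = float(eval_end)
    if rest_length < 0:
        raise ValueError("rest_length must be nonnegative")
    if history.nu and rest_start < history.event_times[-1] - 1e-12:
        raise ValueError("rest_start precedes the last recorded event")
    rest_end = rest_start + rest_length
    if rest_end > eval_end + 1e-12:
        raise ValueError("rest period extends past the evaluation end")
    conditioned = merge_ties(
        EventHistory(
            athlete_id=history.athlete_id,
            event_times=np.append(history.event_times, rest_start),
            career_end=max(history.career_end, eval_end),
            retirement_as_event=False,
        )
    )
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=np.int64)
    for rep in range(n_reps):
        new = _simulate_times(
            params, rest_end, eval_end, conditioned.event_times, rng
        )
        counts[rep] = len(new)
    values, freq = np.unique(counts, return_counts=True)
    pmf = {int(v): float(c) / n_reps for v, c in zip(values, freq)}
    if thresholds is None:
        thresholds = tuple(range(1, int(counts.max()) + 1)) if counts.max() else (1,)
    prob_at_least = {
        int(k): float(np.mean(counts >= k)) for k in thresholds
    }
    return ScenarioResult(
        count_pmf=pmf,
        mean_count=float(counts.mean()),
        prob_at_least=prob_at_least,
        n_reps=n_reps,
        seed=seed,
    )
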