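"""Event histories of recurrent athlete absences and cohort I/O.

Time is measured in *player hours*: units of 1,000 bouts of exposure
(wins + losses + absences).  Each athlete contributes an ordered sequence
of absence (*kyujo*) occurrence times and a career-end time.  Under the
retirement-as-event convention the career end itself is recorded as the
final occurrence, which removes right-censoring from the likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "EventHistory",
    "Cohort",
    "merge_ties",
    "read_cohort",
    "write_cohort",
    "load_config",
]

_REQUIRED_COLUMNS = ("athlete_id", "event_time", "career_end")


@dataclass
class EventHistory:
    """One athlete's ordered absence times plus the career-end convention.

    Parameters
    ----------
    athlete_id : str
        Unique identifier.
    event_times : sequence of float
        Occurrence times in player hours, sorted nondecreasing, all positive
        and no later than ``career_end``.  Exact ties are permitted on input
        and collapsed by :func:`merge_ties`.
    career_end : float
        Player hours at the last observation (retirement or censoring).
    retirement_as_event : bool or None
        Whether the final event *is* the career end (retirement counted as
        an occurrence).  ``None`` means infer: true iff the last event time
        equals ``career_end``.
    """

    athlete_id: str
    event_times: np.ndarray
    career_end: float
    retirement_as_event: bool | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.event_times, dtype=float)
        if times.ndim != 1:
            raise ValueError("event_times must be one-dimensional")
        self.event_times = times
        self.career_end = float(self.career_end)
        if self.career_end <= 0:
            raise ValueError(
                f"career_end must be positive, got {self.career_end!r} "
                f"for athlete {self.athlete_id!r}"
            )
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError(
                    f"event_times must be sorted for athlete {self.athlete_id!r}"
                )
            if times[0] <= 0:
                raise ValueError(
                    f"event times must be positive for athlete {self.athlete_id!r}"
                )
            if times[-1] > self.career_end + 1e-12:
                raise ValueError(
                    f"event time {times[-1]} exceeds career_end {self.career_end} "
                    f"for athlete {self.athlete_id!r}"
                )
        ends_with_event = bool(
            times.size and np.isclose(times[-1], self.career_end)
        )
        if self.retirement_as_event is None:
            self.retirement_as_event = ends_with_event
        elif self.retirement_as_event and not ends_with_event:
            raise ValueError(
                f"retirement_as_event=True requires the last event to equal "
                f"career_end for athlete {self.athlete_id!r}"
            )

    @property
    def nu(self) -> int:
        """Number of recorded occurrences."""
        return int(self.event_times.size)

    @property
    def exposure_end(self) -> float:
        """Upper limit of the likelihood integral.

        Equals the final event under retirement-as-event, otherwise the
        (censoring) career end.
        """
        if self.retirement_as_event:
            return float(self.event_times[-1])
        return self.career_end

    def truncated(self, t: float, inclusive: bool = True) -> "EventHistory":
        """History restricted to events at or before ``t`` (or strictly before)."""
        times = self.event_times
        kept = times[times <= t] if inclusive else times[times < t]
        return EventHistory(
            athlete_id=self.athlete_id,
            event_times=kept,
            career_end=self.career_end,
            retirement_as_event=False
            if not (kept.size and np.isclose(kept[-1], self.career_end))
            else True,
        )


def merge_ties(history: EventHistory) -> EventHistory:
    """Collapse occurrences recorded at identical player hours into one.

    Consecutive absences do not advance distinct exposure time, so
    back-to-back occurrences land on the same player-hour mark and are
    counted as a single occurrence.  Idempotent.
    """
    times = np.unique(history.event_times)
    return replace(history, event_times=times)


@dataclass
class Cohort:
    """A collection of athlete histories with unique ids."""

    histories: tuple[EventHistory, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.histories = tuple(self.histories)
        ids = [h.athlete_id for h in self.histories]
        if len(set(ids)) != len(ids):
            raise ValueError("athlete ids must be unique within a cohort")

    @property
    def n(self) -> int:
        return len(self.histories)

    def __iter__(self) -> Iterator[EventHistory]:
        return iter(self.histories)

    def __len__(self) -> int:
        return self.n

    @property
    def total_events(self) -> int:
        return sum(h.nu for h in self.histories)

    def merged(self) -> "Cohort":
        return Cohort(tuple(merge_ties(h) for h in self.histories))


def read_cohort(
    path: str | Path,
    format: str = "csv",
    retirement_as_event: bool | None = None,
    merge: bool = True,
) -> Cohort:
    """Read a cohort from a long-format CSV.

    One row per event with columns ``athlete_id,event_time,career_end``;
    an empty ``event_time`` encodes an athlete with zero events.  Rows are
    grouped by athlete and sorted; exact duplicate times are collapsed when
    ``merge`` is true.
    """
    if format != "csv":
        raise ValueError(f"unsupported cohort format {format!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"athlete_id": str})
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message
        raise ValueError(f"malformed cohort file {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks columns {missing}")
    for column in ("event_time", "career_end"):
        try:
            frame[column] = pd.to_numeric(frame[column])
        except (ValueError, TypeError) as exc:
            bad = frame[pd.to_numeric(frame[column], errors="coerce").isna()
                        & frame[column].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"cohort file {path}: unparseable {column} near line {line}"
            ) from exc

    histories = []
    for athlete_id, group in frame.groupby("athlete_id", sort=True):
        ends = group["career_end"].dropna().unique()
        if len(ends) != 1:
            raise ValueError(
                f"athlete {athlete_id!r} must have exactly one career_end, "
                f"got {sorted(map(float, ends))}"
            )
        times = np.sort(group["event_time"].dropna().to_numpy(dtype=float))
        history = EventHistory(
            athlete_id=str(athlete_id),
            event_times=times,
            career_end=float(ends[0]),
            retirement_as_event=retirement_as_event if times.size else False,
        )
        histories.append(merge_ties(history) if merge else history)
    return Cohort(tuple(histories))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in the long CSV dialect read by :func:`read_cohort`."""
    rows: list[dict[str, object]] = []
    for history in cohort:
        if history.nu == 0:
            rows.append(
                {
                    "athlete_id": history.athlete_id,
                    "event_time": "",
                    "career_end": history.career_end,
                }
            )
        else:
            for t in history.event_times:
                rows.append(
                    {
                        "athlete_id": history.athlete_id,
                        "event_time": float(t),
                        "career_end": history.career_end,
                    }
                )
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config; `retirement_as_event` defaults to True."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    data.setdefault("retirement_as_event", True)
    return data
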