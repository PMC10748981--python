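"""Weekly theatre template and daily surgery bookings.

Baseline rules of the unit: four theatres run three sessions per day
(morning, afternoon, evening) on Monday-Friday.  A morning or afternoon
session books either one revision or two primary joint replacements; an
evening session books one primary.  A "baseline+weekend" variant runs the
same daily template seven days a week.

Whether a morning/afternoon session takes a revision is a Bernoulli draw per
session.  The per-session probability is calibrated so that the long-run
share of booked patients who are revisions matches a target case mix: with
probability ``p`` a session yields 1 revision, otherwise 2 primaries, so a
theatre-day books ``2p`` revisions among ``5 - 2p`` patients and the share
``s = 2p / (5 - 2p)`` inverts to ``p = 5s / (2(1+s))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "WEEKDAYS",
    "SESSIONS",
    "SESSION_START",
    "ScheduleConfig",
    "WeekTemplate",
    "SessionCell",
    "PlannedSurgery",
    "revision_session_probability",
    "build_week_template",
    "realise_daily_bookings",
    "baseline_schedule",
    "weekend_schedule",
]

WEEKDAYS: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")
SESSIONS: tuple[str, ...] = ("morning", "afternoon", "evening")

#: Session start times as fractions of a day (09:00, 13:00, 17:00). Only the
#: ordering matters at the daily audit resolution of the ward model.
SESSION_START: dict[str, float] = {"morning": 0.375, "afternoon": 0.54, "evening": 0.71}

#: Revision share of the study case mix, used for default calibration.
DEFAULT_REVISION_SHARE = 0.13


class InfeasibleCalibrationError(ValueError):
    """The requested revision share cannot be produced by the session rules."""


def revision_session_probability(target_revision_share: float) -> float:
    """Per-session revision probability reproducing a target booked share.

    Solves ``2p / (5 - 2p) = s`` for ``p``.  Feasible for ``0 <= s <= 2/3``
    (at ``p = 1`` every morning/afternoon session is a revision and the share
    is 2 revisions of 3 patients per theatre-day).
    """
    s = target_revision_share
    if not 0.0 <= s <= 2.0 / 3.0:
        raise InfeasibleCalibrationError(
            f"revision share {s} outside the feasible range [0, 2/3] "
            "of the one-revision-or-two-primaries session rules"
        )
    return 5.0 * s / (2.0 * (1.0 + s))


@dataclass(frozen=True)
class ScheduleConfig:
    """Theatre-session structure and booking rules.

    ``revision_session_prob`` may be a single probability or a per-weekday
    mapping (e.g. to front-load revisions early in the week).  The default is
    calibrated to the study's 13% revision case mix.
    """

    n_theatres: int = 4
    operating_weekdays: tuple[int, ...] = (0, 1, 2, 3, 4)  # Mon..Fri
    sessions_per_day: int = 3
    revision_session_prob: float | Mapping[int, float] = field(
        default_factory=lambda: revision_session_probability(DEFAULT_REVISION_SHARE)
    )
    label: str = "baseline"

    def __post_init__(self) -> None:
        if self.n_theatres < 0:
            raise ValueError(f"n_theatres must be >= 0: {self.n_theatres}")
        if not 0 <= self.sessions_per_day <= len(SESSIONS):
            raise ValueError(
                f"sessions_per_day must be in [0, {len(SESSIONS)}]: "
                f"{self.sessions_per_day}"
            )
        if any(not 0 <= d <= 6 for d in self.operating_weekdays):
            raise ValueError("operating_weekdays must be indices 0 (Mon) .. 6 (Sun)")
        for p in self._prob_values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"revision_session_prob must lie in [0,1]: {p}")

    def _prob_values(self) -> tuple[float, ...]:
        if isinstance(self.revision_session_prob, Mapping):
            return tuple(self.revision_session_prob.values())
        return (self.revision_session_prob,)

    def prob_for_weekday(self, weekday: int) -> float:
        if isinstance(self.revision_session_prob, Mapping):
            return float(self.revision_session_prob.get(weekday, 0.0))
        return float(self.revision_session_prob)

    @property
    def sessions(self) -> tuple[str, ...]:
        return SESSIONS[: self.sessions_per_day]


def baseline_schedule(**overrides) -> ScheduleConfig:
    """Four theatres, three sessions per day, Monday-Friday."""
    return ScheduleConfig(label="baseline", **overrides)


def weekend_schedule(**overrides) -> ScheduleConfig:
    """Same daily allocations as baseline but operating seven days a week."""
    return ScheduleConfig(
        operating_weekdays=tuple(range(7)), label="baseline+weekend", **overrides
    )


@dataclass(frozen=True)
class SessionCell:
    """One bookable theatre session slot in the weekly template."""

    weekday: int  # 0 = Mon .. 6 = Sun
    theatre: int
    session: str


@dataclass(frozen=True)
class WeekTemplate:
    """Enumerated session cells for one week, with the generating config."""

    config: ScheduleConfig
    cells: tuple[SessionCell, ...]

    def cells_for_weekday(self, weekday: int) -> tuple[SessionCell, ...]:
        return tuple(c for c in self.cells if c.weekday == weekday)


def build_week_template(config: ScheduleConfig) -> WeekTemplate:
    """Enumerate (weekday, theatre, session) cells for operating weekdays.

    Cells are ordered weekday, then session (morning, afternoon, evening),
    then theatre index — the order in which bookings claim beds on ties.
    """
    cells = tuple(
        SessionCell(weekday=wd, theatre=t, session=sess)
        for wd in sorted(set(config.operating_weekdays))
        for sess in config.sessions
        for t in range(config.n_theatres)
    )
    return WeekTemplate(config=config, cells=cells)


@dataclass(frozen=True)
class PlannedSurgery:
    """A booked theatre slot for one patient on a given simulation day."""

    day_index: int
    weekday: int
    theatre: int
    session: str
    surgical_class: str  # "primary" | "revision"

    @property
    def arrival_time(self) -> float:
        """Continuous arrival instant in days from simulation start."""
        return self.day_index + SESSION_START[self.session]


def realise_daily_bookings(
    template: WeekTemplate, day_index: int, rng: np.random.Generator
) -> list[PlannedSurgery]:
    """Realise the bookings of one simulation day under the session rules.

    Day 0 is a Monday.  Each morning/afternoon cell books one revision with
    the configured per-weekday probability, else two primaries; each evening
    cell books one primary.  Bookings are ordered session-major then theatre,
    which fixes the tie-break for bed contention at equal arrival instants.
    """
    weekday = day_index % 7
    p = template.config.prob_for_weekday(weekday)
    bookings: list[PlannedSurgery] = []
    for cell in template.cells_for_weekday(weekday):
        if cell.session == "evening":
            classes = ("primary",)
        elif rng.random() < p:
            classes = ("revision",)
        else:
            classes = ("primary", "primary")
        for surgical_class in classes:
            bookings.append(
                PlannedSurgery(
                    day_index=day_index,
                    weekday=weekday,
                    theatre=cell.theatre,
                    session=cell.session,
                    surgical_class=surgical_class,
                )
            )
    return bookings
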