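"""Experiment scenarios: productivity multipliers and the what-if grid.

A scenario is one cell of the experiment design: a bed count, a theatre
schedule, a length-of-stay multiplier and a delayed-proportion multiplier.
The study grid crosses bed counts 30-70 (step 5) with two schedules (5-day
baseline, 7-day baseline+weekend) and two settings each for lengths of stay
and delayed proportion (baseline and 0.25x baseline), 72 scenarios in all.

Multipliers scale the per-procedure length-of-stay specs (mean and SD
together, preserving the coefficient of variation) and the delayed
proportion.  The delayed-stay distribution itself always remains at its
baseline values.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Sequence

from .input_model import ModelParams
from .schedule import ScheduleConfig, baseline_schedule, weekend_schedule

__all__ = [
    "ScenarioConfig",
    "GridSpec",
    "InvalidScenarioError",
    "apply_multipliers",
    "build_scenario_grid",
    "study_grid",
    "study_bed_values",
]


class InvalidScenarioError(ValueError):
    """A scenario's multipliers produce parameters outside their domain."""


#: Bed counts of the study grid: 30-70 in increments of 5 (9 values).
def study_bed_values() -> tuple[int, ...]:
    return tuple(range(30, 75, 5))


@dataclass(frozen=True)
class ScenarioConfig:
    """One experiment cell: beds, schedule and productivity multipliers."""

    label: str
    n_beds: int
    schedule: ScheduleConfig
    los_multiplier: float = 1.0
    prop_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_beds < 0:
            raise InvalidScenarioError(f"n_beds must be >= 0: {self.n_beds}")
        if not self.los_multiplier > 0:
            raise InvalidScenarioError(
                f"los_multiplier must be positive: {self.los_multiplier}"
            )
        if not self.prop_multiplier > 0:
            raise InvalidScenarioError(
                f"prop_multiplier must be positive: {self.prop_multiplier}"
            )


def apply_multipliers(
    params: ModelParams, los_multiplier: float, prop_multiplier: float
) -> ModelParams:
    """Scale LOS specs and delayed proportion; delayed-stay spec untouched.

    Every procedure's mean and SD are multiplied by ``los_multiplier`` and
    ``prop_delayed`` by ``prop_multiplier``.  Raises
    :class:`InvalidScenarioError` if the scaled proportion exceeds 1.
    """
    if not los_multiplier > 0 or not prop_multiplier > 0:
        raise InvalidScenarioError("multipliers must be positive")
    scaled_prop = params.prop_delayed * prop_multiplier
    if scaled_prop > 1.0 + 1e-12:
        raise InvalidScenarioError(
            f"scaled delayed proportion {scaled_prop:.4f} exceeds 1"
        )
    return replace(
        params,
        los_specs={
            label: spec.scaled(los_multiplier)
            for label, spec in params.los_specs.items()
        },
        prop_delayed=min(scaled_prop, 1.0),
    )


def _los_name(multiplier: float) -> str:
    if math.isclose(multiplier, 1.0):
        return "high_los"
    if math.isclose(multiplier, 0.25):
        return "low_los"
    return f"los{multiplier:g}x"


def _prop_name(multiplier: float) -> str:
    if math.isclose(multiplier, 1.0):
        return "prop_high"
    if math.isclose(multiplier, 0.25):
        return "prop_low"
    return f"prop{multiplier:g}x"


def scenario_label(
    n_beds: int, schedule: ScheduleConfig, los_multiplier: float, prop_multiplier: float
) -> str:
    sched = schedule.label.replace("+", "_")
    return (
        f"beds{n_beds}_{sched}_"
        f"{_los_name(los_multiplier)}_{_prop_name(prop_multiplier)}"
    )


@dataclass(frozen=True)
class GridSpec:
    """Factor levels of a full-factorial scenario grid."""

    bed_values: Sequence[int]
    schedules: Sequence[ScheduleConfig]
    los_multipliers: Sequence[float] = (1.0, 0.25)
    prop_multipliers: Sequence[float] = (1.0, 0.25)

    def __post_init__(self) -> None:
        for name in ("bed_values", "schedules", "los_multipliers", "prop_multipliers"):
            if len(getattr(self, name)) == 0:
                raise InvalidScenarioError(f"grid factor {name} is empty")


def study_grid() -> GridSpec:
    """The 72-scenario study grid: 9 bed values x 2 schedules x 2 LOS x 2 prop."""
    return GridSpec(
        bed_values=study_bed_values(),
        schedules=(baseline_schedule(), weekend_schedule()),
        los_multipliers=(1.0, 0.25),
        prop_multipliers=(1.0, 0.25),
    )


def build_scenario_grid(spec: GridSpec) -> list[ScenarioConfig]:
    """Cross the grid factors into deterministically ordered scenarios.

    Order: beds outermost, then schedule, LOS multiplier, proportion
    multiplier innermost.  Labels encode all four factors using the study
    vocabulary (high_los/low_los, prop_high/prop_low).
    """
    return [
        ScenarioConfig(
            label=scenario_label(beds, sched, lm, pm),
            n_beds=beds,
            schedule=sched,
            los_multiplier=lm,
            prop_multiplier=pm,
        )
        for beds, sched, lm, pm in itertools.product(
            spec.bed_values, spec.schedules, spec.los_multipliers, spec.prop_multipliers
        )
    ]
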