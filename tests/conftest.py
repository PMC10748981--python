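import numpy as np
import pytest

from orthosim.input_model import (
    CaseMix,
    LosSpec,
    ModelParams,
    PROCEDURES,
    baseline_params,
)
from orthosim.scenarios import ScenarioConfig
from orthosim.schedule import ScheduleConfig


@pytest.fixture(scope="session")
def params() -> ModelParams:
    """Baseline study parameters (shared, frozen dataclass)."""
    return baseline_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def deterministic_params(los_days: float = 2.0) -> ModelParams:
    """All stays exactly `los_days`, no delayed discharges — analytic oracle."""
    spec = LosSpec(los_days, 0.0)
    return ModelParams(
        los_specs={p: spec for p in PROCEDURES},
        delayed_los=spec,
        prop_delayed=0.0,
        case_mix=CaseMix(
            primary_share=1.0,
            within_primary={"p-THR": 1.0, "p-TKR": 0.0, "p-UKR": 0.0},
            within_revision={"r-THR": 0.55, "r-TKR": 0.45},
        ),
    )


def one_theatre_schedule(sessions_per_day: int = 3, weekdays=tuple(range(7))):
    """Single theatre, no revision sessions: 5 primaries/day at 3 sessions."""
    return ScheduleConfig(
        n_theatres=1,
        operating_weekdays=tuple(weekdays),
        sessions_per_day=sessions_per_day,
        revision_session_prob=0.0,
        label="test",
    )


def make_scenario(n_beds: int, schedule, los_multiplier=1.0, prop_multiplier=1.0):
    return ScenarioConfig(
        label=f"test_beds{n_beds}",
        n_beds=n_beds,
        schedule=schedule,
        los_multiplier=los_multiplier,
        prop_multiplier=prop_multiplier,
    )
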