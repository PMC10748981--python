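"""Discrete-event engine for the ring-fenced ward.

Patients booked by the theatre schedule arrive at their session start time
and claim a bed from a finite pool.  If a bed is free the patient is
admitted, holds the bed for a sampled length of stay and releases it at
discharge; if no bed is free the theatre slot is *lost* — the patient leaves
the system with no retry, queueing or overflow.  Occupancy is audited once
per simulated day at end of day.

Delayed discharges are modelled by stochastic routing: with the (scenario-
scaled) delay probability a patient's whole stay is drawn from the
delayed-stay lognormal at baseline parameters; otherwise from the
procedure's lognormal with mean and SD scaled by the scenario's
length-of-stay multiplier.

Time is continuous in days; day 0 is a Monday and the simulation starts with
an empty ward, so an initial warm-up period should be discarded before
summarising (see :mod:`orthosim.metrics`).

The event calendar is a binary heap over (time, priority) with discharges
processed before audits and audits before arrivals at identical instants;
arrivals at the same instant claim beds in booking order (session, theatre,
booking index).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .input_model import (
    ModelParams,
    PROCEDURES,
    InvalidParameterError,
    lognormal_from_moments,
    sample_los,
    sample_procedure,
)
from .scenarios import InvalidScenarioError, ScenarioConfig
from .schedule import PlannedSurgery, build_week_template, realise_daily_bookings

__all__ = [
    "Patient",
    "ReplicationResult",
    "route_total_los",
    "run_replication",
    "run_replications",
    "DEFAULT_WARMUP_DAYS",
    "DEFAULT_COLLECT_DAYS",
    "DEFAULT_N_REPS",
]

#: Default run controls: 6-week warm-up, 26-week collection, 30 replications.
DEFAULT_WARMUP_DAYS = 42
DEFAULT_COLLECT_DAYS = 182
DEFAULT_N_REPS = 30


def route_total_los(
    procedure: str,
    params: ModelParams,
    los_multiplier: float,
    rng: np.random.Generator,
    prop_multiplier: float = 1.0,
    delay_mode: str = "replace",
) -> tuple[bool, float]:
    """Stochastic discharge routing: (delayed flag, total stay in days).

    The delayed flag is Bernoulli(prop_delayed x prop_multiplier).  A delayed
    patient's stay is drawn from the delayed-stay distribution at baseline
    parameters — never scaled by the LOS multiplier.  A non-delayed stay is
    drawn from the procedure's lognormal with mean and SD scaled by
    ``los_multiplier``.

    ``delay_mode="add"`` instead treats the delayed draw as extra days on top
    of the (scaled) procedure stay; the default ``"replace"`` treats it as
    the whole stay.
    """
    if procedure not in PROCEDURES:
        raise InvalidParameterError(f"unknown procedure label: {procedure!r}")
    if not los_multiplier > 0:
        raise InvalidScenarioError(f"los_multiplier must be positive: {los_multiplier}")
    if delay_mode not in ("replace", "add"):
        raise ValueError(f"delay_mode must be 'replace' or 'add': {delay_mode!r}")
    p_delay = params.prop_delayed * prop_multiplier
    if p_delay > 1.0 + 1e-12:
        raise InvalidScenarioError(f"scaled delayed proportion {p_delay:.4f} exceeds 1")

    delayed = bool(rng.random() < p_delay)
    spec = params.los_specs[procedure].scaled(los_multiplier)
    if delayed:
        los = float(sample_los(params.delayed_lognormal(), rng))
        if delay_mode == "add":
            los += float(
                sample_los(lognormal_from_moments(spec.mean_days, spec.sd_days), rng)
            )
    else:
        los = float(
            sample_los(lognormal_from_moments(spec.mean_days, spec.sd_days), rng)
        )
    return delayed, los


@dataclass(frozen=True)
class Patient:
    """One simulated patient: booking, routing outcome and bed interval."""

    id: int
    procedure: str
    surgical_class: str
    booking: PlannedSurgery
    delayed: bool
    los_days: float
    admit_time: float | None
    discharge_time: float | None
    outcome: str  # "admitted" | "lost_slot"


@dataclass
class ReplicationResult:
    """Daily series of one seeded run plus its run metadata.

    ``daily_occupancy[d]`` is the bed census at the end-of-day audit of day
    ``d``; throughput/lost-slot/booking series count events on day ``d``.
    Day 0 is a Monday; series span warm-up plus collection days.
    """

    n_beds: int
    warmup_days: int
    collect_days: int
    seed_entropy: int | Sequence[int]
    daily_occupancy: np.ndarray
    daily_bookings: np.ndarray
    daily_lost_slots: np.ndarray
    daily_throughput: dict[str, np.ndarray]  # admissions per procedure per day

    @property
    def horizon_days(self) -> int:
        return self.warmup_days + self.collect_days

    @property
    def daily_admissions(self) -> np.ndarray:
        return np.sum([self.daily_throughput[p] for p in PROCEDURES], axis=0)


# event priorities at identical timestamps: free beds, then audit, then admit
_DISCHARGE, _AUDIT, _ARRIVAL = 0, 1, 2


def run_replication(
    scenario: ScenarioConfig,
    params: ModelParams,
    seed: int | np.random.SeedSequence,
    warmup_days: int = DEFAULT_WARMUP_DAYS,
    collect_days: int = DEFAULT_COLLECT_DAYS,
    delay_mode: str = "replace",
) -> ReplicationResult:
    """Simulate one seeded replication of a scenario.

    Bookings and patient attributes (procedure, delayed flag, stay) are drawn
    for every booked slot independently of bed availability, so runs with the
    same seed share identical demand across bed counts (common random
    numbers).  Bed contention is then resolved deterministically in event
    order.  Identical seeds reproduce identical results bit for bit.
    """
    horizon = warmup_days + collect_days
    if horizon <= 0:
        raise InvalidScenarioError(
            f"horizon must be positive: warmup {warmup_days} + collect {collect_days}"
        )
    if warmup_days < 0 or collect_days < 0:
        raise InvalidScenarioError("warmup_days and collect_days must be >= 0")

    seed_seq = (
        seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    )
    booking_rng, patient_rng = (np.random.default_rng(s) for s in seed_seq.spawn(2))

    template = build_week_template(scenario.schedule)

    # Realise all demand up front (independent of bed availability).
    patients: list[Patient] = []
    daily_bookings = np.zeros(horizon, dtype=np.int64)
    for day in range(horizon):
        bookings = realise_daily_bookings(template, day, booking_rng)
        daily_bookings[day] = len(bookings)
        for booking in bookings:
            procedure = sample_procedure(
                params.case_mix, booking.surgical_class, patient_rng
            )
            delayed, los = route_total_los(
                procedure,
                params,
                scenario.los_multiplier,
                patient_rng,
                prop_multiplier=scenario.prop_multiplier,
                delay_mode=delay_mode,
            )
            patients.append(
                Patient(
                    id=len(patients),
                    procedure=procedure,
                    surgical_class=booking.surgical_class,
                    booking=booking,
                    delayed=delayed,
                    los_days=los,
                    admit_time=None,
                    discharge_time=None,
                    outcome="pending",
                )
            )

    # Event loop over a single calendar.
    events: list[tuple[float, int, int]] = []  # (time, priority, payload)
    for patient in patients:
        heapq.heappush(
            events, (patient.booking.arrival_time, _ARRIVAL, patient.id)
        )
    for day in range(horizon):
        heapq.heappush(events, (float(day + 1), _AUDIT, day))

    daily_occupancy = np.zeros(horizon, dtype=np.int64)
    daily_lost = np.zeros(horizon, dtype=np.int64)
    daily_throughput = {p: np.zeros(horizon, dtype=np.int64) for p in PROCEDURES}
    occupied = 0

    while events:
        time, kind, payload = heapq.heappop(events)
        if kind == _DISCHARGE:
            occupied -= 1
        elif kind == _AUDIT:
            daily_occupancy[payload] = occupied
        else:  # arrival
            patient = patients[payload]
            day = patient.booking.day_index
            if occupied < scenario.n_beds:
                occupied += 1
                discharge_time = time + patient.los_days
                patients[payload] = Patient(
                    **{
                        **patient.__dict__,
                        "admit_time": time,
                        "discharge_time": discharge_time,
                        "outcome": "admitted",
                    }
                )
                daily_throughput[patient.procedure][day] += 1
                heapq.heappush(events, (discharge_time, _DISCHARGE, payload))
            else:
                patients[payload] = Patient(
                    **{**patient.__dict__, "outcome": "lost_slot"}
                )
                daily_lost[day] += 1

    admissions = np.sum([daily_throughput[p] for p in PROCEDURES], axis=0)
    assert np.array_equal(daily_bookings, admissions + daily_lost), (
        "conservation violated: bookings != admissions + lost slots"
    )
    assert daily_occupancy.max(initial=0) <= scenario.n_beds

    return ReplicationResult(
        n_beds=scenario.n_beds,
        warmup_days=warmup_days,
        collect_days=collect_days,
        seed_entropy=seed_seq.entropy,
        daily_occupancy=daily_occupancy,
        daily_bookings=daily_bookings,
        daily_lost_slots=daily_lost,
        daily_throughput=daily_throughput,
    )


def run_replications(
    scenario: ScenarioConfig,
    params: ModelParams,
    n_reps: int = DEFAULT_N_REPS,
    base_seed: int = 0,
    warmup_days: int = DEFAULT_WARMUP_DAYS,
    collect_days: int = DEFAULT_COLLECT_DAYS,
    delay_mode: str = "replace",
) -> list[ReplicationResult]:
    """Run independent replications on substreams spawned from one seed.

    Substream ``i`` depends only on ``base_seed`` and ``i`` — not on the
    scenario — so matched replication indices across scenarios share common
    random numbers.
    """
    if n_reps < 1:
        raise InvalidScenarioError(f"n_reps must be >= 1: {n_reps}")
    streams = np.random.SeedSequence(base_seed).spawn(n_reps)
    return [
        run_replication(
            scenario,
            params,
            stream,
            warmup_days=warmup_days,
            collect_days=collect_days,
            delay_mode=delay_mode,
        )
        for stream in streams
    ]
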