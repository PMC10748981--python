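"""Output analysis: warm-up truncation, per-weekday summaries, aggregation.

Utilisation is defined at day level as audited occupancy divided by the bed
count, then averaged over the collection days of each weekday (and overall).
Warm-up days are excluded from every summary, removing the empty-ward
initialisation bias.  Cross-replication spread uses the Tukey boxplot
convention: quartiles, median and whiskers at the most extreme values within
1.5 interquartile ranges of the quartiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .input_model import PROCEDURES
from .ward_sim import ReplicationResult

__all__ = [
    "WEEKDAY_NAMES",
    "ReplicationSummary",
    "SummaryStats",
    "summarise_replication",
    "aggregate_replications",
    "flag_pressure",
    "PRESSURE_THRESHOLD",
]

WEEKDAY_NAMES: tuple[str, ...] = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: Mean occupancy above ~85-90% is commonly taken to signal recurrent bed
#: crises; the default pressure flag threshold is the lower end of that band.
PRESSURE_THRESHOLD = 0.85


@dataclass(frozen=True)
class ReplicationSummary:
    """Collection-period means of one replication."""

    n_beds: int
    collect_days: int
    mean_utilisation: float
    mean_daily_throughput: float
    mean_daily_lost_slots: float
    weekday_utilisation: Mapping[str, float]
    weekday_lost_slots: Mapping[str, float]
    weekday_throughput: Mapping[str, float]
    throughput_per_procedure: Mapping[str, float]
    total_throughput: int
    total_lost_slots: int


def summarise_replication(
    result: ReplicationResult, warmup_days: int | None = None
) -> ReplicationSummary:
    """Summarise one replication over its collection period.

    ``warmup_days`` defaults to the value recorded in the result; it must be
    strictly less than the series horizon.  Utilisation is NaN when the
    scenario has zero beds.
    """
    warmup = result.warmup_days if warmup_days is None else warmup_days
    horizon = len(result.daily_occupancy)
    if not 0 <= warmup < horizon:
        raise ValueError(f"warmup_days {warmup} must lie in [0, horizon {horizon})")

    days = np.arange(warmup, horizon)
    weekdays = days % 7
    occupancy = result.daily_occupancy[warmup:]
    lost = result.daily_lost_slots[warmup:]
    admissions = result.daily_admissions[warmup:]

    beds = result.n_beds
    utilisation = occupancy / beds if beds > 0 else np.full(len(occupancy), np.nan)

    def by_weekday(series: np.ndarray) -> dict[str, float]:
        return {
            WEEKDAY_NAMES[wd]: float(series[weekdays == wd].mean())
            if np.any(weekdays == wd)
            else float("nan")
            for wd in range(7)
        }

    per_procedure = {
        p: float(result.daily_throughput[p][warmup:].mean()) for p in PROCEDURES
    }
    return ReplicationSummary(
        n_beds=beds,
        collect_days=len(days),
        mean_utilisation=float(np.nanmean(utilisation)),
        mean_daily_throughput=float(admissions.mean()),
        mean_daily_lost_slots=float(lost.mean()),
        weekday_utilisation=by_weekday(utilisation),
        weekday_lost_slots=by_weekday(lost.astype(float)),
        weekday_throughput=by_weekday(admissions.astype(float)),
        throughput_per_procedure=per_procedure,
        total_throughput=int(admissions.sum()),
        total_lost_slots=int(lost.sum()),
    )


def _metric_rows(summary: ReplicationSummary) -> list[tuple[str, str, float]]:
    rows = [
        ("utilisation", "overall", summary.mean_utilisation),
        ("throughput", "overall", summary.mean_daily_throughput),
        ("lost_slots", "overall", summary.mean_daily_lost_slots),
    ]
    rows += [("utilisation", wd, v) for wd, v in summary.weekday_utilisation.items()]
    rows += [("lost_slots", wd, v) for wd, v in summary.weekday_lost_slots.items()]
    rows += [("throughput", wd, v) for wd, v in summary.weekday_throughput.items()]
    rows += [
        ("throughput_per_procedure", p, v)
        for p, v in summary.throughput_per_procedure.items()
    ]
    return rows


@dataclass(frozen=True)
class SummaryStats:
    """Cross-replication statistics, boxplot-ready.

    ``table`` has one row per (metric, key) — key a weekday name, a procedure
    label or ``"overall"`` — with columns mean, min, q1, median, q3, max and
    Tukey whiskers.  ``pressure_flags`` lists weekdays whose mean utilisation
    exceeded the flag threshold (set by :func:`flag_pressure`).
    """

    n_replications: int
    table: pd.DataFrame
    pressure_flags: tuple[str, ...] = ()
    pressure_threshold: float | None = None

    def mean_of(self, metric: str, key: str = "overall") -> float:
        rows = self.table[(self.table.metric == metric) & (self.table.key == key)]
        if rows.empty:
            raise KeyError(f"no aggregated metric {metric!r} with key {key!r}")
        return float(rows["mean"].iloc[0])

    @property
    def mean_utilisation(self) -> float:
        return self.mean_of("utilisation")

    def weekday_means(self, metric: str) -> dict[str, float]:
        return {wd: self.mean_of(metric, wd) for wd in WEEKDAY_NAMES}


def aggregate_replications(summaries: Sequence[ReplicationSummary]) -> SummaryStats:
    """Aggregate per-replication summaries into cross-replication spread."""
    if len(summaries) == 0:
        raise ValueError("aggregate_replications requires at least one summary")

    long = pd.DataFrame(
        [
            {"rep": i, "metric": metric, "key": key, "value": value}
            for i, summary in enumerate(summaries)
            for metric, key, value in _metric_rows(summary)
        ]
    )

    def agg(group: pd.Series) -> pd.Series:
        values = group.to_numpy(dtype=float)
        q1, median, q3 = np.percentile(values, [25, 50, 75])
        iqr = q3 - q1
        in_fence = values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]
        return pd.Series(
            {
                "mean": values.mean(),
                "min": values.min(),
                "q1": q1,
                "median": median,
                "q3": q3,
                "max": values.max(),
                "whisker_lo": in_fence.min() if len(in_fence) else values.min(),
                "whisker_hi": in_fence.max() if len(in_fence) else values.max(),
            }
        )

    table = (
        long.groupby(["metric", "key"], sort=False)["value"]
        .apply(agg)
        .unstack()
        .reset_index()
    )
    return SummaryStats(n_replications=len(summaries), table=table)


def flag_pressure(
    stats: SummaryStats, threshold: float = PRESSURE_THRESHOLD
) -> SummaryStats:
    """Flag weekdays whose mean utilisation exceeds the pressure threshold."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1]: {threshold}")
    means = stats.weekday_means("utilisation")
    flags = tuple(wd for wd in WEEKDAY_NAMES if means[wd] > threshold)
    return SummaryStats(
        n_replications=stats.n_replications,
        table=stats.table,
        pressure_flags=flags,
        pressure_threshold=threshold,
    )
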