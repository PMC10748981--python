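# Methods

## Model structure

`orthosim` simulates individual patient flow through a ring-fenced elective
orthopaedic facility: theatre sessions generate booked surgical demand, and
a finite ward bed pool serves it. The waiting list is assumed infinite —
every bookable slot is filled — so the model measures the *capacity* of a
bed/theatre configuration, not referral demand. Beds are protected from
emergency admissions (ring-fencing), so the only arrival process is the
theatre schedule.

Time is continuous, in days; day 0 is a Monday and sessions start at 09:00,
13:00 and 17:00 (0.375, 0.54, 0.71 of a day — only their ordering matters at
daily resolution). A booked patient arrives at the session start, claims a
bed if one is free and holds it for the sampled stay; if the ward is full
the theatre slot is lost and the patient leaves with no retry, queueing or
overflow transfer. Real units mitigate some of these losses (bed management,
transfer to an acute site); the model deliberately reports the unmitigated
mismatch. Occupancy is audited once per day at end of day, so a stay that
starts and ends between two audits occupies a bed but is invisible to the
occupancy series — an accepted discretisation at daily reporting resolution.

The event calendar is a binary heap keyed on (time, event priority):
discharges are processed before the audit, and the audit before arrivals, at
identical instants; simultaneous arrivals claim beds in booking order
(session, then theatre index, then booking index within the session).

## Stochastic inputs

Lengths of stay are lognormal in all cases, specified by arithmetic mean and
SD in days and converted by moment matching (`σ² = ln(1+(sd/μ)²)`,
`μ_log = ln μ − σ²/2`), which reproduces the stated moments exactly; `sd = 0`
degenerates to a point mass, used by the deterministic test oracles.
Baseline values (days):

| category | mean | SD |
|---|---|---|
| p-THR | 4.4 | 2.9 |
| p-TKR | 4.7 | 2.8 |
| p-UKR | 2.9 | 2.1 |
| r-THR | 6.9 | 7.0 |
| r-TKR | 7.2 | 7.6 |
| delayed discharge | 16.5 | 15.1 |

A patient is routed to a delayed discharge with probability 0.076 at
baseline. **The delayed draw replaces the whole stay** rather than adding to
the procedure stay: the delayed distribution was fitted on delayed patients'
complete spells and its mean already exceeds every procedure mean, so
addition would double-count. The alternative additive semantics is available
behind `delay_mode="add"` for sensitivity analysis. For the same reason,
per-procedure distributions are fitted on non-delayed spells only; whether
the study's own fits excluded delayed spells is not documented, so this is a
declared interpretation.

The case mix (87% primary: 51/38/11 p-THR/p-TKR/p-UKR; 13% revision: 55/45
r-THR/r-TKR) enters twice: procedure labels are drawn within the surgical
class of each booking, and the class itself emerges from the session rules.
Because "one revision or two primaries" leaves the choice rule open, the
choice is a per-session Bernoulli with probability calibrated in closed form
(`p = 5s/(2(1+s)) ≈ 0.2876` for `s = 0.13`) so the long-run booked revision
share equals the observed mix without introducing a waiting-list model. The
probability may also be set per weekday, enabling schedules that front-load
revisions early in the week; the default is uniform.

## Scenarios

A scenario multiplies every procedure LOS spec (mean **and** SD, preserving
the coefficient of variation and hence the lognormal shape parameter — the
least-informative scaling) and the delayed proportion; the delayed-stay
distribution itself is never rescaled. The study grid crosses beds
30–70 step 5, schedules {5-day, 7-day}, LOS multipliers {1, 0.25} and
delayed-proportion multipliers {1, 0.25}: 72 scenarios, labelled with the
high_los/low_los, prop_high/prop_low vocabulary.

## Run controls and reproducibility

Defaults: 42 warm-up days (discarded; the simulation starts empty and the
delayed-patient census, whose mean residual life is ~15 days, dominates the
transient), 182 collection days (26 weeks, an exact multiple of 7 so every
weekday is observed equally often), 30 replications. All are configurable;
the source publication states none of them, so these are this package's own
choices, sized for stable per-weekday means.

All randomness flows from one base seed through `numpy` `SeedSequence`
spawning: replication *i* uses child stream *i* of the base seed regardless
of scenario, and within a replication separate substreams drive schedule
realisation and patient attributes. Demand (bookings, procedures, delay
flags, stays) is realised independently of bed availability, so matched
replications across bed counts share common random numbers; with identical
demand, throughput is non-decreasing and lost slots non-increasing in beds.
Identical seeds reproduce results bit for bit.

## Summaries

Per-day utilisation is audited occupancy divided by beds; weekday and
overall figures are means of day-level values over collection days
(day-level averaging first, then weekday grouping — the averaging order is a
declared choice). Cross-replication spread uses the Tukey boxplot
convention: quartiles, median, whiskers at the most extreme values within
1.5 IQR. Weekdays whose mean utilisation exceeds a threshold (default 0.85,
the conventional lower bound of the bed-crisis band) are flagged.

Deterministic verification: with stays fixed at 2.0 days and 5 bookings/day
7 days/week, Little's law gives L = λW = 10 occupied beds, and the audited
census equals 10 exactly after warm-up; per-day conservation
(bookings = admissions + lost slots) is asserted inside the engine on every
run.

## Synthetic EHR generator

`generate_synthetic_ehr` emulates the kind of spell-level extract the model
is parameterised from: procedure label, length of stay, delayed flag. It
reproduces the generating distributions and proportions but none of the
structure of real records — no dates, seasonality, readmission, coding noise
or correlation between complexity and delay — so passing parameter-recovery
tests demonstrates the fit/generate pipeline is self-consistent, not that
real extracts are this clean. `generate_reference_cohort` is a synthetic
stand-in for the study cohort with its exact marginal counts (6,912 spells,
529 delayed, per-procedure counts), so the 7.6% delayed fraction is exactly
representable; stay values in it are synthetic draws.

Recovery accuracy is limited by category counts: at 50,000 records the
revision categories receive ~3,000–3,500 non-delayed spells and, with
coefficients of variation near 1, the relative standard error of a sample SD
is 4–6%; recovered SDs for those categories should be read with that
uncertainty.

## Known limitations

- No patient attributes (age, frailty, complexity) beyond procedure and
  delay flag; delayed patients may in reality be systematically more complex.
- Lost slots are terminal; real mitigations would recover some of them, so
  modelled lost-slot counts are an upper bound on system-reason losses.
- Theatre time itself is not a resource: sessions never overrun, and
  patient-reason non-attendance is out of scope.
- Only the five core elective procedures are modelled; day cases and complex
  spinal work lie outside the bed-planning scope.
- Historical (pre-pandemic) stay distributions are assumed to describe
  baseline behaviour.
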