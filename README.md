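# orthosim

Discrete-event simulation of a **ring-fenced elective orthopaedic unit** —
operating theatres feeding a protected ward bed pool — for capacity planners
weighing bed numbers, theatre schedules and productivity measures (shorter
stays, fewer delayed discharges) against surgical throughput.

## The model

Patients are booked by theatre-session rules: four theatres run three
sessions a day (Monday–Friday at baseline, 7-day in the weekend variant); a
morning or afternoon session holds either **one revision or two primary**
joint replacements, an evening session one primary. Five procedures are
modelled — primary total hip (p-THR), primary total knee (p-TKR),
unicompartmental knee (p-UKR), revision hip (r-THR) and revision knee
(r-TKR) — with case mix 87% primary (51/38/11 within class) and 13% revision
(55/45). The per-session revision probability is calibrated so the booked
mix reproduces the 13% revision share: solving `2p/(5−2p) = s` gives
`p = 5s/(2(1+s)) ≈ 0.288`.

Each booked patient arrives at the session start and claims a bed. If none
is free the theatre slot is **lost** (no queueing or rebooking); otherwise
the bed is held for a length of stay *L* drawn by stochastic routing:

- with probability `p_delay` (baseline 0.076) the patient is a **delayed
  discharge** and *L* ~ Lognormal fitted to delayed spells
  (mean 16.5 d, SD 15.1 d), never rescaled by scenarios;
- otherwise *L* ~ Lognormal for the procedure, e.g. p-THR mean 4.4 d,
  SD 2.9 d, scaled by the scenario's length-of-stay multiplier.

Means and SDs convert to lognormal parameters by moment matching:
`σ² = ln(1 + (sd/μ)²)`, `μ_log = ln(μ) − σ²/2`.

Outputs per scenario: **surgical throughput** (per procedure), **bed
utilisation per weekday** (occupancy at a daily end-of-day audit divided by
beds; sustained values above ~85–90% indicate recurrent bed crises) and
**lost theatre slots per weekday**. The scenario grid crosses beds 30–70
(step 5), two schedules, and baseline vs 0.25× settings for stay lengths and
delayed proportion — 72 scenarios.

## Worked example

```python
from orthosim import (
    baseline_params, baseline_schedule, ScenarioConfig,
    run_replications, summarise_replication, aggregate_replications, flag_pressure,
)

params = baseline_params()
scenario = ScenarioConfig(
    label="beds40_baseline_high_los_prop_high",
    n_beds=40, schedule=baseline_schedule(),
    los_multiplier=1.0, prop_multiplier=1.0,
)
results = run_replications(scenario, params, n_reps=30, base_seed=1)
stats = flag_pressure(aggregate_replications([summarise_replication(r) for r in results]))

print(f"mean utilisation      : {stats.mean_utilisation:.1%}")
print(f"mean daily throughput : {stats.mean_of('throughput'):.1f} surgeries")
print(f"mean daily lost slots : {stats.mean_of('lost_slots'):.1f}")
print(f"pressure flags (>85%) : {', '.join(stats.pressure_flags)}")
```

prints

```
mean utilisation      : 87.5%
mean daily throughput : 6.2 surgeries
mean daily lost slots : 6.4
pressure flags (>85%) : Mon, Tue, Wed, Thu, Fri
```

At historical stay lengths the proposed 40-bed ward runs at 87.5% mean
occupancy, every operating weekday is flagged above the 85% pressure
threshold, and more surgeries are lost for want of a bed (6.4/day) than are
performed (6.2/day) — the bed pool, not theatre capacity, is the binding
constraint. Re-running with `los_multiplier=0.25` (stays cut to national
benchmark levels) lifts throughput to ~11.9/day at ~71% utilisation.

The same experiment from a shell, plus the full 72-scenario grid:

```bash
orthosim --beds 40 --reps 30 --seed 1 --out results/single
orthosim --grid --reps 30 --seed 1 --out results/grid
```

writing `summary.csv` (per scenario × metric × weekday, with cross-
replication quartiles), `replications.csv` and a reproducibility manifest.
Runs are deterministic per seed: replication *i* uses substream *i* of the
base seed, independent of the scenario, so matched replications share
common random numbers across bed counts.

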