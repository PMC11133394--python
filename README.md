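# rbtsched — random breath test schedule optimisation

Random breath tests (RBTs, sobriety checkpoints) deter drink driving both
through the tests themselves and through drivers who pass an active site and
observe it.  Police resources are limited, so the daily question is *where,
when and for how long* to run test sites on a road network.  `rbtsched` is a
toolkit for that scheduling problem, aimed at transport-safety researchers
and enforcement planners: it builds crash- and traffic-intensity matrices
from point records, clusters days by their 24-hour alcohol-crash profile,
optimises daily schedules with a genetic algorithm under resource
constraints, and evaluates any schedule with a Monte-Carlo drink-driver
simulator.

## The model

A day is divided into t\* = 96 fifteen-minute intervals.  A schedule is a
set of test sites g_w = {t̄_w, ṯ_w, i_w} (start interval, finish interval,
link), equivalently a binary link × interval matrix S with s_{i,t} = 1 when
testing is active.  Feasibility requires

- N ≤ N_max sites per day (default 58),
- t_min ≤ ṯ_w − t̄_w ≤ t_max per site (default 1–3 h),
- Σ_w (ṯ_w − t̄_w) ≤ Δ total (default 58 h).

A site can deliver at most ς = 4 tests/min, so a driver passing when the
flow is f vehicles per interval is tested with probability

    p = 1                    if f·t*/1440 ≤ ς,
    p = 1440·ς / (t*·f)      otherwise.

With C the crash matrix (historical alcohol-related crashes per link and
interval, standing proxy for drink-driver presence) and F the flow matrix
(measured on sensored links, inverse-distance imputed elsewhere with weights
0.5·(1 − d_i/Σd) over the U = 3 nearest sensors), the deterrence fitness of
a schedule is

    V = α·P + β·Q + γ·R,
    P = Σ s·c·p   (expected positive tests)
    Q = Σ s·f·p   (expected total tests)
    R = Σ s·f − Q (observing drivers)

with default weights α = 0.999994, β = 10⁻⁵, γ = −4·10⁻⁶.  A genetic
algorithm over site lists maximises V: elitist selection, one-site-swap
crossover, and an Extend/Split/Generate mutation with probabilities
0.4/0.3/0.3.  Days are first clustered (K = 4) by their 24-bin hourly crash
vectors using a k-medoids variant with a minimum cluster size of
⌈n/(4K)⌉, and each of the 14 date types (holiday/non-holiday × weekday) is
mapped to its majority cluster, so a date to be scheduled uses its cluster's
crash matrix (RBT-opt1) or the overall crash matrix (RBT-opt2).  Benchmarks
are a uniform random scheduler (RBT-rand) and a deterministic greedy
scheduler of 75-minute sites ranked on c̄ = ĉ + 2f/f_max (RBT-det).
Schedules are compared by simulating drink drivers between random
origin/destination pairs along shortest travel-time paths at 50 km/h, with
departure times drawn from the cluster's hourly crash distribution and
first-capture stopping at test sites.

## Worked example

```python
import numpy as np, pandas as pd
import rbtsched as r

bundle = r.make_scenario(r.ScenarioSpec(n_nodes=25, n_days=365, seed=42))
models = r.build_models(bundle, r.RunConfig(seed=42))

day = pd.Timestamp("2016-07-08").date()
print("cluster for", day, "->", models.cluster_for_date(day))

best, trace = r.schedule_for(models, day, "opt1", rng=np.random.default_rng(42))
print(f"GA finished after {len(trace)} generations; "
      f"best fitness {trace['best_fitness'].iloc[-1]:.3f}")
print(f"schedule: {len(best)} sites, {best.total_duration_hours():.2f} h total")

rng = np.random.default_rng(0)
trips = r.generate_trips(models.net, 500, models.eps_for_date(day), 50.0, rng)
res = r.simulate_day(trips, best, models.flow_for_date(day), models.net,
                     models.cfg.capacity, rng)
print(f"positives {res.positives} of {res.n_offenders} offenders; "
      f"expected tests {res.tests_total:.0f}; observers {res.observers:.0f}; "
      f"pct of trip traveled {res.pct_trip_traveled:.1f}%")
```

Output:

```
cluster for 2016-07-08 -> 0
GA finished after 623 generations; best fitness 0.770
schedule: 48 sites, 58.00 h total
positives 170 of 500 offenders; expected tests 3652; observers 12; pct of trip traveled 45.6%
```

The fitness 0.770 is dominated by α·P (expected positives against the
cluster crash matrix); the simulator then catches 170 of 500 simulated
offenders with this schedule, each on average 45.6 % of the way through
their trip.  `tests` adds the expected sober tests from the flow matrix to
the captured offenders; `observers` counts untested pass-bys.

The same workflow is available from the shell via the `rbt` command
(`rbt synth`, `rbt impute`, `rbt cluster`, `rbt optimize`, `rbt benchmark`,
`rbt simulate`, `rbt report`).

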