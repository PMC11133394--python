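# Methods

## Scope and data model

`rbtsched` schedules daily roadside random breath tests (RBTs) on a road
network to maximise a deterrence score, and evaluates schedules by
simulation.  The network is an undirected graph of links with lengths (km)
and speeds (km/h); test sites sit at link midpoints.  All intensities are
link × interval matrices over t\* = 96 fifteen-minute intervals: the flow
matrix F(κ) (vehicles per interval), the crash matrix C(κ) (alcohol-related
crash counts, used as the only observable proxy for drink-driver presence),
and the binary schedule matrix S(κ).  A schedule is equivalently a list of
sites {t̄, ṯ, i}; the two forms are inter-convertible, with a site active
during intervals t̄+1 … ṯ so its duration is ṯ − t̄ intervals.  Internally a
site may have t̄ = 0 (active from midnight); the resource constraints do not
bound t̄, so nothing downstream changes.

## Flow imputation

Sensored links carry measured flows; every other link receives the weighted
combination of its U nearest sensors with weights w_i = 0.5·(1 − d_i/Σd).
The formula is applied literally: the weights sum to 1 only at U = 3, which
is therefore the default; other U are allowed (with an optional
renormalisation switch, off by default) and the non-unit weight sum is the
caller's responsibility.  If every selected sensor is exactly coincident
with the target the ratio d_i/Σd is taken as 1/U (the symmetric limit).
Nearest-sensor ties break to the lowest sensor id; a sensor with no data on
a given day is dropped for that day and the nearest sets recomputed.
Distances are great-circle km by default; a planar option exists for
abstract synthetic networks.  Per-weekday mean matrices F̂(Monday) …
F̂(Sunday) summarise the imputed history and stand in for any date to be
scheduled.

## Day clustering

Days with at least one crash form the clustering set; each is a 24-bin
hourly crash vector.  A k-medoids variant enforces a minimum cluster size of
⌈n/(4K)⌉ so every cluster remains statistically usable: assignment is
nearest-medoid followed by a repair pass that moves the cheapest points
(smallest distance increase, ties to lowest index) out of surplus clusters
until all floors hold; medoids are then refined by within-cluster updates
followed by a PAM-style swap scan, each step accepted only when the floored
objective improves, terminating at a local optimum where no feasible
improving swap exists.  The alternating phase is a cheap warm start; the
swap scan provides the local-optimality guarantee.  Distances are Euclidean
on the count vectors (an L1 option exists).  Cluster summaries are the
per-day mean crash matrix C^k and the hourly departure distribution ε_k
(the cluster's aggregate crash histogram normalised to 1; the simulator
samples the departure hour from it and the minute uniformly).  Each of the
14 date types (holiday/non-holiday × Mon…Sun) maps to the cluster holding
the majority of its days, ties to the lowest cluster index; an unobserved
holiday type falls back to its non-holiday weekday, and a type with no
fallback stays flagged as unmapped.

## Capacity and fitness

A site delivers at most ς = 4 tests/min, giving the tested-driver
probability p = min(1, 1440ς/(t*·f)); flow within an interval is treated as
uniform, and zero flow gives p = 1.  No lower bound on p is imposed.  The
deterrence fitness V = αP + βQ + γR combines expected positives
P = Σ s·c·p, expected tests Q = Σ s·f·p and observers R = Σ s·f − Q.  The
default γ is a small negative number (observers mildly penalised), which
contradicts the all-positive framing of the score; the implementation
accepts any finite weights and logs a warning on sign disagreement.  The
fitness is computed both as the weighted count sum and as a single per-cell
sum, asserted to agree to 1e-9 relative; the GA consumes the per-cell form
through cumulative sums along time, making a schedule's fitness a sum of
O(1) window lookups.

## Genetic algorithm

Populations hold Φ₁ = 100 feasible site schedules (initialised by the random
benchmark scheduler).  Each generation keeps the Φ₂ = 30 fittest, adds
Φ₃ = 34 crossover offspring and Φ₄ = 50 mutation offspring from
tournament-of-2 parents, then truncates the pooled set back to Φ₁ by
fitness.  Φ₂+Φ₃+Φ₄ exceeds Φ₁ by design; truncation resolves it.  Crossover
swaps one uniformly chosen site between the parents; swaps creating
overlapping windows or constraint violations are resampled (budget 20), else
the parents pass through.  Mutation applies exactly one of Extend (a random
site starts one interval earlier with probability p_e = 0.5, else finishes
one later; if the chosen direction is blocked the other is tried), Split
(a site with duration ≥ 2·t_min is cut at a uniform interior boundary
leaving both parts ≥ t_min; a new site on another uniformly chosen link
receives the first part's duration with probability p_s = 0.5, else the
second's, at a uniform feasible start, and the original keeps the remainder)
or Generate (a new site with uniform feasible link, uniform duration in
[t_min, t_max] and uniform start), chosen with probabilities 0.4/0.3/0.3;
infeasible draws are resampled up to the budget and the schedule is returned
unchanged if none succeeds, so every individual ever present is feasible.
Iteration stops after 50 generations without best-fitness improvement or at
1000 generations.  Elites guarantee a non-decreasing best-fitness trace, and
a fixed seed gives a bit-identical run.

## Benchmarks

RBT-rand draws sites with uniform links, starts and durations (durations
uniform in [t_min, t_max]) until adding another site would breach the
site-count or total-duration cap.  RBT-det scores every (link, 75-minute
window) candidate on the modified crash matrix c̄ = ĉ + 2f̂/f̂\* (the
max-flow cell gains exactly +2) and accepts the best non-conflicting
windows greedily — a deterministic approximation of the underlying
combinatorial maximisation (ties break to lower link id, then earlier
start); the exhaustive optimum is kept as a test oracle on tiny instances.
With Δ = 58 h and 1.25-h sites, the duration cap limits RBT-det to 46
sites; this emerges from the constraints, not a special rule.

## Simulator

Drink drivers travel between uniformly drawn distinct connected nodes along
shortest travel-time paths (deterministic lexicographic tie-break on link
ids) at a fixed 50 km/h, departing at ε_k-distributed times.  A driver
occupies link ν during (τ₁ + Σ_{u<ν} l/v, τ₁ + Σ_{u≤ν} l/v) minutes and
meets a site when the midpoint-crossing instant (entry + half the link's
travel time, taken modulo 1440 so post-midnight trip segments land on the
same scheduling day) falls in an active interval; each encounter is an
independent Bernoulli(p) draw and the first success removes the driver.
Sober traffic is not individually simulated: reported totals add the
deterministic expectations Q and R from the flow matrix to the captured
offenders.  The percentage-of-trip-traveled metric averages, over captured
offenders only (a switch can count uncaptured ones at 100 %), the distance
from the origin to the capture midpoint divided by the full
origin-destination path length.  The route-sum expectation Σ s·(Σ_u q)·p
is also available and upper-bounds the first-capture count.  Simulated
crash histories place Poisson-distributed daily counts uniformly along
uniformly chosen trip traces.

## Synthetic scenarios

The generator provides the statistical structure the method assumes, with
one deterministic bundle per seed: a connected grid (or random-geometric)
network; Poisson sensor counts around a weekday diurnal curve peaking
08:00–17:00 (base 48 vehicles/15-min at the peak, 8 off-peak — just under
the 4/min site capacity, matching a mostly rural regime), damped ×0.7 on
weekends, with a lognormal per-link scale (σ = 0.8) plus a small arterial
class (5 % of sensored links at 20× flow) so the network-wide maximum flow
dwarfs the typical link the way metropolitan arterials dwarf rural roads;
and a crash history at 1.24 crashes/day network-wide, times drawn from a
night-heavy mixture (55 % mass after 17:00, 25 % before 04:00, weekends
shifted further into the early morning), counts boosted ×1.6 on weekends
and holidays, locations uniform along uniformly chosen links.  Defaults:
100-node grid, 20 % sensored, 730-day history — sized so the full
cluster → optimise → simulate pipeline runs in minutes on one CPU.

What the generator does *not* emulate: any spatial correlation between
crash locations and traffic (real alcohol crashes concentrate on heavily
used roads, so crash-targeted schedules enjoy a spatial advantage over
random placement that is absent here), congestion-dependent speeds,
and non-uniform offender origin/destination preferences.  Consequently,
passing tests demonstrate the machinery (constraint handling, optimiser
convergence, calibrated capture probabilities, directional superiority of
the optimised schedules over both benchmarks on positives) but not the full
benchmark ordering seen on real data: with spatially uninformative crashes,
the deterministic crash-and-flow benchmark fills most of its 46 sites with
daytime flow-dominant windows, collecting many tests and observers but
fewer positives than even the random scheduler.  The qualitative signature
— the deterministic benchmark showing by far the most observing drivers —
is reproduced.

## Numerical choices and degenerate inputs

Hours↔intervals conversions use exact rational arithmetic and reject
t_min/t_max values that are not whole intervals.  Point-to-link projection
measures to the link midpoint by default (a true point-to-segment option
exists) with ties to the lowest link id.  Empty or zero-length paths yield a
degenerate, flagged trace.  Two sites on one link must be separated by at
least one inactive interval; touching windows merge at canonicalisation.
Validators report every violated clause rather than throwing.  All
randomness flows through explicit numpy Generators seeded from the run
configuration.

## Known limitations

The flow imputation ignores network topology (distance only); the greedy
deterministic benchmark is an approximation of its combinatorial program;
the day-cluster model assumes date-type structure is expressible through a
hard majority map; and the simulator's offender population size per day is
a free parameter (default 500) with no empirical anchor.
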