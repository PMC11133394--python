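"""Genetic algorithm over daily test-site schedules.

Individuals are canonical site schedules.  Each generation keeps the top
phi2 elites, produces phi3 crossover offspring (one uniformly chosen site
swapped between two tournament-selected parents) and phi4 mutation offspring
(one of Extend / Split / Generate applied with probabilities p_E/p_S/p_G),
pools them with the elites and truncates to phi1 by fitness.  Every operator
repairs-or-resamples so that the whole population always satisfies the
resource constraints; elitism makes the best-fitness trace non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fitness import CapacityModel, FitnessWeights, fitness_cell_values, test_probability
from .schedule import ScheduleConstraints, SiteSchedule, TestSite, validate_constraints

log = logging.getLogger(__name__)

__all__ = ["GAParams", "mutate", "crossover", "optimize", "ScheduleEvaluator"]


@dataclass
class GAParams:
    """GA hyperparameters; defaults are the reference configuration."""

    phi1: int = 100  # population size
    phi2: int = 30   # elites kept
    phi3: int = 34   # crossover offspring
    phi4: int = 50   # mutation offspring
    p_extend: float = 0.40
    p_split: float = 0.30
    p_generate: float = 0.30
    p_earlier: float = 0.50   # Extend: start one interval earlier, else finish later
    p_first_part: float = 0.50  # Split: new site copies the first part's duration
    patience: int = 50
    max_generations: int = 1000
    resample_budget: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if abs(self.p_extend + self.p_split + self.p_generate - 1.0) > 1e-9:
            raise ValueError("p_extend + p_split + p_generate must equal 1")
        for p in (self.p_earlier, self.p_first_part):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if not (self.phi1 >= self.phi2 >= 1):
            raise ValueError("need phi1 >= phi2 >= 1")


# --------------------------------------------------------------------- helpers

def _link_windows(schedule: SiteSchedule, skip: int | None = None) -> dict:
    """link -> list of (start, finish) windows, optionally skipping one site."""
    win: dict = {}
    for w, s in enumerate(schedule.sites):
        if w == skip:
            continue
        win.setdefault(s.link, []).append((s.start, s.finish))
    return win


def _feasible_starts(windows, duration: int, t_star: int):
    """Start values a such that window (a, a+duration) conflicts with nothing.

    A gap of at least one inactive interval is required on either side of any
    existing window on the same link.
    """
    out = []
    for a in range(0, t_star - duration + 1):
        b = a + duration
        if all(b < s or a > f for s, f in windows):
            out.append(a)
    return out


def _extend(schedule, params, c, rng):
    if not schedule.sites:
        return None
    w = int(rng.integers(len(schedule)))
    s = schedule.sites[w]
    if s.duration_intervals + 1 > c.t_max_intervals:
        return None
    if schedule.total_duration_intervals + 1 > c.delta_intervals:
        return None
    windows = _link_windows(schedule, skip=w).get(s.link, [])
    earlier_ok = s.start >= 1 and all(s.start - 1 > f for _, f in windows if f <= s.start)
    later_ok = s.finish + 1 <= schedule.t_star and all(
        s.finish + 1 < st for st, _ in windows if st >= s.finish)
    go_earlier = rng.random() < params.p_earlier
    if go_earlier and not earlier_ok:
        go_earlier = False if later_ok else None
    elif not go_earlier and not later_ok:
        go_earlier = True if earlier_ok else None
    if go_earlier is None:
        return None
    new = TestSite(s.start - 1, s.finish, s.link) if go_earlier else \
        TestSite(s.start, s.finish + 1, s.link)
    sites = list(schedule.sites)
    sites[w] = new
    return SiteSchedule.from_sites(sites, t_star=schedule.t_star, day=schedule.day)


def _split(schedule, params, c, link_ids, rng):
    t_min = c.t_min_intervals
    cands = [w for w, s in enumerate(schedule.sites)
             if s.duration_intervals >= 2 * t_min]
    if not cands or len(schedule) + 1 > c.n_max:
        return None
    w = cands[int(rng.integers(len(cands)))]
    s = schedule.sites[w]
    d = s.duration_intervals
    d1 = int(rng.integers(t_min, d - t_min + 1))
    d2 = d - d1
    new_dur = d1 if rng.random() < params.p_first_part else d2
    keep_dur = d - new_dur
    windows = _link_windows(schedule, skip=w)
    # candidate links for the relocated part (any other link without conflict)
    link_pool = [l for l in link_ids if l != s.link]
    if not link_pool:
        return None
    link = link_pool[int(rng.integers(len(link_pool)))]
    starts = _feasible_starts(windows.get(link, []), new_dur, schedule.t_star)
    if not starts:
        return None
    a = starts[int(rng.integers(len(starts)))]
    sites = list(schedule.sites)
    sites[w] = TestSite(s.start, s.start + keep_dur, s.link)
    sites.append(TestSite(a, a + new_dur, link))
    return SiteSchedule.from_sites(sites, t_star=schedule.t_star, day=schedule.day)


def _generate(schedule, c, link_ids, rng):
    if len(schedule) + 1 > c.n_max:
        return None
    room = c.delta_intervals - schedule.total_duration_intervals
    hi = min(c.t_max_intervals, room)
    if hi < c.t_min_intervals:
        return None
    dur = int(rng.integers(c.t_min_intervals, hi + 1))
    windows = _link_windows(schedule)
    link = link_ids[int(rng.integers(len(link_ids)))]
    starts = _feasible_starts(windows.get(link, []), dur, schedule.t_star)
    if not starts:
        return None
    a = starts[int(rng.integers(len(starts)))]
    sites = list(schedule.sites) + [TestSite(a, a + dur, link)]
    return SiteSchedule.from_sites(sites, t_star=schedule.t_star, day=schedule.day)


def mutate(schedule: SiteSchedule, params: GAParams, constraints: ScheduleConstraints,
           link_ids, rng) -> SiteSchedule:
    """Apply one of Extend / Split / Generate; repair-or-resample.

    Resamples the operation up to the resample budget; if no feasible
    mutation is found the schedule is returned unchanged.
    """
    ops = np.array([params.p_extend, params.p_split, params.p_generate])
    for _ in range(params.resample_budget):
        op = rng.choice(3, p=ops)
        if op == 0:
            out = _extend(schedule, params, constraints, rng)
        elif op == 1:
            out = _split(schedule, params, constraints, link_ids, rng)
        else:
            out = _generate(schedule, constraints, link_ids, rng)
        if out is not None and not validate_constraints(out, constraints):
            return out
    log.debug("no feasible mutation after %d resamples", params.resample_budget)
    return schedule


def crossover(s1: SiteSchedule, s2: SiteSchedule, rng,
              constraints: ScheduleConstraints, resample_budget: int = 20):
    """Swap one uniformly chosen site between the parents.

    Swaps producing overlapping/touching windows or constraint violations are
    resampled; after the budget is exhausted the parents are returned.
    """
    if not s1.sites or not s2.sites:
        return s1, s2
    for _ in range(resample_budget):
        a = s1.sites[int(rng.integers(len(s1)))]
        b = s2.sites[int(rng.integers(len(s2)))]
        try:
            c1 = SiteSchedule(tuple(sorted((set(s1.sites) - {a}) | {b},
                                           key=lambda s: (s.link, s.start))),
                              t_star=s1.t_star, day=s1.day)
            c2 = SiteSchedule(tuple(sorted((set(s2.sites) - {b}) | {a},
                                           key=lambda s: (s.link, s.start))),
                              t_star=s2.t_star, day=s2.day)
        except ValueError:
            continue
        if validate_constraints(c1, constraints) or validate_constraints(c2, constraints):
            continue
        return c1, c2
    return s1, s2


# ------------------------------------------------------------------- optimizer

class ScheduleEvaluator:
    """Fast fitness via per-cell values and a cumulative sum over time."""

    def __init__(self, C, F, weights: FitnessWeights, cap: CapacityModel, link_ids):
        C = np.asarray(C, dtype=float)
        F = np.asarray(F, dtype=float)
        if C.shape != F.shape:
            raise ValueError("crash and flow matrices must share shape")
        self.link_ids = np.asarray(link_ids)
        if len(self.link_ids) != C.shape[0]:
            raise ValueError("link_ids length must match matrix rows")
        self.t_star = C.shape[1]
        self._row = {lid: i for i, lid in enumerate(self.link_ids)}
        W = fitness_cell_values(C, F, weights, cap)
        self._wcs = np.concatenate([np.zeros((W.shape[0], 1)), np.cumsum(W, axis=1)], axis=1)
        p = test_probability(F, cap)
        self._pc_cs = np.concatenate([np.zeros((C.shape[0], 1)),
                                      np.cumsum(p * C, axis=1)], axis=1)
        self._pf_cs = np.concatenate([np.zeros((C.shape[0], 1)),
                                      np.cumsum(p * F, axis=1)], axis=1)
        self._f_cs = np.concatenate([np.zeros((C.shape[0], 1)),
                                     np.cumsum(F, axis=1)], axis=1)

    def __call__(self, schedule: SiteSchedule) -> float:
        return float(sum(self._wcs[self._row[s.link], s.finish]
                         - self._wcs[self._row[s.link], s.start]
                         for s in schedule.sites))

    def counts(self, schedule: SiteSchedule):
        P = Q = flow = 0.0
        for s in schedule.sites:
            r = self._row[s.link]
            P += self._pc_cs[r, s.finish] - self._pc_cs[r, s.start]
            Q += self._pf_cs[r, s.finish] - self._pf_cs[r, s.start]
            flow += self._f_cs[r, s.finish] - self._f_cs[r, s.start]
        return P, Q, flow - Q


def _tournament(pop, fits, rng):
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    return pop[i] if fits[i] >= fits[j] else pop[j]


def optimize(C, F, weights: FitnessWeights, cap: CapacityModel,
             constraints: ScheduleConstraints, params: GAParams, link_ids,
             rng=None, initial_population=None):
    """Run the GA; returns (best_schedule, trace DataFrame).

    The trace has one row per generation with the best fitness, the best
    schedule's expected positives/tests/observers, and the number of distinct
    fitness values in the population (a diversity summary).
    """
    from .benchmarks import random_schedule  # deferred: benchmarks uses schedule only

    # constraint feasibility is validated by construction of `constraints`
    _ = constraints.t_min_intervals, constraints.t_max_intervals
    if rng is None:
        rng = np.random.default_rng(params.seed)
    evaluate = ScheduleEvaluator(C, F, weights, cap, link_ids)
    link_ids = list(evaluate.link_ids)

    if initial_population is None:
        pop = [random_schedule(link_ids, constraints, rng,
                               t_star=constraints.t_star) for _ in range(params.phi1)]
    else:
        pop = list(initial_population)
    fits = [evaluate(s) for s in pop]

    rows = []
    best_fit = -np.inf
    best_schedule = None
    stale = 0
    for gen in range(params.max_generations):
        order = sorted(range(len(pop)), key=lambda i: -fits[i])
        elites = [pop[i] for i in order[:params.phi2]]
        elite_fits = [fits[i] for i in order[:params.phi2]]

        children = []
        while len(children) < params.phi3:
            p1 = _tournament(pop, fits, rng)
            p2 = _tournament(pop, fits, rng)
            c1, c2 = crossover(p1, p2, rng, constraints, params.resample_budget)
            children.extend([c1, c2])
        children = children[:params.phi3]
        for _ in range(params.phi4):
            parent = _tournament(pop, fits, rng)
            children.append(mutate(parent, params, constraints, link_ids, rng))

        child_fits = [evaluate(s) for s in children]
        pool = elites + children
        pool_fits = elite_fits + child_fits
        order = sorted(range(len(pool)), key=lambda i: -pool_fits[i])[:params.phi1]
        pop = [pool[i] for i in order]
        fits = [pool_fits[i] for i in order]

        if fits[0] > best_fit + 1e-12:
            best_fit, best_schedule = fits[0], pop[0]
            stale = 0
        else:
            stale += 1
        P, Q, R = evaluate.counts(best_schedule)
        rows.append({"generation": gen, "best_fitness": best_fit,
                     "best_P": P, "best_Q": Q, "best_R": R,
                     "distinct_fitness": len(set(np.round(fits, 9)))})
        if stale >= params.patience:
            break
    return best_schedule, pd.DataFrame(rows)
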