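"""GA operators (Extend/Split/Generate, site-swap crossover) and the optimiser."""

import itertools

import numpy as np
import pytest

from rbtsched.benchmarks import random_schedule
from rbtsched.fitness import CapacityModel, FitnessWeights
from rbtsched.ga import (GAParams, ScheduleEvaluator, crossover, mutate, optimize)
from rbtsched.schedule import (ScheduleConstraints, SiteSchedule, TestSite,
                               validate_constraints)

LINKS = list(range(8))
CONS = ScheduleConstraints(n_max=6, delta_h=12.0)


def make_params(**kw):
    defaults = dict(seed=0)
    defaults.update(kw)
    return GAParams(**defaults)


class TestParams:
    def test_operation_probabilities_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GAParams(p_extend=0.5, p_split=0.5, p_generate=0.5)

    def test_population_ordering_enforced(self):
        with pytest.raises(ValueError):
            GAParams(phi1=10, phi2=20)


class TestMutate:
    def test_extend_starts_one_interval_earlier(self):
        sched = SiteSchedule((TestSite(40, 44, 2),), t_star=96)
        params = make_params(p_extend=1.0, p_split=0.0, p_generate=0.0, p_earlier=1.0)
        rng = np.random.default_rng(0)
        out = mutate(sched, params, CONS, LINKS, rng)
        assert out.sites == (TestSite(39, 44, 2),)

    def test_extend_finishes_one_interval_later(self):
        sched = SiteSchedule((TestSite(40, 44, 2),), t_star=96)
        params = make_params(p_extend=1.0, p_split=0.0, p_generate=0.0, p_earlier=0.0)
        out = mutate(sched, params, CONS, LINKS, np.random.default_rng(0))
        assert out.sites == (TestSite(40, 45, 2),)

    def test_split_requires_twice_minimum_duration(self):
        # a 1-h site cannot split under t_min = 1 h; with only Split enabled
        # the schedule must come back unchanged
        sched = SiteSchedule((TestSite(40, 44, 2),), t_star=96)
        params = make_params(p_extend=0.0, p_split=1.0, p_generate=0.0)
        out = mutate(sched, params, CONS, LINKS, np.random.default_rng(0))
        assert out.sites == sched.sites

    def test_split_conserves_total_duration(self):
        sched = SiteSchedule((TestSite(10, 22, 2),), t_star=96)  # 3 h
        params = make_params(p_extend=0.0, p_split=1.0, p_generate=0.0)
        out = mutate(sched, params, CONS, LINKS, np.random.default_rng(1))
        assert len(out) == 2
        assert out.total_duration_intervals == 12
        links = {s.link for s in out.sites}
        assert 2 in links and len(links) == 2

    def test_generate_adds_a_site(self):
        sched = SiteSchedule((TestSite(0, 8, 0),), t_star=96)
        params = make_params(p_extend=0.0, p_split=0.0, p_generate=1.0)
        out = mutate(sched, params, CONS, LINKS, np.random.default_rng(2))
        assert len(out) == 2
        new = [s for s in out.sites if s != TestSite(0, 8, 0)][0]
        assert CONS.t_min_intervals <= new.duration_intervals <= CONS.t_max_intervals

    def test_mutations_always_feasible(self):
        """Thousands of mutations of random feasible schedules stay feasible."""
        rng = np.random.default_rng(7)
        params = make_params()
        for _ in range(300):
            sched = random_schedule(LINKS, CONS, rng)
            for _ in range(5):
                sched = mutate(sched, params, CONS, LINKS, rng)
                assert validate_constraints(sched, CONS) == []


class TestCrossover:
    def parents(self):
        s1 = SiteSchedule.from_sites([(0, 4, 0), (10, 14, 1), (20, 24, 2), (30, 34, 3)])
        s2 = SiteSchedule.from_sites([(40, 44, 4), (50, 54, 5), (60, 64, 6), (70, 74, 7)])
        return s1, s2

    def test_exactly_one_site_swapped(self):
        s1, s2 = self.parents()
        rng = np.random.default_rng(0)
        c1, c2 = crossover(s1, s2, rng, CONS)
        moved_out = set(s1.sites) - set(c1.sites)
        moved_in = set(c1.sites) - set(s1.sites)
        assert len(moved_out) == 1 and len(moved_in) == 1
        assert moved_in.pop() in s2.sites
        # the union of the two offspring equals the union of the parents
        assert set(c1.sites) | set(c2.sites) == set(s1.sites) | set(s2.sites)

    def test_empty_parent_returned_unchanged(self):
        s1 = SiteSchedule((), t_star=96)
        s2 = SiteSchedule.from_sites([(0, 4, 0)])
        assert crossover(s1, s2, np.random.default_rng(0), CONS) == (s1, s2)

    def test_conflicting_swap_resampled_or_rejected(self):
        # both parents have one site each on link 0 with overlapping windows:
        # swapping must not create two overlapping sites
        s1 = SiteSchedule.from_sites([(0, 4, 0), (10, 14, 1)])
        s2 = SiteSchedule.from_sites([(2, 6, 0)])
        rng = np.random.default_rng(0)
        for _ in range(20):
            c1, c2 = crossover(s1, s2, rng, CONS)
            assert validate_constraints(c1, CONS) == []
            assert validate_constraints(c2, CONS) == []

    def test_offspring_always_feasible(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            s1 = random_schedule(LINKS, CONS, rng)
            s2 = random_schedule(LINKS, CONS, rng)
            c1, c2 = crossover(s1, s2, rng, CONS)
            assert validate_constraints(c1, CONS) == []
            assert validate_constraints(c2, CONS) == []


def toy_problem():
    """2 links x 8 intervals, one 2-interval site allowed: 14 candidates."""
    cons = ScheduleConstraints(n_max=1, t_min_h=6.0, t_max_h=6.0, delta_h=6.0, t_star=8)
    rng = np.random.default_rng(99)
    C = rng.poisson(1.0, size=(2, 8)).astype(float)
    F = rng.uniform(0, 200, size=(2, 8))
    cap = CapacityModel(varsigma=4.0, t_star=8)
    w = FitnessWeights()
    return cons, C, F, cap, w


def exhaustive_optimum(cons, C, F, cap, w, links=(0, 1)):
    ev = ScheduleEvaluator(C, F, w, cap, links)
    best = -np.inf
    dur = cons.t_min_intervals
    for link in links:
        for a in range(0, cons.t_star - dur + 1):
            s = SiteSchedule((TestSite(a, a + dur, link),), t_star=cons.t_star)
            best = max(best, ev(s))
    return best


class TestOptimize:
    def test_reaches_exhaustive_optimum_on_toy(self):
        cons, C, F, cap, w = toy_problem()
        target = exhaustive_optimum(cons, C, F, cap, w)
        hits = 0
        for seed in range(10):
            params = make_params(seed=seed, max_generations=200, patience=30)
            best, trace = optimize(C, F, w, cap, cons, params, [0, 1])
            if trace["best_fitness"].iloc[-1] >= target - 1e-9:
                hits += 1
        assert hits >= 9

    def test_trace_is_nondecreasing(self):
        cons, C, F, cap, w = toy_problem()
        params = make_params(seed=1, max_generations=60, patience=20,
                             phi1=20, phi2=5, phi3=6, phi4=8)
        _, trace = optimize(C, F, w, cap, cons, params, [0, 1])
        assert trace["best_fitness"].is_monotonic_increasing

    def test_same_seed_same_result(self):
        cons, C, F, cap, w = toy_problem()
        params = make_params(seed=5, max_generations=40, patience=15,
                             phi1=20, phi2=5, phi3=6, phi4=8)
        b1, t1 = optimize(C, F, w, cap, cons, params, [0, 1])
        b2, t2 = optimize(C, F, w, cap, cons, params, [0, 1])
        assert b1.sites == b2.sites
        assert t1["best_fitness"].tolist() == t2["best_fitness"].tolist()

    def test_population_feasibility_closure(self):
        cons, C, F, cap, w = toy_problem()
        params = make_params(seed=2, max_generations=25, patience=25,
                             phi1=15, phi2=4, phi3=4, phi4=6)
        best, _ = optimize(C, F, w, cap, cons, params, [0, 1])
        assert validate_constraints(best, cons) == []
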