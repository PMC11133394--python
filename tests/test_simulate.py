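"""Drink-driver trip generation, first-capture simulation and reporting."""

import numpy as np
import pytest
from scipy import stats

from rbtsched.fitness import CapacityModel
from rbtsched.schedule import ScheduleConstraints, SiteSchedule, TestSite
from rbtsched.simulate import (crashes_per_day, generate_trips, km_per_day,
                               sample_departure, simulate_day,
                               synthesize_crashes, trips_per_day)

from conftest import build_net

CAP = CapacityModel()


def uniform_eps():
    return np.full(24, 1.0 / 24)


def one_link_net(length=10.0):
    return build_net({0: (0.0, 0.0), 1: (0.0, 0.5)},
                     [(0, 0, 1, length, 50.0)], metric="euclidean")


class TestScaleArithmetic:
    def test_daily_km_from_yearly(self):
        assert km_per_day(6.36e10) == pytest.approx(1.74e8, rel=0.005)

    def test_daily_trip_count(self):
        assert trips_per_day(km_per_day(6.36e10), 8.9) == pytest.approx(2e7, rel=0.05)

    def test_daily_crash_rate(self):
        assert round(crashes_per_day(2256, 5), 2) == 1.24


class TestTrips:
    def test_zero_drivers(self, small_net, rng):
        assert generate_trips(small_net, 0, uniform_eps(), 50.0, rng) == []

    def test_degenerate_departure_hour(self, small_net, rng):
        eps = np.zeros(24); eps[22] = 1.0
        trips = generate_trips(small_net, 50, eps, 50.0, rng)
        assert all(22 * 60 <= t.tau1 < 23 * 60 for t in trips)

    def test_origin_differs_from_destination(self, small_net, rng):
        trips = generate_trips(small_net, 100, uniform_eps(), 50.0, rng)
        assert all(t.origin != t.destination for t in trips)
        assert all(len(t.trace.links) >= 1 for t in trips)

    def test_departure_histogram_matches_pmf(self, small_net):
        rng = np.random.default_rng(0)
        eps = np.zeros(24)
        eps[[1, 18, 20, 22]] = [0.1, 0.3, 0.4, 0.2]
        hours = [int(sample_departure(eps, rng) // 60) for _ in range(10000)]
        observed = np.bincount(hours, minlength=24)[[1, 18, 20, 22]]
        _, pval = stats.chisquare(observed, 10000 * eps[[1, 18, 20, 22]])
        assert pval > 0.01

    def test_bad_pmf_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_departure(np.full(24, 0.5), rng)

    def test_too_small_network_rejected(self, rng):
        net = one_link_net()
        tiny = build_net({0: (0.0, 0.0)}, [], metric="euclidean")
        import pandas as pd
        with pytest.raises(ValueError):
            generate_trips(tiny, 1, uniform_eps(), 50.0, rng)


class TestSimulateDay:
    def schedule_all_day(self, link=0, t_star=96):
        return SiteSchedule((TestSite(0, t_star, link),), t_star=t_star)

    def test_certain_capture_at_midpoint(self, rng):
        net = one_link_net()
        eps = np.zeros(24); eps[10] = 1.0
        trips = generate_trips(net, 5, eps, 50.0, rng)
        F = np.zeros((1, 96))  # zero flow -> p = 1
        res = simulate_day(trips, self.schedule_all_day(), F, net, CAP, rng)
        assert res.positives == 5
        assert res.pct_trip_traveled == pytest.approx(50.0)

    def test_empty_schedule_catches_nobody(self, small_net, rng):
        trips = generate_trips(small_net, 20, uniform_eps(), 50.0, rng)
        empty = SiteSchedule((), t_star=96)
        res = simulate_day(trips, empty, np.zeros((small_net.n_links, 96)),
                           small_net, CAP, rng)
        assert res.positives == 0
        assert res.pct_trip_traveled is None
        assert res.tests_total == 0.0

    def test_binomial_capture_rate(self):
        """10k single-encounter trips at p = 0.5: positives within 3 SE of 5000."""
        net = one_link_net()
        rng = np.random.default_rng(4)
        eps = np.zeros(24); eps[12] = 1.0
        trips = generate_trips(net, 10000, eps, 50.0, rng)
        F = np.full((1, 96), 120.0)  # p = 0.5 everywhere
        res = simulate_day(trips, self.schedule_all_day(), F, net, CAP, rng)
        se = np.sqrt(10000 * 0.5 * 0.5)
        assert abs(res.positives - 5000) <= 3 * se
        # sober expectations ride along: Q + R = total scheduled flow
        assert res.tests_total - res.positives + res.observers == pytest.approx(
            96 * 120.0)

    def test_first_capture_under_route_sum_bound(self, grid_net):
        """Simulated positives never exceed the route-sum expectation."""
        rng = np.random.default_rng(8)
        trips = generate_trips(grid_net, 300, uniform_eps(), 50.0, rng)
        sched = SiteSchedule.from_sites(
            [(0, 96, lid) for lid in grid_net.link_ids[:20]], t_star=96)
        F = np.zeros((grid_net.n_links, 96))  # p = 1: every encounter captures
        res = simulate_day(trips, sched, F, grid_net, CAP, rng)
        from rbtsched.schedule import sites_to_matrix
        S = sites_to_matrix(sched, grid_net.link_ids).astype(float)
        # route-sum Lambda counts each encountered site once per driver
        encounters = 0
        dt = 1440.0 / 96
        for t in trips:
            for link, entry in zip(t.trace.links, t.trace.entry):
                mid = (entry + (grid_net.link_length(link) / 2) / 50.0 * 60.0) % 1440
                if S[grid_net.link_row(link), int(mid // dt)]:
                    encounters += 1
        assert res.positives <= encounters

    def test_fixed_seed_bit_identical(self, small_net):
        F = np.full((small_net.n_links, 96), 100.0)
        sched = SiteSchedule.from_sites([(30, 42, int(small_net.link_ids[3]))])
        results = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            trips = generate_trips(small_net, 100, uniform_eps(), 50.0, rng)
            res = simulate_day(trips, sched, F, small_net, CAP, rng)
            results.append((res.positives, res.tests_total, res.pct_trip_traveled,
                            res.drivers["captured"].tolist()))
        assert results[0] == results[1]


class TestSynthesizeCrashes:
    def test_zero_rate(self, small_net, rng):
        trips = generate_trips(small_net, 10, uniform_eps(), 50.0, rng)
        assert synthesize_crashes(small_net, trips, 0.0, rng) == []

    def test_poisson_mean_recovered(self, small_net):
        rng = np.random.default_rng(5)
        trips = generate_trips(small_net, 30, uniform_eps(), 50.0, rng)
        counts = [len(synthesize_crashes(small_net, trips, 1.24, rng))
                  for _ in range(1000)]
        se = np.sqrt(1.24 / 1000)
        assert abs(np.mean(counts) - 1.24) <= 3 * se

    def test_crashes_lie_on_trip_traces(self, small_net):
        rng = np.random.default_rng(6)
        trips = generate_trips(small_net, 20, uniform_eps(), 50.0, rng)
        crashes = synthesize_crashes(small_net, trips, 20.0, rng)
        trip_links = {l for t in trips for l in t.trace.links}
        for c in crashes:
            assert 0 <= c.time_min < 1440
            assert small_net.project_point(c.location) in trip_links
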