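"""Crash matrices, size-constrained k-medoids, and date-type mapping."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from rbtsched.crashes import (ConstrainedKMedoids, CrashRecord, DayClusterModel,
                              build_crash_matrices, cluster_summaries, date_type,
                              kmedoids_min_size, map_date_types)
from rbtsched.network import GeoPoint
from rbtsched.synth import make_daily_profile_vectors


def rec(date, hh, mm, point):
    return CrashRecord(date=date, time_min=hh * 60 + mm, location=point)


class TestCrashMatrices:
    def test_single_crash_increments_one_cell(self, small_net):
        p = small_net.midpoint(3)
        data = build_crash_matrices([rec(dt.date(2016, 1, 4), 0, 7, p)], small_net)
        C = data.day_matrix(dt.date(2016, 1, 4))
        assert C[small_net.link_row(3), 0] == 1
        assert C.sum() == 1

    def test_boundary_bin_2359_is_interval_96(self, small_net):
        p = small_net.midpoint(0)
        data = build_crash_matrices([rec(dt.date(2016, 1, 4), 23, 59, p)], small_net)
        assert data.events["interval"].iloc[0] == 96

    def test_total_count_conserved(self, small_net, rng):
        records = [rec(dt.date(2016, 1, 4) + dt.timedelta(int(rng.integers(0, 30))),
                       int(rng.integers(0, 24)), int(rng.integers(0, 60)),
                       small_net.midpoint(int(rng.choice(small_net.link_ids))))
                   for _ in range(57)]
        data = build_crash_matrices(records, small_net)
        assert data.overall_matrix().sum() == 57
        days, psi = data.daily_vectors()
        assert psi.sum() == 57

    def test_t_star_must_divide_day(self, small_net):
        with pytest.raises(ValueError):
            build_crash_matrices([], small_net, t_star=100)


class TestConstrainedKMedoids:
    def test_k1_medoid_minimises_total_distance(self, rng):
        X = rng.normal(size=(40, 24))
        km = ConstrainedKMedoids(n_clusters=1, random_state=0).fit(X)
        D = cdist(X, X)
        assert km.medoid_indices_[0] == int(np.argmin(D.sum(axis=1)))
        assert km.inertia_ == pytest.approx(D.sum(axis=1).min())

    def test_recovers_two_separated_groups(self):
        rng = np.random.default_rng(0)
        night = rng.poisson(5.0, size=(60, 24)) * (np.arange(24) >= 18)
        day = rng.poisson(5.0, size=(60, 24)) * ((np.arange(24) > 8) & (np.arange(24) < 17))
        X = np.vstack([night, day])
        labels = ConstrainedKMedoids(n_clusters=2, random_state=1).fit_predict(X)
        from sklearn.metrics import adjusted_rand_score
        truth = np.repeat([0, 1], 60)
        assert adjusted_rand_score(truth, labels) >= 0.9

    def test_planted_four_profiles_recovered_over_seeds(self):
        """Four distinct hourly profiles are recovered (ARI >= 0.9, 10 seeds)."""
        psi, truth = make_daily_profile_vectors(n_days=320, crashes_per_day=40,
                                                separation=4.0, seed=11)
        from sklearn.metrics import adjusted_rand_score
        for seed in range(10):
            labels = ConstrainedKMedoids(n_clusters=4, random_state=seed).fit_predict(psi)
            assert adjusted_rand_score(truth, labels) >= 0.9

    def test_size_floor_met_and_partition(self):
        psi, _ = make_daily_profile_vectors(n_days=200, seed=3)
        km = kmedoids_min_size(psi, 4, seed=5)
        sizes = np.bincount(km.labels_, minlength=4)
        assert sizes.sum() == 200
        assert sizes.min() >= int(np.ceil(200 / 16))

    def test_objective_nonincreasing(self):
        psi, _ = make_daily_profile_vectors(n_days=150, seed=9)
        km = kmedoids_min_size(psi, 3, seed=2)
        trace = np.array(km.objective_trace_)
        assert (np.diff(trace) <= 1e-9).all()

    def test_repair_enforces_floor_every_call(self, rng):
        D = rng.uniform(size=(30, 3))
        labels = ConstrainedKMedoids._assign(D, floor=8)
        assert np.bincount(labels, minlength=3).min() >= 8

    def test_infeasible_floor_rejected(self):
        X = np.zeros((5, 24))
        with pytest.raises(ValueError):
            ConstrainedKMedoids(n_clusters=4, size_floor=2).fit(X)

    def test_medoids_are_members(self):
        psi, _ = make_daily_profile_vectors(n_days=100, seed=1)
        km = kmedoids_min_size(psi, 4, seed=1)
        for k, idx in enumerate(km.medoid_indices_):
            np.testing.assert_array_equal(km.cluster_centers_[k], psi[idx])

    def test_sklearn_param_interface(self):
        km = ConstrainedKMedoids(n_clusters=3)
        km.set_params(n_clusters=5, random_state=7)
        assert km.get_params()["n_clusters"] == 5
        with pytest.raises(ValueError):
            km.set_params(bogus=1)


class TestDateTypes:
    def make_calendar(self, days):
        return pd.DataFrame({"date": days,
                             "is_holiday": [0] * len(days)})

    def test_majority_mapping(self):
        # 10 Mondays: 4 in cluster 0, 6 in cluster 1 -> o(Monday) = 1
        days = [dt.date(2016, 1, 4) + dt.timedelta(7 * i) for i in range(10)]
        labels = np.array([0] * 4 + [1] * 6)
        cal = self.make_calendar(days)
        o, m = map_date_types(labels, days, cal, K=2)
        assert o[date_type(days[0], False)] == 1
        assert m[0, 0] == 4 and m[1, 0] == 6

    def test_tie_goes_to_lowest_cluster(self):
        days = [dt.date(2016, 1, 4) + dt.timedelta(7 * i) for i in range(4)]
        labels = np.array([1, 1, 0, 0])
        o, _ = map_date_types(labels, days, self.make_calendar(days), K=2)
        assert o[0] == 0

    def test_holiday_fallback_to_same_weekday(self):
        days = [dt.date(2016, 1, 4) + dt.timedelta(7 * i) for i in range(3)]
        labels = np.array([2, 2, 2])
        o, _ = map_date_types(labels, days, self.make_calendar(days), K=3)
        # no holiday Mondays observed: falls back to non-holiday Monday cluster
        assert o[7] == o[0] == 2

    def test_planted_type_structure_recovered(self):
        # weekends planted in cluster 1, weekdays in cluster 0
        days = [dt.date(2016, 1, 4) + dt.timedelta(i) for i in range(28)]
        labels = np.array([1 if d.weekday() >= 5 else 0 for d in days])
        o, m = map_date_types(labels, days, self.make_calendar(days), K=2)
        for j in range(7):
            assert o[j] == (1 if j >= 5 else 0)
        assert m.sum() == 28

    def test_missing_calendar_label_rejected(self):
        days = [dt.date(2016, 1, 4)]
        with pytest.raises(ValueError):
            map_date_types(np.array([0]), days, self.make_calendar([]), K=1)


class TestClusterSummaries:
    def test_singleton_cluster_matrix_is_that_day(self, small_net):
        d1, d2 = dt.date(2016, 1, 4), dt.date(2016, 1, 5)
        records = [rec(d1, 22, 0, small_net.midpoint(1)),
                   rec(d2, 9, 0, small_net.midpoint(2)),
                   rec(d2, 9, 30, small_net.midpoint(2))]
        data = build_crash_matrices(records, small_net)
        days, _ = data.daily_vectors()
        mats, eps = cluster_summaries(data, days, np.array([0, 1]), K=2)
        np.testing.assert_array_equal(mats[0], data.day_matrix(d1))
        np.testing.assert_array_equal(mats[1], data.day_matrix(d2))
        for k in (0, 1):
            assert eps[k].sum() == pytest.approx(1.0)
        assert eps[0][22] == 1.0

    def test_two_identical_days_mean_equals_either(self, small_net):
        d1, d2 = dt.date(2016, 1, 4), dt.date(2016, 1, 5)
        records = [rec(d, 20, 15, small_net.midpoint(4)) for d in (d1, d2)]
        data = build_crash_matrices(records, small_net)
        days, _ = data.daily_vectors()
        mats, _ = cluster_summaries(data, days, np.array([0, 0]), K=1)
        np.testing.assert_array_equal(mats[0], data.day_matrix(d1))


class TestDayClusterModel:
    def test_fit_roundtrip(self, small_net, tmp_path, rng):
        days = [dt.date(2016, 1, 4) + dt.timedelta(i) for i in range(120)]
        records = []
        for d in days:
            for _ in range(1 + int(rng.integers(0, 3))):
                hour = 20 if d.weekday() < 5 else 1
                records.append(rec(d, hour, int(rng.integers(0, 60)),
                                   small_net.midpoint(int(rng.choice(small_net.link_ids)))))
        cal = pd.DataFrame({"date": days, "is_holiday": [0] * len(days)})
        data = build_crash_matrices(records, small_net)
        model = DayClusterModel.fit(data, cal, K=2, seed=0)
        assert set(model.matrices) == {0, 1}
        assert model.cluster_for_date(days[0], False) in (0, 1)
        model.to_json(tmp_path / "model.json")
        assert (tmp_path / "model.json").stat().st_size > 0
        pct = model.row_percentages()
        observed = model.m.sum(axis=0) > 0
        np.testing.assert_allclose(pct[:, observed].sum(axis=0), 100.0)
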