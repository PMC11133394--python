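"""Crash matrices, day clustering by 24-h crash profile, and date-type maps.

Alcohol-related crash records (date, time, lat/lon) stand proxy for drink
driving.  Each record is projected to its nearest link and binned into one of
t* daily intervals, giving per-day crash matrices C(kappa), the overall matrix
C_hat, and 24-dimensional hourly crash vectors psi_kappa.  Days with at least
one crash are clustered by a k-medoids variant with a minimum-cluster-size
floor ceil(n/(4K)), and each of the 14 date types (holiday/non-holiday x
Mon..Sun) is mapped to its majority cluster.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .network import GeoPoint, RoadNetwork

log = logging.getLogger(__name__)

__all__ = [
    "CrashRecord",
    "CrashData",
    "build_crash_matrices",
    "ConstrainedKMedoids",
    "kmedoids_min_size",
    "date_type",
    "DATE_TYPE_LABELS",
    "map_date_types",
    "cluster_summaries",
    "DayClusterModel",
]

_WD = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")
DATE_TYPE_LABELS = tuple(f"{h} {w}" for h in ("Non-holiday", "Holiday") for w in _WD)
N_DATE_TYPES = 14


@dataclass(frozen=True)
class CrashRecord:
    date: object  # datetime.date
    time_min: float  # minutes since 00:00
    location: GeoPoint

    def __post_init__(self) -> None:
        if not (0.0 <= self.time_min < 1440.0):
            raise ValueError("crash time must be in [0, 1440) minutes")


def date_type(date, is_holiday: bool) -> int:
    """0..13 index: holiday flag * 7 + weekday (Monday = 0)."""
    return int(bool(is_holiday)) * 7 + pd.Timestamp(date).weekday()


@dataclass
class CrashData:
    """Projected, binned crash events plus the matrices derived from them."""

    events: pd.DataFrame  # columns: date, link_id, interval (1..t*), hour (0..23)
    net: RoadNetwork
    t_star: int = 96

    def day_matrix(self, date) -> np.ndarray:
        """Per-day crash matrix C(kappa), shape (n_links, t_star)."""
        C = np.zeros((self.net.n_links, self.t_star))
        sub = self.events[self.events["date"] == date]
        for r in sub.itertuples(index=False):
            C[self.net.link_row(r.link_id), r.interval - 1] += 1
        return C

    def overall_matrix(self) -> np.ndarray:
        """C_hat: crash counts summed over every day in the history."""
        C = np.zeros((self.net.n_links, self.t_star))
        rows = self.events["link_id"].map(self.net.link_row).to_numpy()
        np.add.at(C, (rows, self.events["interval"].to_numpy() - 1), 1.0)
        return C

    def mean_matrix(self, dates) -> np.ndarray:
        """Per-day mean crash matrix over a set of dates (cluster matrix C^k)."""
        dates = list(dates)
        if not dates:
            raise ValueError("empty date set")
        C = np.zeros((self.net.n_links, self.t_star))
        sub = self.events[self.events["date"].isin(dates)]
        rows = sub["link_id"].map(self.net.link_row).to_numpy()
        np.add.at(C, (rows, sub["interval"].to_numpy() - 1), 1.0)
        return C / len(dates)

    def daily_vectors(self):
        """(days, Psi): days with >= 1 crash and their 24-bin hourly vectors."""
        counts = self.events.groupby(["date", "hour"]).size()
        days = sorted({d for d, _ in counts.index})
        psi = np.zeros((len(days), 24))
        idx = {d: i for i, d in enumerate(days)}
        for (d, h), n in counts.items():
            psi[idx[d], h] = n
        return days, psi


def build_crash_matrices(records, net: RoadNetwork, t_star: int = 96) -> CrashData:
    """Project crash records onto the network and bin into t* intervals."""
    if 1440 % t_star:
        raise ValueError("t_star must divide 1440")
    dt = 1440.0 / t_star
    rows = []
    for rec in records:
        lid = net.project_point(rec.location)
        rows.append({"date": rec.date, "link_id": lid,
                     "interval": int(rec.time_min // dt) + 1,
                     "hour": int(rec.time_min // 60)})
    cols = ["date", "link_id", "interval", "hour"]
    return CrashData(events=pd.DataFrame(rows, columns=cols), net=net, t_star=t_star)


# --------------------------------------------------------------------------
# Size-constrained k-medoids
# --------------------------------------------------------------------------

class ConstrainedKMedoids:
    """k-medoids with a minimum-cluster-size floor, sklearn estimator style.

    Clusters must each contain at least ``size_floor`` points (default
    ceil(n / (4 * n_clusters))).  Assignment is nearest-medoid followed by a
    repair step that moves the cheapest points out of surplus clusters until
    every floor is met; medoids are refined by within-cluster updates and then
    PAM-style swaps, each accepted only when the floored objective improves.

    Attributes after fit: ``labels_``, ``medoid_indices_``,
    ``cluster_centers_``, ``inertia_``, ``n_iter_``.
    """

    def __init__(self, n_clusters: int = 4, size_floor: int | None = None,
                 metric: str = "euclidean", max_iter: int = 100,
                 random_state: int | None = None):
        self.n_clusters = n_clusters
        self.size_floor = size_floor
        self.metric = metric
        self.max_iter = max_iter
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {"n_clusters": self.n_clusters, "size_floor": self.size_floor,
                "metric": self.metric, "max_iter": self.max_iter,
                "random_state": self.random_state}

    def set_params(self, **params) -> "ConstrainedKMedoids":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- internals ----------------------------------------------------------
    def _floor(self, n: int) -> int:
        if self.size_floor is not None:
            return int(self.size_floor)
        return int(np.ceil(n / (4 * self.n_clusters)))

    @staticmethod
    def _assign(D_med: np.ndarray, floor: int) -> np.ndarray:
        """Nearest-medoid assignment repaired to meet the size floor.

        Deficit clusters are filled by moving, one at a time, the point from a
        surplus cluster with the smallest distance increase (ties to lowest
        point index).
        """
        labels = np.argmin(D_med, axis=1)
        K = D_med.shape[1]
        sizes = np.bincount(labels, minlength=K)
        while True:
            deficits = np.where(sizes < floor)[0]
            if not len(deficits):
                return labels
            k = deficits[0]
            donors = np.where(sizes > floor)[0]
            donors = donors[donors != k]
            cand = np.flatnonzero(np.isin(labels, donors))
            if not len(cand):
                raise ValueError("size floor infeasible during repair")
            delta = D_med[cand, k] - D_med[cand, labels[cand]]
            j = cand[int(np.argmin(delta))]
            sizes[labels[j]] -= 1
            labels[j] = k
            sizes[k] += 1

    def _cost(self, D: np.ndarray, medoids: np.ndarray, floor: int):
        labels = self._assign(D[:, medoids], floor)
        cost = float(D[np.arange(len(labels)), medoids[labels]].sum())
        return cost, labels

    def fit(self, X, y=None) -> "ConstrainedKMedoids":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        n = len(X)
        K = self.n_clusters
        floor = self._floor(n)
        if n < K * floor:
            raise ValueError(f"{n} points cannot meet floor {floor} in {K} clusters")
        rng = np.random.default_rng(self.random_state)
        metric = "cityblock" if self.metric in ("l1", "cityblock", "manhattan") else "euclidean"
        D = cdist(X, X, metric=metric)

        medoids = np.sort(rng.choice(n, size=K, replace=False))
        cost, labels = self._cost(D, medoids, floor)
        self.objective_trace_ = [cost]
        n_iter = 0
        # Phase 1: alternating within-cluster medoid updates
        for n_iter in range(1, self.max_iter + 1):
            new_medoids = medoids.copy()
            for k in range(K):
                members = np.flatnonzero(labels == k)
                within = D[np.ix_(members, members)].sum(axis=0)
                new_medoids[k] = members[int(np.argmin(within))]
            new_cost, new_labels = self._cost(D, new_medoids, floor)
            if new_cost < cost - 1e-12:
                medoids, cost, labels = new_medoids, new_cost, new_labels
                self.objective_trace_.append(cost)
            else:
                break
        # Phase 2: PAM swap scan until no feasible improving swap remains
        improved = True
        while improved and n_iter < self.max_iter:
            improved = False
            n_iter += 1
            best = (cost, None)
            in_medoids = set(medoids.tolist())
            for k in range(K):
                for p in range(n):
                    if p in in_medoids:
                        continue
                    trial = medoids.copy()
                    trial[k] = p
                    c, _ = self._cost(D, trial, floor)
                    if c < best[0] - 1e-12:
                        best = (c, trial)
            if best[1] is not None:
                medoids = best[1]
                cost, labels = self._cost(D, medoids, floor)
                self.objective_trace_.append(cost)
                improved = True

        order = np.argsort(medoids)  # canonical cluster numbering by medoid index
        medoids = medoids[order]
        relabel = np.empty(K, dtype=int)
        relabel[order] = np.arange(K)
        self.labels_ = relabel[labels]
        self.medoid_indices_ = medoids
        self.cluster_centers_ = X[medoids]
        self.inertia_ = cost
        self.n_iter_ = n_iter
        self.size_floor_ = floor
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def kmedoids_min_size(psi: np.ndarray, K: int, seed=None, **kw) -> ConstrainedKMedoids:
    """Cluster daily crash vectors into K groups with floor ceil(n/(4K))."""
    return ConstrainedKMedoids(n_clusters=K, random_state=seed, **kw).fit(psi)


# --------------------------------------------------------------------------
# Date-type mapping and cluster summaries
# --------------------------------------------------------------------------

def map_date_types(labels: np.ndarray, days, calendar: pd.DataFrame, K: int):
    """Majority map o(.) from the 14 date types to clusters.

    calendar: DataFrame with columns date, is_holiday.  Returns (o, m) where
    m[k, j] counts type-j days in cluster k and o[j] = argmax_k m[k, j] (ties
    to lowest cluster index).  A type with zero observed days falls back to
    the non-holiday same-weekday mapping and is logged.
    """
    cal = dict(zip(calendar["date"], calendar["is_holiday"]))
    missing = [d for d in days if d not in cal]
    if missing:
        raise ValueError(f"calendar has no label for {missing[:3]} ...")
    m = np.zeros((K, N_DATE_TYPES), dtype=int)
    for lab, day in zip(labels, days):
        m[lab, date_type(day, cal[day])] += 1
    o = np.full(N_DATE_TYPES, -1, dtype=int)
    for j in range(N_DATE_TYPES):
        if m[:, j].sum() > 0:
            o[j] = int(np.argmax(m[:, j]))  # argmax ties -> lowest index
    for j in range(N_DATE_TYPES):
        if o[j] < 0:
            fallback = j % 7  # non-holiday same weekday
            if o[fallback] >= 0:
                log.warning("date type %r has no observed days; falling back to %r",
                            DATE_TYPE_LABELS[j], DATE_TYPE_LABELS[fallback])
                o[j] = o[fallback]
    for j in np.flatnonzero(o < 0):
        log.warning("date type %r is unmapped (no observed days, no fallback)",
                    DATE_TYPE_LABELS[j])
    return o, m


def cluster_summaries(crash_data: CrashData, days, labels: np.ndarray, K: int):
    """Cluster crash matrices C^k (per-day means) and departure pmfs eps_k.

    eps_k is the cluster's aggregate hourly crash histogram normalised to sum
    to 1 (the simulator samples drink-driver departure hours from it).
    """
    days = list(days)
    matrices, eps = {}, {}
    _, psi = crash_data.daily_vectors()
    day_index = {d: i for i, d in enumerate(crash_data.daily_vectors()[0])}
    for k in range(K):
        members = [d for d, lab in zip(days, labels) if lab == k]
        if not members:
            raise ValueError(f"cluster {k} is empty")
        matrices[k] = crash_data.mean_matrix(members)
        hist = psi[[day_index[d] for d in members]].sum(axis=0)
        total = hist.sum()
        if total == 0:
            raise ValueError(f"cluster {k} has no crashes")
        eps[k] = hist / total
    return matrices, eps


@dataclass
class DayClusterModel:
    """Fitted day-type clustering bundle used by the optimiser and simulator."""

    K: int
    days: list
    labels: np.ndarray
    medoid_days: list
    o: np.ndarray  # date type (0..13) -> cluster
    m: np.ndarray  # (K, 14) date-type counts
    matrices: dict = field(repr=False, default_factory=dict)  # k -> C^k
    eps: dict = field(repr=False, default_factory=dict)  # k -> 24-pmf

    @classmethod
    def fit(cls, crash_data: CrashData, calendar: pd.DataFrame, K: int = 4,
            seed=None, **kw) -> "DayClusterModel":
        days, psi = crash_data.daily_vectors()
        km = kmedoids_min_size(psi, K, seed=seed, **kw)
        o, m = map_date_types(km.labels_, days, calendar, K)
        matrices, eps = cluster_summaries(crash_data, days, km.labels_, K)
        return cls(K=K, days=days, labels=km.labels_,
                   medoid_days=[days[i] for i in km.medoid_indices_],
                   o=o, m=m, matrices=matrices, eps=eps)

    def cluster_for_date(self, date, is_holiday: bool) -> int:
        k = int(self.o[date_type(date, is_holiday)])
        if k < 0:
            raise ValueError(f"date type of {date} is unmapped (no observed days)")
        return k

    def row_percentages(self) -> np.ndarray:
        """m normalised within each date type (column shares, in percent)."""
        col = self.m.sum(axis=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(col > 0, 100.0 * self.m / col, 0.0)

    def to_json(self, path) -> None:
        payload = {
            "K": self.K,
            "days": [str(d) for d in self.days],
            "labels": self.labels.tolist(),
            "medoid_days": [str(d) for d in self.medoid_days],
            "o": self.o.tolist(),
            "m": self.m.tolist(),
            "eps": {str(k): v.tolist() for k, v in self.eps.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
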