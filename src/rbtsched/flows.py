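"""Traffic-flow matrices and inverse-distance imputation for unsensored links.

Only a small fraction of links carry flow sensors.  Flows on the rest are
imputed from the U nearest sensored links with weights

    w_i = 0.5 * (1 - d_i / sum_j d_j)

over the U nearest sensors.  With U = 3 the weights sum to exactly 1; the
formula is applied literally for other U (weight sum 0.5 for U = 2), with an
optional renormalisation switch that is off by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import RoadNetwork

log = logging.getLogger(__name__)

__all__ = ["SensorFlowSet", "eq_weights", "impute_flow", "build_flow_matrices",
           "WeekdayFlowProfile", "WEEKDAYS"]

WEEKDAYS = ("Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday", "Sunday")


@dataclass
class SensorFlowSet:
    """Measured flows on sensored links.

    flows : long DataFrame with columns link_id, date, interval (1..t_star),
        count.  Vehicle counts per 15-min interval (t_star = 96 default).
    """

    flows: pd.DataFrame
    t_star: int = 96

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.flows)
        required = {"link_id", "date", "interval", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"sensor flow table missing columns {sorted(missing)}")
        if (df["count"] < 0).any():
            raise ValueError("flow counts must be non-negative")
        if df["interval"].min() < 1 or df["interval"].max() > self.t_star:
            raise ValueError("interval index outside 1..t_star")
        self.flows = df

    @property
    def sensor_links(self) -> np.ndarray:
        return np.unique(self.flows["link_id"].to_numpy())

    @property
    def dates(self) -> list:
        return sorted(self.flows["date"].unique())

    def day_vectors(self, date) -> dict:
        """sensor link id -> length-t_star flow vector for one date.

        Sensors with no row on that date are dropped for the day (and the
        nearest-sensor sets recomputed by the caller); missing intervals of a
        present sensor count as zero flow.
        """
        sub = self.flows[self.flows["date"] == date]
        out = {}
        for lid, grp in sub.groupby("link_id"):
            vec = np.zeros(self.t_star)
            vec[grp["interval"].to_numpy() - 1] = grp["count"].to_numpy()
            out[lid] = vec
        return out


def eq_weights(distances: np.ndarray) -> np.ndarray:
    """Inverse-distance weights 0.5*(1 - d_i/sum d) over the nearest-U set.

    All-zero distances (every sensor coincident with the target) take the
    symmetric limit d_i/sum d = 1/U.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 1 or len(d) < 2:
        raise ValueError("need at least U = 2 nearest sensors")
    total = d.sum()
    ratios = np.full(len(d), 1.0 / len(d)) if total == 0.0 else d / total
    return 0.5 * (1.0 - ratios)


def _nearest_sensors(net: RoadNetwork, target_link, sensor_ids: np.ndarray, U: int):
    """ids and distances of the U sensored links nearest to target's midpoint.

    Ties broken by lowest sensor link id (sensor_ids must be sorted).
    """
    p = net.midpoint(target_link)
    rows = np.array([net.link_row(s) for s in sensor_ids])
    mids = net.midpoints[rows]
    d = net._dist(p.lat, p.lon, mids[:, 0], mids[:, 1])
    order = np.lexsort((sensor_ids, d))[:U]  # distance first, then id
    return sensor_ids[order], d[order]


def impute_flow(target_link, net: RoadNetwork, sensors: SensorFlowSet, date,
                U: int = 3, renormalise: bool = False) -> np.ndarray:
    """Imputed flow vector for one unsensored link on one date."""
    if U < 2:
        raise ValueError("U must be >= 2 (the weight is identically 0 at U = 1)")
    day = sensors.day_vectors(date)
    ids = np.array(sorted(day))
    if len(ids) < U:
        raise ValueError(f"only {len(ids)} sensors with data on {date}; need U={U}")
    near_ids, near_d = _nearest_sensors(net, target_link, ids, U)
    w = eq_weights(near_d)
    if renormalise:
        w = w / w.sum()
    return sum(wi * day[sid] for wi, sid in zip(w, near_ids))


@dataclass
class WeekdayFlowProfile:
    """Per-weekday mean flow matrices F̂(Monday)..F̂(Sunday).

    matrices maps weekday name -> (n_links, t_star) array in network link
    order.
    """

    matrices: dict = field(default_factory=dict)

    def for_date(self, date) -> np.ndarray:
        name = WEEKDAYS[pd.Timestamp(date).weekday()]
        return self.matrices[name]


def build_flow_matrices(net: RoadNetwork, sensors: SensorFlowSet, U: int = 3,
                        renormalise: bool = False):
    """Full per-day flow matrices plus the per-weekday mean profile.

    Returns (daily, profile): daily maps date -> (n_links, t_star) array with
    measured rows on sensored links and imputed rows elsewhere; profile is the
    element-wise per-weekday mean over the member dates.
    """
    if U < 2:
        raise ValueError("U must be >= 2")
    if len(sensors.sensor_links) < U:
        raise ValueError("fewer sensors than U")
    unknown = set(sensors.sensor_links) - set(net.link_ids)
    if unknown:
        raise ValueError(f"sensor links not in network: {sorted(unknown)[:5]}")

    daily: dict = {}
    nearest_cache: dict = {}
    for date in sensors.dates:
        day = sensors.day_vectors(date)
        ids = np.array(sorted(day))
        if len(ids) < U:
            log.warning("date %s has %d sensors (<U=%d); skipped", date, len(ids), U)
            continue
        key = tuple(ids)
        if key not in nearest_cache:
            nearest_cache[key] = {
                lid: _nearest_sensors(net, lid, ids, U)
                for lid in net.link_ids if lid not in day
            }
        F = np.zeros((net.n_links, sensors.t_star))
        for lid, vec in day.items():
            F[net.link_row(lid)] = vec
        for lid, (near_ids, near_d) in nearest_cache[key].items():
            w = eq_weights(near_d)
            if renormalise:
                w = w / w.sum()
            F[net.link_row(lid)] = sum(wi * day[s] for wi, s in zip(w, near_ids))
        daily[date] = F

    profile = WeekdayFlowProfile()
    by_wd: dict = {}
    for date, F in daily.items():
        by_wd.setdefault(WEEKDAYS[pd.Timestamp(date).weekday()], []).append(F)
    for name, mats in by_wd.items():
        profile.matrices[name] = np.mean(mats, axis=0)
    return daily, profile
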