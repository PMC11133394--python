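"""Seeded synthetic scenarios: networks, sensor flows, crash histories, calendars.

The generators emulate the statistical structure the scheduling method
assumes: weekday traffic peaking 08:00-17:00 with a weekend damping factor
and order-of-magnitude per-link flow differences; alcohol-related crashes
concentrated after 17:00 (and before 04:00) with a weekend/holiday excess at
about 1.24 crashes per day network-wide; and a calendar labelling every day
with one of the 14 holiday/non-holiday x weekday types.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crashes import CrashRecord
from .network import GeoPoint, RoadNetwork

__all__ = ["ScenarioSpec", "make_network", "make_flows", "make_calendar",
           "make_crash_history", "make_scenario", "make_daily_profile_vectors"]


@dataclass
class ScenarioSpec:
    """Defaults are the desk-scale study conditions."""

    network_kind: str = "grid"  # "grid" | "random-geometric"
    n_nodes: int = 100
    sensor_fraction: float = 0.2
    # flows: vehicles per 15-min interval at a typical (scale-1) link
    peak_level: float = 48.0
    offpeak_level: float = 8.0
    peak_window: tuple = (8, 17)  # hours, [start, end)
    weekend_factor: float = 0.7
    link_scale_sigma: float = 0.8  # lognormal spread of per-link flow scales
    arterial_fraction: float = 0.05  # share of sensored links that are arterials
    arterial_scale: float = 20.0  # urban-arterial flow multiple of a typical link
    n_flow_days: int = 28
    # crashes
    crash_rate_per_day: float = 1.24
    evening_weight: float = 0.55  # 17:00-24:00
    early_morning_weight: float = 0.25  # 00:00-04:00
    weekend_multiplier: float = 1.6
    # calendar
    start_date: str = "2015-07-01"
    n_days: int = 730
    holidays: tuple = ()  # ISO dates; default: Jan 1, Dec 25/26 of covered years
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensor_fraction <= 1.0):
            raise ValueError("sensor_fraction must be in [0, 1]")
        if self.crash_rate_per_day < 0:
            raise ValueError("crash rate must be >= 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.evening_weight + self.early_morning_weight > 1.0:
            raise ValueError("temporal crash weights exceed 1")


def _default_holidays(dates) -> set:
    out = set()
    for d in dates:
        ts = pd.Timestamp(d)
        if (ts.month, ts.day) in {(1, 1), (12, 25), (12, 26)}:
            out.add(ts.date())
    return out


def make_network(spec: ScenarioSpec) -> RoadNetwork:
    """Connected synthetic network; grid mode is fully deterministic."""
    rng = np.random.default_rng([spec.seed, 1])
    n = spec.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if spec.network_kind == "grid":
        side = int(np.ceil(np.sqrt(n)))
        lat0, lon0, step = -37.0, 145.0, 0.02
        nodes, rows, nid = {}, [], {}
        count = 0
        for r in range(side):
            for c in range(side):
                if count >= n:
                    break
                nid[(r, c)] = count
                nodes[count] = (lat0 + r * step, lon0 + c * step)
                count += 1
        lid = 0
        for (r, c), u in nid.items():
            for dr, dc in ((0, 1), (1, 0)):
                if (r + dr, c + dc) in nid:
                    v = nid[(r + dr, c + dc)]
                    length = float(rng.uniform(1.5, 3.0))
                    speed = float(rng.choice([50.0, 60.0, 80.0, 100.0]))
                    rows.append({"id": lid, "u": u, "v": v,
                                 "length_km": length, "speed_kmh": speed})
                    lid += 1
        return RoadNetwork(nodes, pd.DataFrame(rows))
    if spec.network_kind == "random-geometric":
        for attempt in range(20):
            sub = np.random.default_rng([spec.seed, 1, attempt])
            lat = -37.0 + sub.uniform(0, 0.2, n)
            lon = 145.0 + sub.uniform(0, 0.2, n)
            nodes = {i: (float(lat[i]), float(lon[i])) for i in range(n)}
            rows = []
            lid = 0
            # connect each node to its 3 nearest neighbours
            from scipy.spatial import cKDTree
            tree = cKDTree(np.column_stack([lat, lon]))
            _, nbrs = tree.query(np.column_stack([lat, lon]), k=4)
            seen = set()
            for i in range(n):
                for j in nbrs[i][1:]:
                    e = (min(i, j), max(i, j))
                    if e in seen:
                        continue
                    seen.add(e)
                    from .network import haversine_km
                    length = max(float(haversine_km(lat[i], lon[i], lat[j], lon[j])), 0.1)
                    rows.append({"id": lid, "u": e[0], "v": e[1], "length_km": length,
                                 "speed_kmh": float(sub.choice([50.0, 60.0, 80.0, 100.0]))})
                    lid += 1
            net = RoadNetwork(nodes, pd.DataFrame(rows))
            import networkx as nx
            g = nx.Graph((r["u"], r["v"]) for r in rows)
            if nx.is_connected(g):
                return net
        raise RuntimeError("could not draw a connected random-geometric network")
    raise ValueError(f"unknown network kind {spec.network_kind!r}")


def _diurnal_curve(spec: ScenarioSpec, weekend: bool, t_star: int = 96) -> np.ndarray:
    hours = (np.arange(t_star) * (1440 // t_star)) // 60
    lo, hi = spec.peak_window
    curve = np.where((hours >= lo) & (hours < hi), spec.peak_level, spec.offpeak_level)
    return curve * (spec.weekend_factor if weekend else 1.0)


def make_flows(net: RoadNetwork, spec: ScenarioSpec, rng=None, t_star: int = 96):
    """Poisson sensor counts around the diurnal curve; returns a long DataFrame.

    Columns: link_id, date, interval (1..t*), count.  Sensors are a seeded
    random subset of links; each link carries a lognormal scale factor so
    flows span realistic orders of magnitude.
    """
    if spec.sensor_fraction <= 0:
        raise ValueError("sensor_fraction must be > 0")
    if rng is None:
        rng = np.random.default_rng([spec.seed, 2])
    n_sensors = max(2, int(round(spec.sensor_fraction * net.n_links)))
    sensors = np.sort(rng.choice(net.link_ids, size=n_sensors, replace=False))
    # a small arterial class carries flows an order of magnitude above the
    # typical link, mirroring the urban/rural contrast of real road networks
    scales = {lid: float(rng.lognormal(0.0, spec.link_scale_sigma)
                         * (spec.arterial_scale
                            if rng.random() < spec.arterial_fraction else 1.0))
              for lid in sensors}
    dates = pd.date_range(spec.start_date, periods=spec.n_flow_days, freq="D").date
    frames = []
    for date in dates:
        weekend = pd.Timestamp(date).weekday() >= 5
        curve = _diurnal_curve(spec, weekend, t_star)
        for lid in sensors:
            counts = rng.poisson(curve * scales[lid])
            frames.append(pd.DataFrame({
                "link_id": lid, "date": date,
                "interval": np.arange(1, t_star + 1), "count": counts}))
    return pd.concat(frames, ignore_index=True)


def make_calendar(spec: ScenarioSpec, extra_days: int = 0) -> pd.DataFrame:
    """date / is_holiday labels covering the history plus extra_days."""
    dates = pd.date_range(spec.start_date, periods=spec.n_days + extra_days, freq="D").date
    holidays = set(pd.Timestamp(h).date() for h in spec.holidays) or _default_holidays(dates)
    return pd.DataFrame({"date": dates,
                         "is_holiday": [int(d in holidays) for d in dates]})


def _crash_time_pmf(spec: ScenarioSpec, weekend: bool) -> np.ndarray:
    """Hourly pmf: mass on 17-24h and 0-4h, the remainder uniform on 4-17h."""
    w_eve, w_am = spec.evening_weight, spec.early_morning_weight
    if weekend:  # weekend nights shift extra mass into the early morning
        w_am = min(w_am * 1.5, 1.0 - w_eve)
    pmf = np.zeros(24)
    pmf[17:24] = w_eve / 7.0
    pmf[0:4] = w_am / 4.0
    pmf[4:17] = (1.0 - w_eve - w_am) / 13.0
    return pmf / pmf.sum()


def make_crash_history(net: RoadNetwork, spec: ScenarioSpec, rng=None):
    """(records, calendar): night-heavy crash history with weekend excess."""
    if rng is None:
        rng = np.random.default_rng([spec.seed, 3])
    calendar = make_calendar(spec)
    is_holiday = dict(zip(calendar["date"], calendar["is_holiday"]))
    records = []
    for date in calendar["date"]:
        weekend = pd.Timestamp(date).weekday() >= 5
        boosted = weekend or is_holiday[date]
        rate = spec.crash_rate_per_day * (spec.weekend_multiplier if boosted else 1.0)
        n = rng.poisson(rate)
        if not n:
            continue
        pmf = _crash_time_pmf(spec, weekend)
        hours = rng.choice(24, size=n, p=pmf)
        times = hours * 60 + rng.uniform(0, 60, size=n)
        link_rows = rng.integers(0, net.n_links, size=n)
        along = rng.uniform(0, 1, size=n)
        for t, r, a in zip(times, link_rows, along):
            u, v = net._end_a[r], net._end_b[r]
            records.append(CrashRecord(
                date=date, time_min=float(t),
                location=GeoPoint(float(u[0] + a * (v[0] - u[0])),
                                  float(u[1] + a * (v[1] - u[1])))))
    return records, calendar


def make_daily_profile_vectors(n_days: int = 1189, n_profiles: int = 4,
                               crashes_per_day: float = 1.9, seed: int = 0,
                               separation: float = 1.0):
    """(psi, labels): daily 24-bin crash vectors from a profile mixture.

    Each day draws a profile (cluster label), a Poisson total around
    crashes_per_day scaled by the profile's activity level, and hour bins
    from the profile's pmf.  ``separation`` scales how distinct the profiles
    are (1 = the default well-separated night/evening/morning/day mixture).
    """
    rng = np.random.default_rng(seed)
    base = np.full(24, 1.0 / 24)
    peaks = [(21, 3.0), (18, 2.0), (1, 2.5), (12, 2.0)]  # (centre hour, width)
    profiles = []
    for centre, width in peaks[:n_profiles]:
        h = np.arange(24)
        d = np.minimum(np.abs(h - centre), 24 - np.abs(h - centre))
        bump = np.exp(-0.5 * (d / width) ** 2)
        pmf = base + separation * bump / bump.sum()
        profiles.append(pmf / pmf.sum())
    labels = rng.integers(0, n_profiles, size=n_days)
    rates = 1.0 + 0.3 * np.arange(n_profiles)  # mild per-profile activity spread
    psi = np.zeros((n_days, 24))
    for i, lab in enumerate(labels):
        n = 0
        while n == 0:  # clustered days have at least one crash by construction
            n = rng.poisson(crashes_per_day * rates[lab] / rates.mean())
        hours = rng.choice(24, size=n, p=profiles[lab])
        np.add.at(psi[i], hours, 1.0)
    return psi, labels


def make_scenario(spec: ScenarioSpec, out_dir=None):
    """Full bundle: network + flows + crashes + calendar (+ files if out_dir).

    Returns a dict with keys net, flows, records, calendar, spec.  When
    out_dir is given, writes nodes.csv, edges.csv, flows.csv, crashes.csv,
    calendar.csv and spec.json.
    """
    net = make_network(spec)
    flow_df = make_flows(net, spec)
    records, calendar = make_crash_history(net, spec)
    bundle = {"net": net, "flows": flow_df, "records": records,
              "calendar": calendar, "spec": spec}
    if out_dir is not None:
        from . import io as _io
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_network_csv(net, out / "nodes.csv", out / "edges.csv")
        flow_df.to_csv(out / "flows.csv", index=False)
        _io.write_crashes_csv(records, out / "crashes.csv")
        calendar.to_csv(out / "calendar.csv", index=False)
        with open(out / "spec.json", "w") as fh:
            payload = dataclasses.asdict(spec)
            payload["peak_window"] = list(spec.peak_window)
            payload["holidays"] = list(spec.holidays)
            json.dump(payload, fh, indent=1)
    return bundle
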