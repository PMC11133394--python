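"""Monte-Carlo drink-driver trips and first-capture schedule evaluation.

Offenders drive from random origins to random destinations along shortest
travel-time paths at a fixed speed, departing at times drawn from the crash
cluster's hourly distribution.  A driver meets a test site when the instant
they pass the midpoint of the site's link falls inside an active interval;
each encounter is an independent Bernoulli draw with the capacity-model
probability, and the first success removes the driver (first-capture
stopping).  Sober traffic enters through the flow matrix as the expected
test and pass-by counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crashes import CrashRecord
from .fitness import CapacityModel, test_probability
from .network import GeoPoint, NoPathError, PathTrace, RoadNetwork
from .schedule import SiteSchedule, sites_to_matrix

__all__ = ["DrinkDriverTrip", "SimulationResult", "generate_trips",
           "simulate_day", "synthesize_crashes", "evaluate_report",
           "km_per_day", "trips_per_day", "crashes_per_day"]


# ---- headline scale arithmetic (vehicle-kilometres, trips, crash rate) ------

def km_per_day(yearly_km: float, days_per_year: int = 365) -> float:
    """Network-wide vehicle-km travelled per day from the yearly total."""
    return yearly_km / days_per_year


def trips_per_day(daily_km: float, mean_trip_km: float) -> float:
    """Daily trip count implied by daily vehicle-km and mean trip length."""
    return daily_km / mean_trip_km


def crashes_per_day(total_crashes: int, years: float, days_per_year: int = 365) -> float:
    """Average daily alcohol-related crash count over a multi-year history."""
    return total_crashes / (years * days_per_year)


# ------------------------------------------------------------------ trips

@dataclass
class DrinkDriverTrip:
    driver_id: int
    origin: object
    destination: object
    tau1: float  # departure, minutes since 00:00
    speed_kmh: float
    trace: PathTrace
    length_km: float


def sample_departure(eps: np.ndarray, rng) -> float:
    """Departure minute: hour from the 24-bin pmf, minute uniform within it."""
    eps = np.asarray(eps, dtype=float)
    if abs(eps.sum() - 1.0) > 1e-9 or len(eps) != 24:
        raise ValueError("eps must be a 24-bin pmf summing to 1")
    hour = rng.choice(24, p=eps)
    return float(hour * 60 + rng.uniform(0.0, 60.0))


def generate_trips(net: RoadNetwork, n_drivers: int, eps: np.ndarray,
                   speed_kmh: float, rng, max_od_retries: int = 50):
    """Random-O/D drink-driver trips with cluster-distributed departures."""
    if n_drivers < 0:
        raise ValueError("n_drivers must be >= 0")
    nodes = sorted(net.nodes)
    if len(nodes) < 2:
        raise ValueError("need at least two nodes to generate trips")
    trips = []
    for u in range(n_drivers):
        links = None
        for _ in range(max_od_retries):
            o, d = (nodes[i] for i in rng.choice(len(nodes), size=2, replace=False))
            try:
                links = net.shortest_time_path(o, d)
                break
            except NoPathError:
                continue
        if links is None:
            raise NoPathError("could not find a connected origin/destination pair")
        tau1 = sample_departure(eps, rng)
        trace = net.traversal_intervals(links, tau1, speed_kmh=speed_kmh)
        trips.append(DrinkDriverTrip(driver_id=u, origin=o, destination=d,
                                     tau1=tau1, speed_kmh=speed_kmh, trace=trace,
                                     length_km=net.path_length_km(links)))
    return trips


# ------------------------------------------------------------------ simulation

@dataclass
class SimulationResult:
    n_offenders: int
    positives: int
    tests_total: float   # expected sober tests plus captured offenders
    observers: float     # expected untested pass-bys (sober traffic)
    pct_trip_traveled: float | None  # mean over captured offenders; None if none
    drivers: pd.DataFrame  # per-driver: captured, capture_link, capture_time, pct


def simulate_day(trips, schedule: SiteSchedule, F: np.ndarray, net: RoadNetwork,
                 cap: CapacityModel, rng, include_uncaptured: bool = False) -> SimulationResult:
    """First-capture evaluation of one day's schedule against a trip set.

    include_uncaptured: count uncaptured offenders at 100% in the
    percentage-of-trip-traveled average (off by default: the average is over
    captured offenders only).
    """
    S = sites_to_matrix(schedule, net.link_ids)
    if F.shape != S.shape:
        raise ValueError("flow matrix shape does not match network/t*")
    p = test_probability(F, cap)
    t_star = schedule.t_star
    dt = 1440.0 / t_star

    rows = []
    positives = 0
    pcts = []
    for trip in trips:
        captured = False
        cap_link = cap_time = None
        pct = None
        dist_before = 0.0
        for link, entry in zip(trip.trace.links, trip.trace.entry):
            length = net.link_length(link)
            mid_instant = entry + (length / 2.0) / trip.speed_kmh * 60.0
            clock = mid_instant % 1440.0  # trips crossing midnight wrap onto the day
            t = int(clock // dt)  # 0-based interval index
            r = net.link_row(link)
            if S[r, t] and rng.random() < p[r, t]:
                captured = True
                cap_link, cap_time = link, mid_instant
                pct = 100.0 * (dist_before + length / 2.0) / trip.length_km
                break
            dist_before += length
        if captured:
            positives += 1
            pcts.append(pct)
        elif include_uncaptured:
            pcts.append(100.0)
        rows.append({"driver_id": trip.driver_id, "captured": captured,
                     "capture_link": cap_link, "capture_time": cap_time, "pct": pct})

    Q_sober = float((S * F * p).sum())
    R_sober = float((S * F).sum() - Q_sober)
    return SimulationResult(
        n_offenders=len(trips), positives=positives,
        tests_total=Q_sober + positives, observers=R_sober,
        pct_trip_traveled=float(np.mean(pcts)) if pcts else None,
        drivers=pd.DataFrame(rows, columns=["driver_id", "captured",
                                            "capture_link", "capture_time", "pct"]))


def synthesize_crashes(net: RoadNetwork, trips, daily_rate: float, rng, date=None):
    """Poisson(daily_rate) crashes placed uniformly along random trip traces."""
    if daily_rate < 0:
        raise ValueError("daily_rate must be >= 0")
    n = int(rng.poisson(daily_rate)) if trips else 0
    crashes = []
    for _ in range(n):
        trip = trips[int(rng.integers(len(trips)))]
        target = rng.uniform(0.0, 1.0) * trip.length_km
        run = 0.0
        for i, link in enumerate(trip.trace.links):
            length = net.link_length(link)
            last = i == len(trip.trace.links) - 1
            if run + length >= target or last:
                along = 0.0 if length == 0 else min(max((target - run) / length, 0.0), 1.0)
                t = trip.trace.entry[i] + along * (trip.trace.exit[i] - trip.trace.entry[i])
                row = net.link_row(link)
                u, v = net._end_a[row], net._end_b[row]
                lat = u[0] + along * (v[0] - u[0])
                lon = u[1] + along * (v[1] - u[1])
                crashes.append(CrashRecord(date=date, time_min=float(t % 1440.0),
                                           location=GeoPoint(float(lat), float(lon))))
                break
            run += length
    return crashes


# ------------------------------------------------------------------ reporting

def evaluate_report(schedules: dict, days, net: RoadNetwork, flow_for_date,
                    eps_for_date, cap: CapacityModel, n_drivers: int,
                    speed_kmh: float, n_reps: int, seed: int,
                    baseline: str = "RBT-det") -> pd.DataFrame:
    """Compare scheduling methods over days, averaged over n_reps seeds.

    schedules: method name -> {date -> SiteSchedule} (or a callable
    (date, rep_rng) -> SiteSchedule for per-rep random schedules).
    flow_for_date / eps_for_date: callables giving the day's flow matrix and
    departure pmf.  Returns one row per (method, day) plus per-method "Average"
    rows; improvement columns are percent changes versus the baseline method
    (omitted if the baseline is missing).
    """
    rows = []
    for method, sched in schedules.items():
        for day in days:
            metrics = {"positives": [], "tests": [], "observers": [], "pct": []}
            for rep in range(n_reps):
                rng = np.random.default_rng([seed, rep, abs(hash(str(day))) % 2**31])
                trips = generate_trips(net, n_drivers, eps_for_date(day), speed_kmh, rng)
                s = sched(day, rng) if callable(sched) else sched[day]
                res = simulate_day(trips, s, flow_for_date(day), net, cap, rng)
                metrics["positives"].append(res.positives)
                metrics["tests"].append(res.tests_total)
                metrics["observers"].append(res.observers)
                if res.pct_trip_traveled is not None:
                    metrics["pct"].append(res.pct_trip_traveled)
            rows.append({"method": method, "day": str(day),
                         "positives": float(np.mean(metrics["positives"])),
                         "tests": float(np.mean(metrics["tests"])),
                         "observers": float(np.mean(metrics["observers"])),
                         "pct_trip_traveled": float(np.mean(metrics["pct"]))
                         if metrics["pct"] else None})
    df = pd.DataFrame(rows)
    avg = df.groupby("method", as_index=False)[["positives", "tests", "observers",
                                                "pct_trip_traveled"]].mean()
    avg.insert(1, "day", "Average")
    df = pd.concat([df, avg], ignore_index=True)
    if baseline in schedules:
        base = df[(df["method"] == baseline)].set_index("day")
        for col in ("positives", "tests", "observers"):
            df[f"{col}_improvement_pct"] = [
                100.0 * (r[col] - base.loc[r["day"], col]) / base.loc[r["day"], col]
                if base.loc[r["day"], col] else np.nan
                for _, r in df.iterrows()]
    return df
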