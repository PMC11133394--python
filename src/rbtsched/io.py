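"""Readers and writers for scenario bundles, schedules and reports.

All interval indices are serialised 1-based; schedule JSON records sites as
{link, start_interval, end_interval} with the site active during intervals
start_interval+1 .. end_interval.  Malformed rows are reported with their
line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .crashes import CrashRecord
from .network import GeoPoint, RoadNetwork
from .schedule import SiteSchedule, TestSite

__all__ = ["read_network", "write_network_csv", "read_crashes_csv",
           "write_crashes_csv", "read_calendar_csv", "read_flows_csv",
           "write_flow_matrix_csv", "read_schedule_json", "write_schedule_json",
           "write_schedule_bed"]


def read_network(nodes_path=None, edges_path=None, geojson_path=None, **kw) -> RoadNetwork:
    if geojson_path is not None:
        return RoadNetwork.from_geojson(geojson_path, **kw)
    return RoadNetwork.from_csv(nodes_path, edges_path, **kw)


def write_network_csv(net: RoadNetwork, nodes_path, edges_path) -> None:
    pd.DataFrame([{"id": k, "lat": p.lat, "lon": p.lon}
                  for k, p in sorted(net.nodes.items())]).to_csv(nodes_path, index=False)
    out = net.links.rename(columns={"u": "from", "v": "to"})
    out.to_csv(edges_path, index=False)


def read_crashes_csv(path):
    """Crash CSV: date (ISO-8601), time (HH:MM), lat, lon."""
    df = pd.read_csv(path, float_precision="round_trip")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            date = pd.Timestamp(row.date).date()
            hh, mm = str(row.time).split(":")
            t = int(hh) * 60 + float(mm)
            if not (0 <= t < 1440):
                raise ValueError("time outside the day")
            records.append(CrashRecord(date=date, time_min=t,
                                       location=GeoPoint(float(row.lat), float(row.lon))))
        except Exception as exc:
            raise ValueError(f"{path}: bad crash row at line {i}: {exc}") from exc
    return records


def write_crashes_csv(records, path) -> None:
    rows = [{"date": r.date, "time": f"{int(r.time_min) // 60:02d}:{int(r.time_min) % 60:02d}",
             "lat": r.location.lat, "lon": r.location.lon} for r in records]
    pd.DataFrame(rows, columns=["date", "time", "lat", "lon"]).to_csv(path, index=False)


def read_calendar_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"date", "is_holiday"} <= set(df.columns):
        raise ValueError("calendar CSV needs columns date, is_holiday")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df["is_holiday"] = df["is_holiday"].astype(int)
    return df


def read_flows_csv(path) -> pd.DataFrame:
    """Sensor flow CSV with columns link_id, date, interval, count."""
    df = pd.read_csv(path)
    required = {"link_id", "date", "interval", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"flow CSV missing columns {sorted(missing)}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for i, (_, row) in enumerate(df.iterrows(), start=2):
        if row["count"] < 0:
            raise ValueError(f"{path}: negative count at line {i}")
    return df


def write_flow_matrix_csv(F, link_ids, path) -> None:
    """Wide flow matrix: link_id, t1..t{t_star}."""
    t_star = F.shape[1]
    df = pd.DataFrame(F, columns=[f"t{t}" for t in range(1, t_star + 1)])
    df.insert(0, "link_id", list(link_ids))
    df.to_csv(path, index=False)


def write_schedule_json(schedule: SiteSchedule, path) -> None:
    payload = {"day": str(schedule.day) if schedule.day is not None else None,
               "t_star": schedule.t_star,
               "sites": [{"link": int(s.link), "start_interval": int(s.start),
                          "end_interval": int(s.finish)} for s in schedule.sites]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_schedule_json(path) -> SiteSchedule:
    with open(path) as fh:
        payload = json.load(fh)
    sites = [TestSite(s["start_interval"], s["end_interval"], s["link"])
             for s in payload["sites"]]
    return SiteSchedule.from_sites(sites, t_star=payload.get("t_star", 96),
                                   day=payload.get("day"))


def write_schedule_bed(schedule: SiteSchedule, path) -> None:
    """BED-like TSV (link, start_min, end_min) for quick inspection."""
    dt = 1440 // schedule.t_star
    rows = [{"link": s.link, "start_min": s.start * dt, "end_min": s.finish * dt}
            for s in schedule.sites]
    pd.DataFrame(rows, columns=["link", "start_min", "end_min"]).to_csv(
        path, sep="\t", index=False, header=False)
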