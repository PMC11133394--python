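"""Road-network representation, point-to-link projection and travel-time routing.

The network is an undirected graph of road segments ("links"), each with a
length in km and a speed limit in km/h.  Test sites sit at link midpoints, so
point events (crashes, sensors) are projected to the link whose midpoint is
nearest.  Routing minimises total travel time sum(l/v) with a deterministic
tie-break (lexicographically smallest link-id sequence) so that every run of
the simulator is reproducible.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "GeoPoint",
    "RoadNetwork",
    "PathTrace",
    "NoPathError",
    "haversine_km",
    "project_point_to_link",
    "shortest_time_path",
    "traversal_intervals",
]


class NoPathError(Exception):
    """Destination unreachable from origin."""


@dataclass(frozen=True)
class GeoPoint:
    """A (latitude, longitude) position in degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; accepts scalars or numpy arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _euclidean_deg(lat1, lon1, lat2, lon2):
    """Literal Euclidean norm on raw (lat, lon) pairs, for abstract planar nets."""
    return np.hypot(np.asarray(lat2, float) - lat1, np.asarray(lon2, float) - lon1)


@dataclass
class PathTrace:
    """A routed trip: ordered link ids with per-link entry/exit clock times.

    Times are minutes since 00:00 of the departure day and are *not* wrapped;
    use ``minute_of_day`` to map an instant onto the 24-h schedule clock.
    """

    links: tuple[int, ...]
    entry: np.ndarray  # minutes, entry[0] == tau1
    exit: np.ndarray
    tau1: float
    degenerate: bool = False  # zero total length

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        self.exit = np.asarray(self.exit, dtype=float)
        if len(self.links) != len(self.entry) or len(self.links) != len(self.exit):
            raise ValueError("links/entry/exit length mismatch")
        if len(self.entry):
            if not math.isclose(self.entry[0], self.tau1):
                raise ValueError("entry[0] must equal tau1")
            if np.any(self.exit <= self.entry):
                raise ValueError("entry/exit must be strictly increasing")
            if np.any(np.abs(self.entry[1:] - self.exit[:-1]) > 1e-9):
                raise ValueError("exit(v) must equal entry(v+1)")

    @property
    def total_time_min(self) -> float:
        return float(self.exit[-1] - self.tau1) if len(self.links) else 0.0


class RoadNetwork:
    """Undirected road network with km lengths and km/h speeds per link.

    Parameters
    ----------
    nodes : mapping node_id -> (lat, lon)
    links : DataFrame with columns id, u, v, length_km, speed_kmh
    metric : "haversine" (default) or "euclidean" for abstract planar networks
        where coordinates are not geographic.
    projection : "midpoint" (distance to link midpoint, default) or "segment"
        (true point-to-segment distance in a local planar frame).
    """

    def __init__(self, nodes, links: pd.DataFrame, metric: str = "haversine",
                 projection: str = "midpoint"):
        if metric not in ("haversine", "euclidean"):
            raise ValueError(f"unknown metric {metric!r}")
        if projection not in ("midpoint", "segment"):
            raise ValueError(f"unknown projection {projection!r}")
        self.metric = metric
        self.projection = projection
        self.nodes = {k: GeoPoint(float(la), float(lo)) for k, (la, lo) in dict(nodes).items()}

        links = pd.DataFrame(links).copy()
        required = {"id", "u", "v", "length_km", "speed_kmh"}
        missing = required - set(links.columns)
        if missing:
            raise ValueError(f"links table missing columns {sorted(missing)}")
        if links["id"].duplicated().any():
            raise ValueError("duplicate link ids")
        if (links["length_km"] <= 0).any():
            raise ValueError("link lengths must be > 0")
        if (links["speed_kmh"] <= 0).any():
            raise ValueError("link speeds must be > 0")
        for col in ("u", "v"):
            bad = set(links[col]) - set(self.nodes)
            if bad:
                raise ValueError(f"link endpoint(s) {sorted(bad)[:5]} not in node set")
        self.links = links.sort_values("id").reset_index(drop=True)

        self.link_ids = self.links["id"].to_numpy()
        self._link_row = {lid: r for r, lid in enumerate(self.link_ids)}
        lat_u = np.array([self.nodes[u].lat for u in self.links["u"]])
        lon_u = np.array([self.nodes[u].lon for u in self.links["u"]])
        lat_v = np.array([self.nodes[v].lat for v in self.links["v"]])
        lon_v = np.array([self.nodes[v].lon for v in self.links["v"]])
        self._end_a = np.column_stack([lat_u, lon_u])
        self._end_b = np.column_stack([lat_v, lon_v])
        self._midpoints = (self._end_a + self._end_b) / 2.0

        # adjacency: node -> sorted list of (link_id, other_node, time_min)
        self._adj: dict = {n: [] for n in self.nodes}
        for row in self.links.itertuples(index=False):
            t = 60.0 * row.length_km / row.speed_kmh
            self._adj[row.u].append((row.id, row.v, t))
            self._adj[row.v].append((row.id, row.u, t))
        for n in self._adj:
            self._adj[n].sort()
        self._sssp_cache: dict = {}

    # ------------------------------------------------------------------ basics
    @property
    def n_links(self) -> int:
        return len(self.link_ids)

    def link_row(self, link_id) -> int:
        return self._link_row[link_id]

    def link_length(self, link_id) -> float:
        return float(self.links["length_km"].iloc[self._link_row[link_id]])

    def link_speed(self, link_id) -> float:
        return float(self.links["speed_kmh"].iloc[self._link_row[link_id]])

    def midpoint(self, link_id) -> GeoPoint:
        lat, lon = self._midpoints[self._link_row[link_id]]
        return GeoPoint(lat, lon)

    @property
    def midpoints(self) -> np.ndarray:
        """(n_links, 2) array of link midpoint (lat, lon)."""
        return self._midpoints

    def _dist(self, lat1, lon1, lat2, lon2):
        if self.metric == "haversine":
            return haversine_km(lat1, lon1, lat2, lon2)
        return _euclidean_deg(lat1, lon1, lat2, lon2)

    def point_to_link_distances(self, p: GeoPoint) -> np.ndarray:
        """Distance from p to every link (midpoint or true segment distance)."""
        if self.projection == "midpoint":
            return self._dist(p.lat, p.lon, self._midpoints[:, 0], self._midpoints[:, 1])
        # segment mode: local equirectangular frame centred on p
        coslat = math.cos(math.radians(p.lat))
        to_xy = lambda ll: np.column_stack([(ll[:, 1] - p.lon) * coslat, ll[:, 0] - p.lat])
        a, b = to_xy(self._end_a), to_xy(self._end_b)
        ab = b - a
        denom = np.maximum((ab ** 2).sum(axis=1), 1e-300)
        t = np.clip(-(a * ab).sum(axis=1) / denom, 0.0, 1.0)
        closest = a + t[:, None] * ab
        deg = np.hypot(closest[:, 0], closest[:, 1])
        if self.metric == "haversine":
            return deg * math.pi / 180.0 * EARTH_RADIUS_KM
        return deg

    def project_point(self, p: GeoPoint):
        """Nearest link to p; ties broken by lowest link id."""
        if self.n_links == 0:
            raise ValueError("cannot project onto an empty network")
        d = self.point_to_link_distances(p)
        # link_ids are sorted ascending, so the first argmin is the lowest id
        return self.link_ids[int(np.argmin(d))]

    # ----------------------------------------------------------------- routing
    def _single_source(self, origin):
        """Dijkstra labelled by (time, link-id path) for deterministic ties."""
        if origin not in self.nodes:
            raise KeyError(f"unknown node {origin!r}")
        cached = self._sssp_cache.get(origin)
        if cached is not None:
            return cached
        best: dict = {origin: (0.0, ())}
        heap = [(0.0, (), origin)]
        while heap:
            t, path, node = heapq.heappop(heap)
            cur = best.get(node)
            if cur is not None and (t, path) > cur:
                continue
            for link_id, other, dt in self._adj[node]:
                cand = (t + dt, path + (link_id,))
                prev = best.get(other)
                if prev is None or cand < prev:
                    best[other] = cand
                    heapq.heappush(heap, (cand[0], cand[1], other))
        self._sssp_cache[origin] = best
        return best

    def shortest_time_path(self, origin, dest) -> tuple[int, ...]:
        """Link-id sequence minimising total l/v; raises NoPathError if none."""
        if origin == dest:
            raise ValueError("origin and destination must differ")
        best = self._single_source(origin)
        if dest not in best:
            raise NoPathError(f"no path from {origin!r} to {dest!r}")
        return best[dest][1]

    def path_length_km(self, links) -> float:
        return float(sum(self.link_length(l) for l in links))

    def traversal_intervals(self, links, tau1: float, speed_kmh: float | None = None) -> PathTrace:
        """Per-link entry/exit clock times for a trip departing at tau1 minutes.

        speed_kmh overrides the per-link speed limits with a single constant
        travel speed (the simulator's fixed-speed assumption); None uses the
        link speeds.
        """
        if not (0.0 <= tau1 < 1440.0):
            raise ValueError("tau1 must be in [0, 1440)")
        links = tuple(links)
        lengths = np.array([self.link_length(l) for l in links])
        if lengths.sum() == 0.0 or not links:
            return PathTrace(links=(), entry=np.array([]), exit=np.array([]),
                             tau1=tau1, degenerate=True)
        if speed_kmh is not None:
            speeds = np.full(len(links), float(speed_kmh))
        else:
            speeds = np.array([self.link_speed(l) for l in links])
        dur = 60.0 * lengths / speeds  # minutes
        bounds = tau1 + np.concatenate([[0.0], np.cumsum(dur)])
        return PathTrace(links=links, entry=bounds[:-1], exit=bounds[1:], tau1=tau1)

    # ---------------------------------------------------------------------- IO
    @classmethod
    def from_csv(cls, nodes_path, edges_path, **kw) -> "RoadNetwork":
        nd = pd.read_csv(nodes_path, float_precision="round_trip")
        ed = pd.read_csv(edges_path, float_precision="round_trip")
        nodes = {r.id: (r.lat, r.lon) for r in nd.itertuples(index=False)}
        ed = ed.rename(columns={"from": "u", "to": "v"})
        return cls(nodes, ed, **kw)

    @classmethod
    def from_geojson(cls, path, **kw) -> "RoadNetwork":
        """Read a FeatureCollection of LineString links.

        Each feature needs properties id, from, to, length_km, speed_kmh; node
        coordinates are taken from the line endpoints ([lon, lat] order).
        """
        with open(path) as fh:
            gj = json.load(fh)
        nodes, rows = {}, []
        for feat in gj["features"]:
            if feat.get("geometry", {}).get("type") != "LineString":
                continue
            props = feat["properties"]
            coords = feat["geometry"]["coordinates"]
            u, v = props["from"], props["to"]
            nodes.setdefault(u, (coords[0][1], coords[0][0]))
            nodes.setdefault(v, (coords[-1][1], coords[-1][0]))
            rows.append({"id": props["id"], "u": u, "v": v,
                         "length_km": props["length_km"], "speed_kmh": props["speed_kmh"]})
        return cls(nodes, pd.DataFrame(rows), **kw)


# Thin functional wrappers matching the operational surface -------------------

def project_point_to_link(p: GeoPoint, net: RoadNetwork):
    return net.project_point(p)


def shortest_time_path(net: RoadNetwork, origin, dest) -> tuple[int, ...]:
    return net.shortest_time_path(origin, dest)


def traversal_intervals(links, tau1: float, net: RoadNetwork,
                        speed_kmh: float | None = None) -> PathTrace:
    return net.traversal_intervals(links, tau1, speed_kmh=speed_kmh)
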