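"""Test-schedule representations and the resource-constraint validator.

A day's schedule is either a list of test sites g_w = {start, finish, link}
or the equivalent binary link x interval matrix S.  Interval convention:
intervals are 1..t* with clock semantics [(t-1)*dt, t*dt); a site {start,
finish} is active during intervals start+1 .. finish, so its duration is
(finish - start) intervals.  ``start`` may be 0, meaning the site is active
from the first interval of the day.

Resource constraints: at most N_max sites per day, each site's duration in
[t_min, t_max] hours, and the summed duration at most Delta hours.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple

import numpy as np

__all__ = ["TestSite", "SiteSchedule", "ScheduleConstraints", "Violation",
           "sites_to_matrix", "matrix_to_sites", "validate_constraints"]


class TestSite(NamedTuple):
    """A site active during intervals start+1 .. finish on one link."""

    start: int
    finish: int
    link: int

    @property
    def duration_intervals(self) -> int:
        return self.finish - self.start


@dataclass(frozen=True)
class SiteSchedule:
    """Canonical site list for one day.

    Canonical form: sites sorted by (link, start); on any one link, active
    windows neither overlap nor touch (two adjacent windows would be a single
    site), i.e. the next start is at least the previous finish + 1.
    """

    sites: tuple
    t_star: int = 96
    day: object = None

    def __post_init__(self) -> None:
        sites = tuple(TestSite(*s) for s in self.sites)
        object.__setattr__(self, "sites", sites)
        for s in sites:
            if not (0 <= s.start < s.finish <= self.t_star):
                raise ValueError(f"site {s} violates 0 <= start < finish <= t*")
        ordered = sorted(sites, key=lambda s: (s.link, s.start))
        if list(sites) != ordered:
            raise ValueError("sites not sorted by (link, start); not canonical")
        for a, b in zip(ordered, ordered[1:]):
            if a.link == b.link and b.start <= a.finish:
                raise ValueError(
                    f"sites {a} and {b} on link {a.link} overlap or touch")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def total_duration_intervals(self) -> int:
        return sum(s.duration_intervals for s in self.sites)

    def total_duration_hours(self) -> float:
        return self.total_duration_intervals * 24.0 / self.t_star

    @staticmethod
    def from_sites(sites, t_star: int = 96, day=None) -> "SiteSchedule":
        """Build a canonical schedule, sorting and merging touching windows."""
        sites = sorted((TestSite(*s) for s in sites), key=lambda s: (s.link, s.start))
        merged: list[TestSite] = []
        for s in sites:
            if merged and merged[-1].link == s.link and s.start <= merged[-1].finish:
                prev = merged.pop()
                s = TestSite(prev.start, max(prev.finish, s.finish), s.link)
            merged.append(s)
        return SiteSchedule(tuple(merged), t_star=t_star, day=day)


def sites_to_matrix(schedule: SiteSchedule, link_ids) -> np.ndarray:
    """Binary schedule matrix S: rows in link_ids order, t* columns."""
    link_ids = np.asarray(link_ids)
    row = {lid: i for i, lid in enumerate(link_ids)}
    S = np.zeros((len(link_ids), schedule.t_star), dtype=np.int8)
    for s in schedule.sites:
        if s.link not in row:
            raise ValueError(f"site link {s.link} not in link set")
        S[row[s.link], s.start:s.finish] = 1  # active intervals start+1..finish
    return S


def matrix_to_sites(S: np.ndarray, link_ids, t_star: int | None = None,
                    day=None) -> SiteSchedule:
    """Maximal runs of ones per row become sites; output is canonical."""
    S = np.asarray(S)
    if not np.isin(S, (0, 1)).all():
        raise ValueError("schedule matrix must be binary")
    if t_star is None:
        t_star = S.shape[1]
    link_ids = np.asarray(link_ids)
    sites = []
    for i, lid in enumerate(link_ids):
        padded = np.concatenate([[0], S[i], [0]])
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)   # 0-based first active column
        ends = np.flatnonzero(d == -1)    # 0-based one-past-last
        for a, b in zip(starts, ends):
            sites.append(TestSite(int(a), int(b), lid))
    sites.sort(key=lambda s: (s.link, s.start))
    return SiteSchedule(tuple(sites), t_star=t_star, day=day)


@dataclass(frozen=True)
class ScheduleConstraints:
    """Police-resource limits on a daily schedule."""

    n_max: int = 58
    t_min_h: float = 1.0
    t_max_h: float = 3.0
    delta_h: float = 58.0
    t_star: int = 96

    def __post_init__(self) -> None:
        if not (0 < self.t_min_h <= self.t_max_h):
            raise ValueError("need 0 < t_min <= t_max")
        if self.delta_h <= 0:
            raise ValueError("Delta must be > 0")
        if self.n_max < 0:
            raise ValueError("N_max must be >= 0")
        if 1440 % self.t_star:
            raise ValueError("t_star must divide 1440")

    def _hours_to_intervals(self, hours: float) -> Fraction:
        frac = Fraction(hours).limit_denominator(10**6) * self.t_star / 24
        return frac

    @property
    def t_min_intervals(self) -> int:
        f = self._hours_to_intervals(self.t_min_h)
        if f.denominator != 1:
            raise ValueError(f"t_min = {self.t_min_h} h is not a whole number "
                             f"of {1440 // self.t_star}-min intervals")
        return int(f)

    @property
    def t_max_intervals(self) -> int:
        f = self._hours_to_intervals(self.t_max_h)
        if f.denominator != 1:
            raise ValueError(f"t_max = {self.t_max_h} h is not a whole number "
                             f"of {1440 // self.t_star}-min intervals")
        return int(f)

    @property
    def delta_intervals(self) -> int:
        # total-duration cap, floored to whole intervals
        return int(self._hours_to_intervals(self.delta_h))


class Violation(NamedTuple):
    clause: str  # "4a" | "4b" | "4c"
    sites: tuple
    message: str


def validate_constraints(schedule: SiteSchedule, c: ScheduleConstraints):
    """Check a schedule against the resource constraints.

    Returns a (possibly empty) list of violations; never raises.
    """
    violations: list[Violation] = []
    if len(schedule) > c.n_max:
        violations.append(Violation("4a", tuple(range(len(schedule))),
                                    f"{len(schedule)} sites > N_max = {c.n_max}"))
    hours_per_interval = 24.0 / schedule.t_star
    bad = []
    for w, s in enumerate(schedule.sites):
        dur_h = s.duration_intervals * hours_per_interval
        if not (c.t_min_h - 1e-12 <= dur_h <= c.t_max_h + 1e-12):
            bad.append(w)
    if bad:
        violations.append(Violation("4b", tuple(bad),
                                    f"site duration outside [{c.t_min_h}, {c.t_max_h}] h"))
    total_h = schedule.total_duration_intervals * hours_per_interval
    if total_h > c.delta_h + 1e-12:
        violations.append(Violation("4c", tuple(range(len(schedule))),
                                    f"total duration {total_h} h > Delta = {c.delta_h} h"))
    return violations
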