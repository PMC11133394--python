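"""Benchmark schedulers: uniform-random and deterministic greedy.

The random scheduler draws site links, start times and durations uniformly
and keeps adding sites until another would breach the site-count or total
duration cap.  The deterministic scheduler scores every (link, 75-minute
window) candidate on a modified crash matrix

    c_bar = c_hat + 2 * f_hat / max(f_hat)

and accepts the best non-conflicting windows greedily until the constraints
bind; it is fully deterministic (score ties broken by lower link id, then
earlier start).
"""

from __future__ import annotations

import numpy as np

from .schedule import ScheduleConstraints, SiteSchedule, TestSite

__all__ = ["random_schedule", "modified_crash_matrix", "det_schedule"]


def random_schedule(link_ids, constraints: ScheduleConstraints, rng,
                    t_star: int | None = None, day=None,
                    max_link_retries: int = 50) -> SiteSchedule:
    """A feasible schedule with uniform links, starts and durations."""
    if t_star is None:
        t_star = constraints.t_star
    link_ids = list(link_ids)
    t_min, t_max = constraints.t_min_intervals, constraints.t_max_intervals
    windows: dict = {}
    sites: list[TestSite] = []
    total = 0
    while True:
        if len(sites) + 1 > constraints.n_max:
            break
        dur = int(rng.integers(t_min, t_max + 1))
        if total + dur > constraints.delta_intervals:
            break
        placed = False
        for _ in range(max_link_retries):
            link = link_ids[int(rng.integers(len(link_ids)))]
            occ = windows.get(link, [])
            starts = [a for a in range(0, t_star - dur + 1)
                      if all(a + dur < s or a > f for s, f in occ)]
            if not starts:
                continue
            a = starts[int(rng.integers(len(starts)))]
            sites.append(TestSite(a, a + dur, link))
            windows.setdefault(link, []).append((a, a + dur))
            total += dur
            placed = True
            break
        if not placed:
            break
    return SiteSchedule.from_sites(sites, t_star=t_star, day=day)


def modified_crash_matrix(C_hat: np.ndarray, F: np.ndarray) -> np.ndarray:
    """c_bar = c_hat + 2 * f / f_max; the max-flow cell gains exactly +2."""
    C_hat = np.asarray(C_hat, dtype=float)
    F = np.asarray(F, dtype=float)
    if C_hat.shape != F.shape:
        raise ValueError("crash and flow matrices must share shape")
    f_star = F.max()
    if f_star <= 0:
        return C_hat.copy()
    return C_hat + 2.0 * F / f_star


def det_schedule(C_hat: np.ndarray, F: np.ndarray, constraints: ScheduleConstraints,
                 link_ids, site_minutes: int = 75, day=None) -> SiteSchedule:
    """Greedy deterministic schedule of fixed-duration sites.

    Ranks all (link, window) candidates of ``site_minutes`` duration by their
    modified-crash-matrix window score and accepts non-conflicting candidates
    until the site-count or total-duration cap binds.
    """
    link_ids = np.asarray(link_ids)
    t_star = constraints.t_star
    dt = 1440 // t_star
    if site_minutes % dt:
        raise ValueError(f"{site_minutes}-min sites need t* admitting {dt}-min intervals")
    dur = site_minutes // dt
    C_bar = modified_crash_matrix(C_hat, F)
    if C_bar.shape != (len(link_ids), t_star):
        raise ValueError("matrix shape does not match link set / t*")

    # window scores via cumulative sums along time
    cs = np.concatenate([np.zeros((C_bar.shape[0], 1)), np.cumsum(C_bar, axis=1)], axis=1)
    n_starts = t_star - dur + 1
    scores = cs[:, dur:dur + n_starts] - cs[:, :n_starts]  # (links, starts)

    rows, starts = np.unravel_index(np.argsort(-scores, axis=None, kind="stable"),
                                    scores.shape)
    windows: dict = {}
    sites: list[TestSite] = []
    total = 0
    dur_h = dur * 24.0 / t_star
    for r, a in zip(rows, starts):
        if len(sites) + 1 > constraints.n_max:
            break
        if (total + dur) * 24.0 / t_star > constraints.delta_h + 1e-12:
            break
        if not (constraints.t_min_h - 1e-12 <= dur_h <= constraints.t_max_h + 1e-12):
            break  # fixed duration incompatible with (4b); emit empty schedule
        link = link_ids[r]
        occ = windows.get(link, [])
        if any(not (a + dur < s or a > f) for s, f in occ):
            continue
        sites.append(TestSite(int(a), int(a + dur), link))
        windows.setdefault(link, []).append((a, a + dur))
        total += dur
    return SiteSchedule.from_sites(sites, t_star=t_star, day=day)
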