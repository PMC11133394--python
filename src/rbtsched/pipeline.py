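"""End-to-end wiring: scenario -> matrices -> schedules -> simulation report.

This is the high-level surface the CLI and the reproduction script drive:
impute flows, build and cluster crash matrices, produce a schedule for any
date by any of the four methods (opt1, opt2, det, rand), and run the
Monte-Carlo comparison.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import benchmarks, ga, simulate
from .config import RunConfig
from .crashes import DayClusterModel, build_crash_matrices
from .flows import SensorFlowSet, build_flow_matrices
from .network import RoadNetwork

log = logging.getLogger(__name__)

__all__ = ["ScenarioModels", "build_models", "schedule_for", "run_comparison"]


class ScenarioModels:
    """Fitted artefacts for one scenario: flows, crash matrices, clustering."""

    def __init__(self, net: RoadNetwork, flow_profile, crash_data, cluster_model,
                 calendar: pd.DataFrame, cfg: RunConfig):
        self.net = net
        self.flow_profile = flow_profile
        self.crash_data = crash_data
        self.cluster_model = cluster_model
        self.calendar = calendar
        self.cfg = cfg
        self._overall = None
        self._holiday = dict(zip(calendar["date"], calendar["is_holiday"]))

    def flow_for_date(self, date) -> np.ndarray:
        return self.flow_profile.for_date(date)

    def is_holiday(self, date) -> bool:
        return bool(self._holiday.get(pd.Timestamp(date).date(), 0))

    def cluster_for_date(self, date) -> int:
        return self.cluster_model.cluster_for_date(date, self.is_holiday(date))

    def crash_matrix_for(self, date, mode: str) -> np.ndarray:
        if mode == "opt1":
            return self.cluster_model.matrices[self.cluster_for_date(date)]
        if self._overall is None:
            self._overall = self.crash_data.overall_matrix()
        return self._overall

    def eps_for_date(self, date) -> np.ndarray:
        return self.cluster_model.eps[self.cluster_for_date(date)]


def build_models(bundle: dict, cfg: RunConfig | None = None,
                 cluster_seed: int | None = None) -> ScenarioModels:
    """Impute flows, bin and cluster crashes for a generated/loaded bundle."""
    cfg = cfg or RunConfig()
    net = bundle["net"]
    sensors = SensorFlowSet(bundle["flows"], t_star=cfg.t_star)
    _, profile = build_flow_matrices(net, sensors, U=cfg.U)
    crash_data = build_crash_matrices(bundle["records"], net, t_star=cfg.t_star)
    model = DayClusterModel.fit(crash_data, bundle["calendar"], K=cfg.K,
                                seed=cfg.seed if cluster_seed is None else cluster_seed)
    return ScenarioModels(net, profile, crash_data, model, bundle["calendar"], cfg)


def schedule_for(models: ScenarioModels, date, method: str, rng=None,
                 ga_params=None):
    """One day's schedule by any of the four methods."""
    cfg = models.cfg
    F = models.flow_for_date(date)
    if method in ("opt1", "opt2"):
        C = models.crash_matrix_for(date, method)
        params = ga_params or cfg.ga
        best, trace = ga.optimize(C, F, cfg.weights, cfg.capacity, cfg.constraints,
                                  params, models.net.link_ids, rng=rng)
        return best, trace
    if method == "det":
        C_hat = models.crash_matrix_for(date, "opt2")
        return benchmarks.det_schedule(C_hat, F, cfg.constraints,
                                       models.net.link_ids, day=date), None
    if method == "rand":
        if rng is None:
            rng = np.random.default_rng(cfg.seed)
        return benchmarks.random_schedule(models.net.link_ids, cfg.constraints,
                                          rng, day=date), None
    raise ValueError(f"unknown method {method!r}")


def run_comparison(models: ScenarioModels, eval_dates, methods=("opt1", "det", "rand"),
                   n_reps: int = 20, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo comparison table over methods x days, averaged over reps.

    GA schedules are computed once per distinct crash cluster (opt1) or once
    overall (opt2) and reused across the matching dates, mirroring per-cluster
    scheduling; random schedules are redrawn per repetition.
    """
    cfg = models.cfg
    schedules: dict = {}
    for method in methods:
        if method == "rand":
            schedules["RBT-rand"] = lambda day, rng: benchmarks.random_schedule(
                models.net.link_ids, cfg.constraints, rng, day=day)
            continue
        per_day = {}
        cache: dict = {}
        for day in eval_dates:
            if method in ("opt1", "opt2"):
                key = (models.cluster_for_date(day) if method == "opt1" else "all",
                       pd.Timestamp(day).weekday())
                if key not in cache:
                    rng = np.random.default_rng([seed, abs(hash((method,) + key)) % 2**31])
                    cache[key], _ = schedule_for(models, day, method, rng=rng)
                per_day[day] = cache[key]
            else:
                per_day[day], _ = schedule_for(models, day, method)
        schedules[f"RBT-{method}"] = per_day
    return simulate.evaluate_report(
        schedules, eval_dates, models.net, models.flow_for_date,
        models.eps_for_date, cfg.capacity, cfg.n_drivers, cfg.speed_kmh,
        n_reps=n_reps, seed=seed)
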