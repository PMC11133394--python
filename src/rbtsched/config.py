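"""Run configuration: one JSON document covering every tunable parameter.

Defaults are the reference experimental configuration: 96 15-min intervals,
capacity 4 tests/min, constraints N_max=58 / t_min=1 h / t_max=3 h / Delta=58 h,
GA sizes 100/30/34/50 with operator probabilities 0.4/0.3/0.3 and
p_e = p_s = 0.5, K = 4 crash clusters, U = 3 imputation neighbours, fitness
weights (0.999994, 1e-5, -4e-6), and a 50 km/h simulated driving speed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

from .fitness import CapacityModel, FitnessWeights
from .ga import GAParams
from .schedule import ScheduleConstraints

__all__ = ["RunConfig", "load_config", "save_config"]

MODES = ("opt1", "opt2", "rand", "det")


@dataclass
class RunConfig:
    t_star: int = 96
    varsigma: float = 4.0
    constraints: ScheduleConstraints = field(default_factory=ScheduleConstraints)
    weights: FitnessWeights = field(default_factory=FitnessWeights)
    ga: GAParams = field(default_factory=GAParams)
    K: int = 4
    U: int = 3
    n_drivers: int = 500
    speed_kmh: float = 50.0
    mode: str = "opt1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.t_star != self.constraints.t_star:
            raise ValueError("t_star mismatch between config and constraints")
        if self.K < 1 or self.U < 2:
            raise ValueError("need K >= 1 and U >= 2")
        if self.n_drivers < 0 or self.speed_kmh <= 0:
            raise ValueError("n_drivers >= 0 and speed > 0 required")

    @property
    def capacity(self) -> CapacityModel:
        return CapacityModel(varsigma=self.varsigma, t_star=self.t_star)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_SECTIONS = {"constraints": ScheduleConstraints, "weights": FitnessWeights,
             "ga": GAParams}


def load_config(path) -> RunConfig:
    """Read a JSON config; absent keys take the defaults above.

    Unknown keys are rejected with the offending names listed.
    """
    with open(path) as fh:
        text = fh.read().strip()
    raw = json.loads(text) if text else {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a JSON object")
    kwargs = {}
    bad = []
    flat_fields = {f.name for f in dataclasses.fields(RunConfig)}
    for key, val in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val) - names
            if unknown:
                bad.extend(f"{key}.{k}" for k in sorted(unknown))
            else:
                kwargs[key] = cls(**val)
        elif key in flat_fields:
            kwargs[key] = val
        else:
            bad.append(key)
    if bad:
        raise ValueError(f"unknown config keys: {bad}")
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=1)
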