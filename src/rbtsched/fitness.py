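"""Testing-capacity probability model and the deterrence fitness.

A site can deliver at most varsigma tests per minute.  With flow f vehicles
per interval (of 1440/t* minutes), the probability that an arbitrary passing
driver is tested is

    p = 1                      if f * t*/1440 <= varsigma
    p = 1440*varsigma/(t* f)   otherwise,

so the delivered per-minute testing rate is min(f * t*/1440, varsigma).
The deterrence fitness of schedule S given crash matrix C and flow matrix F is

    V = alpha * P + beta * Q + gamma * R,

with P = sum s*c*p (expected positive tests, crashes as the drink-driving
proxy), Q = sum s*f*p (total tests) and R = sum s*f - Q (observing drivers
who pass an active site untested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["CapacityModel", "FitnessWeights", "DeterrenceCounts",
           "test_probability", "expected_counts", "fitness",
           "fitness_cell_values", "expected_positives_from_trips"]


@dataclass(frozen=True)
class CapacityModel:
    """Per-site testing capacity: at most varsigma tests per minute."""

    varsigma: float = 4.0
    t_star: int = 96

    def __post_init__(self) -> None:
        if self.varsigma <= 0:
            raise ValueError("varsigma must be > 0")
        if 1440 % self.t_star:
            raise ValueError("t_star must divide 1440")


@dataclass(frozen=True)
class FitnessWeights:
    """Weights on positives (alpha), tests (beta) and observers (gamma).

    The model intends all three positive, but the reference experiment uses a
    small negative observer weight; any finite reals are accepted and a
    warning logged when gamma <= 0 or alpha/beta <= 0.
    """

    alpha: float = 0.999994
    beta: float = 1e-5
    gamma: float = -4e-6

    def __post_init__(self) -> None:
        for name, v in (("alpha", self.alpha), ("beta", self.beta), ("gamma", self.gamma)):
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.alpha <= 0 or self.beta <= 0 or self.gamma <= 0:
            log.warning("fitness weights (%g, %g, %g) contradict the all-positive "
                        "deterrence assumption", self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class DeterrenceCounts:
    P: float  # expected positive tests
    Q: float  # expected total tests
    R: float  # expected observing drivers
    V: float | None = None  # fitness, if weights were supplied
    Lambda: float | None = None  # trip-based expected positives, if computed


def test_probability(f, cap: CapacityModel):
    """Probability of an arbitrary driver being tested at an active site.

    f is vehicles per interval (scalar or array); zero flow gives p = 1.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("flow must be non-negative")
    per_min = f * cap.t_star / 1440.0
    with np.errstate(divide="ignore"):
        p = np.where(per_min <= cap.varsigma, 1.0,
                     1440.0 * cap.varsigma / (cap.t_star * np.maximum(f, 1e-300)))
    return p if p.ndim else float(p)


def _check_shapes(S, C, F):
    S, C, F = (np.asarray(x, dtype=float) for x in (S, C, F))
    if not (S.shape == C.shape == F.shape):
        raise ValueError(f"shape mismatch: S{S.shape}, C{C.shape}, F{F.shape}")
    return S, C, F


def expected_counts(S, C, F, cap: CapacityModel) -> DeterrenceCounts:
    """Expected positives, total tests and observers for a schedule matrix."""
    S, C, F = _check_shapes(S, C, F)
    p = test_probability(F, cap)
    P = float((S * C * p).sum())
    Q = float((S * F * p).sum())
    R = float((S * F).sum() - Q)
    return DeterrenceCounts(P=P, Q=Q, R=R)


def fitness(S, C, F, weights: FitnessWeights, cap: CapacityModel) -> float:
    """Deterrence fitness V = alpha*P + beta*Q + gamma*R.

    Computed both as the weighted sum of the three counts and as the
    equivalent single-sum cell form; the two are asserted to agree to 1e-9
    relative.
    """
    counts = expected_counts(S, C, F, cap)
    v_sum = weights.alpha * counts.P + weights.beta * counts.Q + weights.gamma * counts.R
    S, C, F = _check_shapes(S, C, F)
    v_cell = float((S * fitness_cell_values(C, F, weights, cap)).sum())
    scale = max(abs(v_sum), abs(v_cell), 1.0)
    if abs(v_sum - v_cell) > 1e-9 * scale:
        raise AssertionError(f"fitness forms disagree: {v_sum} vs {v_cell}")
    return v_sum


def fitness_cell_values(C, F, weights: FitnessWeights, cap: CapacityModel) -> np.ndarray:
    """Per-cell fitness contribution W with V = sum over active cells of W.

    W = alpha*p*c + (beta*p + gamma*(1-p))*f; precomputing W makes schedule
    fitness a sum over active cells, which the GA exploits via cumulative
    sums along the time axis.
    """
    C = np.asarray(C, dtype=float)
    F = np.asarray(F, dtype=float)
    p = test_probability(F, cap)
    return weights.alpha * p * C + (weights.beta * p + weights.gamma * (1.0 - p)) * F


def expected_positives_from_trips(S, occupancies, p) -> float:
    """Trip-based expected positives Lambda = sum s * (sum_u q^u) * p.

    occupancies: iterable of binary (links, t*) arrays, one per drink driver.
    Counts every active site on a driver's route, so it slightly overestimates
    relative to first-site stopping.
    """
    S = np.asarray(S, dtype=float)
    p = np.asarray(p, dtype=float)
    total = 0.0
    for q in occupancies:
        q = np.asarray(q, dtype=float)
        if q.shape != S.shape:
            raise ValueError("occupancy shape does not match schedule")
        total += float((S * q * p).sum())
    return total
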