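"""Marginal-value-theorem choice model primitives.

A forager facing a depleting patch either harvests again or pays a travel
cost to reach a fresh patch.  The model compares the expected reward of the
next harvest against a per-condition exit threshold through a softmax with
inverse temperature beta.  The threshold is determined by the totals of a
condition: rewards collected, number of travels (each charged the travel
cost in apples), and the number of harvest periods T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .environment import EnvironmentConfig, sample_patch, harvest_patch

__all__ = [
    "MVTParams",
    "ConditionSummary",
    "expected_reward",
    "condition_threshold",
    "harvest_likelihood",
    "self_consistent_threshold",
    "BestThresholdResult",
    "best_threshold_search",
]

PARAM_NAMES = (
    "c_low_cognitive",
    "c_high_cognitive",
    "c_low_physical",
    "c_high_physical",
    "log_beta",
)


@dataclass(frozen=True)
class MVTParams:
    """Per-participant travel costs (apples) and softmax inverse temperature.

    High-effort costs are *marginal*: the travel cost in a high-effort block
    is ``c_low + c_high`` for that effort type.  Costs may be negative
    (effort seeking); beta must be non-negative (zero gives indifferent
    choice, useful only on the generative side).
    """

    c_low_cognitive: float = 0.0
    c_high_cognitive: float = 0.0
    c_low_physical: float = 0.0
    c_high_physical: float = 0.0
    inverse_temperature: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.inverse_temperature) and self.inverse_temperature >= 0):
            raise ValueError(
                f"inverse_temperature must be finite and >= 0, got {self.inverse_temperature}"
            )
        for name in PARAM_NAMES[:4]:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite, got {getattr(self, name)}")

    def condition_cost(self, effort_type: str, effort_level: str) -> float:
        """Total travel cost for a condition (marginal parameterization)."""
        low = getattr(self, f"c_low_{effort_type}")
        if effort_level == "low":
            return low
        return low + getattr(self, f"c_high_{effort_type}")

    def to_vector(self) -> np.ndarray:
        return np.array(
            [
                self.c_low_cognitive,
                self.c_high_cognitive,
                self.c_low_physical,
                self.c_high_physical,
                math.log(self.inverse_temperature),
            ]
        )

    @classmethod
    def from_vector(cls, v) -> "MVTParams":
        return cls(
            c_low_cognitive=float(v[0]),
            c_high_cognitive=float(v[1]),
            c_low_physical=float(v[2]),
            c_high_physical=float(v[3]),
            inverse_temperature=float(np.exp(v[4])),
        )


@dataclass(frozen=True)
class ConditionSummary:
    """Realized totals of one condition, which pin down its exit threshold."""

    condition: str
    total_rewards: float
    n_travels: int
    harvest_periods: float  # T = condition duration / harvest time

    def __post_init__(self) -> None:
        if not self.harvest_periods > 0:
            raise ValueError(f"harvest_periods (T) must be > 0, got {self.harvest_periods}")
        if self.n_travels < 0:
            raise ValueError(f"n_travels must be >= 0, got {self.n_travels}")


def expected_reward(last_reward: float, kappa: float):
    """Expected reward of the next harvest: last reward times the mean decay.

    The floor applies to obtained rewards, not to this expectation.  For the
    first free decision after a forced harvest, ``last_reward`` is the
    forced harvest's reward.
    """
    if not 0 < kappa < 1:
        raise ValueError(f"kappa must lie in (0, 1), got {kappa}")
    last = np.asarray(last_reward, dtype=float)
    if np.any(last < 0):
        raise ValueError("last_reward must be >= 0")
    out = last * kappa
    return float(out) if np.isscalar(last_reward) else out


def condition_threshold(summary: ConditionSummary, condition_cost: float) -> float:
    """Exit threshold rho = (sum rewards - n_travels * cost) / T.

    The average net reward per harvest period: total rewards minus total
    travel costs, divided by the number of harvest periods in the condition.
    """
    return (summary.total_rewards - summary.n_travels * condition_cost) / summary.harvest_periods


def harvest_likelihood(expected_reward, threshold, beta):
    """P(harvest) = logistic(beta * (R_e - rho)).

    Vectorized over any broadcastable combination of inputs.
    """
    r = np.asarray(expected_reward, dtype=float)
    rho = np.asarray(threshold, dtype=float)
    b = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(rho)) and np.all(np.isfinite(b))):
        raise ValueError("expected_reward, threshold, and beta must be finite")
    z = b * (r - rho)
    out = np.exp(-np.logaddexp(0.0, -z))
    return float(out) if out.ndim == 0 else out


def _patch_cycle(threshold: float, config: EnvironmentConfig) -> tuple[float, int]:
    """Expected rewards and harvest count for one patch under a fixed threshold.

    Deterministic expectation dynamics: the forced harvest yields the mean
    initial reward; each further expected reward multiplies by the mean
    decay, floored like obtained rewards; harvesting continues while the
    expected next reward is at least the threshold.
    """
    kappa = config.decay_mean
    reward = config.initial_reward_mean
    total = reward
    n_harvests = 1
    # hard cap guards pathological thresholds at or below the floored plateau
    while reward * kappa >= threshold:
        reward = max(config.reward_floor, reward * kappa)
        total += reward
        n_harvests += 1
        if n_harvests > 10_000:
            break
    return total, n_harvests


def self_consistent_threshold(
    condition_cost: float,
    config: EnvironmentConfig,
    tol: float = 1e-3,
    max_iter: int = 50,
    damping: float = 0.5,
) -> float:
    """Fixed point of the threshold equation under expectation dynamics.

    The threshold depends on realized totals, which depend on behavior under
    the threshold.  Iterates rho -> (sum rewards - cost) / harvest periods
    for one deterministic patch cycle until the update is below ``tol`` (in
    apples) or ``max_iter`` is reached.
    """
    travel_periods = config.travel_duration / config.harvest_duration
    rho = config.initial_reward_mean * config.decay_mean / 2.0
    for _ in range(max_iter):
        total, n_harvests = _patch_cycle(rho, config)
        periods = n_harvests + travel_periods
        rho_new = (total - condition_cost) / periods
        step = rho_new - rho
        rho = rho + damping * step
        if abs(step) < tol:
            break
    return rho


@dataclass
class BestThresholdResult:
    """Outcome of a grid search over fixed exit-threshold policies."""

    best_threshold: float
    reward_rate: float  # apples per second at the best threshold
    mean_harvests: float
    sd_harvests: float
    grid: np.ndarray = field(repr=False)
    rates: np.ndarray = field(repr=False)


def best_threshold_search(
    config: EnvironmentConfig,
    grid,
    n_sim: int = 2000,
    rng: np.random.Generator | int = 0,
) -> BestThresholdResult:
    """Simulate fixed-threshold policies and return the reward-rate maximizer.

    For each candidate threshold, ``n_sim`` patch visits are simulated: the
    forced harvest, then harvesting while the expected next reward stays at
    or above the threshold, then travel.  The long-run reward rate is total
    apples over total seconds.  Also summarizes how many harvests it takes
    to reach the threshold.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    kappa = config.decay_mean

    rates = np.empty(grid.size)
    harvest_stats = np.empty((grid.size, 2))
    base_seed = int(rng.integers(2**63))
    for j, rho in enumerate(grid):
        # common random numbers across grid points for a smooth rate curve
        sub = np.random.default_rng(base_seed)
        total_reward = 0.0
        total_time = 0.0
        harvest_counts = np.empty(n_sim)
        for s in range(n_sim):
            patch = sample_patch(config, sub)
            total_reward += patch.current_reward
            n = 1
            while patch.current_reward * kappa >= rho:
                reward, patch = harvest_patch(patch, config, sub)
                total_reward += reward
                n += 1
                if n > 10_000:
                    break
            total_time += n * config.harvest_duration + config.travel_duration
            harvest_counts[s] = n
        rates[j] = total_reward / total_time
        harvest_stats[j] = harvest_counts.mean(), harvest_counts.std(ddof=1)

    best = int(np.argmax(rates))
    return BestThresholdResult(
        best_threshold=float(grid[best]),
        reward_rate=float(rates[best]),
        mean_harvests=float(harvest_stats[best, 0]),
        sd_harvests=float(harvest_stats[best, 1]),
        grid=grid,
        rates=rates,
    )
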