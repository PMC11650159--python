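"""Orchard environment: patch rewards, decay, and configuration.

The environment is a block-structured patch-foraging world.  Each patch
yields an initial reward drawn from a normal distribution; every further
harvest multiplies the previous reward by a beta-distributed decay draw,
floored at a minimum reward.  Blocks pair an effort type (cognitive or
physical) with an effort level (low or high) and run for a fixed duration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

__all__ = [
    "EffortCondition",
    "EnvironmentConfig",
    "Patch",
    "DEFAULT_CONDITIONS",
    "sample_patch",
    "harvest_patch",
]

EFFORT_TYPES = ("cognitive", "physical")
EFFORT_LEVELS = ("low", "high")


@dataclass(frozen=True)
class EffortCondition:
    """One (effort type, effort level) block condition."""

    effort_type: str
    effort_level: str

    def __post_init__(self) -> None:
        if self.effort_type not in EFFORT_TYPES:
            raise ValueError(f"effort_type must be one of {EFFORT_TYPES}, got {self.effort_type!r}")
        if self.effort_level not in EFFORT_LEVELS:
            raise ValueError(f"effort_level must be one of {EFFORT_LEVELS}, got {self.effort_level!r}")

    @property
    def label(self) -> str:
        return f"{self.effort_type}_{self.effort_level}"


DEFAULT_CONDITIONS = (
    EffortCondition("cognitive", "low"),
    EffortCondition("cognitive", "high"),
    EffortCondition("physical", "low"),
    EffortCondition("physical", "high"),
)


@dataclass(frozen=True)
class EnvironmentConfig:
    """All orchard, timing, and condition parameters.

    Defaults: initial reward ~ N(15, 1) apples, decay ~ Beta(14.90873,
    2.033008) (mean 0.88), floor 0.5 apples, eight 7-minute blocks (two per
    condition).  Trial timings are configurable; the defaults give an agent
    on the order of tens of decisions per block.
    """

    initial_reward_mean: float = 15.0
    initial_reward_sd: float = 1.0
    decay_alpha: float = 14.90873
    decay_beta: float = 2.033008
    reward_floor: float = 0.5
    harvest_duration: float = 3.0
    travel_duration: float = 24.0
    block_duration: float = 420.0
    n_blocks_per_condition: int = 2
    conditions: tuple[EffortCondition, ...] = DEFAULT_CONDITIONS

    def __post_init__(self) -> None:
        for name in ("harvest_duration", "travel_duration", "block_duration"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not self.reward_floor > 0:
            raise ValueError(f"reward_floor must be > 0, got {self.reward_floor}")
        if not (self.decay_alpha > 0 and self.decay_beta > 0):
            raise ValueError(
                f"decay_alpha and decay_beta must be > 0, got {self.decay_alpha}, {self.decay_beta}"
            )
        if self.initial_reward_sd < 0:
            raise ValueError(f"initial_reward_sd must be >= 0, got {self.initial_reward_sd}")
        if self.n_blocks_per_condition < 0:
            raise ValueError(
                f"n_blocks_per_condition must be >= 0, got {self.n_blocks_per_condition}"
            )
        if isinstance(self.conditions, list):
            object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def decay_mean(self) -> float:
        """Analytic mean of the per-harvest decay distribution (kappa)."""
        return self.decay_alpha / (self.decay_alpha + self.decay_beta)

    @property
    def condition_duration(self) -> float:
        """Total time spent in one condition, in seconds."""
        return self.n_blocks_per_condition * self.block_duration

    @property
    def harvest_periods_per_condition(self) -> float:
        """T: condition duration divided by the harvest time."""
        return self.condition_duration / self.harvest_duration

    @property
    def n_blocks_total(self) -> int:
        return self.n_blocks_per_condition * len(self.conditions)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "initial_reward_mean",
                "initial_reward_sd",
                "decay_alpha",
                "decay_beta",
                "reward_floor",
                "harvest_duration",
                "travel_duration",
                "block_duration",
                "n_blocks_per_condition",
            )
        }
        d["conditions"] = [[c.effort_type, c.effort_level] for c in self.conditions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EnvironmentConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(EffortCondition(t, l) for t, l in d["conditions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "EnvironmentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_overrides(self, **kwargs) -> "EnvironmentConfig":
        return replace(self, **kwargs)


@dataclass
class Patch:
    """A depleting patch: the last obtained harvest and a harvest counter."""

    current_reward: float
    n_harvests: int = 0


def sample_patch(config: EnvironmentConfig, rng: np.random.Generator | int) -> Patch:
    """Draw a fresh patch whose initial reward ~ N(mean, sd).

    The initial reward is the yield of the patch's first (forced) harvest.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    reward = float(rng.normal(config.initial_reward_mean, config.initial_reward_sd))
    return Patch(current_reward=reward, n_harvests=1)


def harvest_patch(
    patch: Patch, config: EnvironmentConfig, rng: np.random.Generator | int
) -> tuple[float, Patch]:
    """Harvest once more: reward = max(floor, previous * Beta decay draw).

    Returns the obtained reward and the updated patch (a new object; the
    input patch is not mutated).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    decay = float(rng.beta(config.decay_alpha, config.decay_beta))
    reward = max(config.reward_floor, patch.current_reward * decay)
    return reward, Patch(current_reward=reward, n_harvests=patch.n_harvests + 1)
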