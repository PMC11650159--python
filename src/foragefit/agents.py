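"""Softmax foraging agents, synthetic cohorts, and synthetic symptom items."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import EnvironmentConfig, sample_patch, harvest_patch
from .io import TRIAL_LOG_COLUMNS
from .model import MVTParams, PARAM_NAMES, self_consistent_threshold

__all__ = [
    "AgentSpec",
    "GroupParams",
    "SymptomGenConfig",
    "simulate_participant",
    "simulate_cohort",
    "generate_symptom_items",
    "resolve_thresholds",
]


@dataclass(frozen=True)
class AgentSpec:
    """Generative counterpart of the choice model.

    ``threshold_mode='self_consistent'`` resolves per-condition exit
    thresholds by fixed-point iteration on the threshold equation;
    ``'fixed'`` takes them from ``fixed_thresholds`` (condition label ->
    apples).  ``missed_rate`` is the probability a free trial is missed.
    """

    true_params: MVTParams
    threshold_mode: str = "self_consistent"
    fixed_thresholds: dict | None = None
    missed_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("fixed", "self_consistent"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and not self.fixed_thresholds:
            raise ValueError("fixed threshold_mode requires fixed_thresholds")
        if not 0 <= self.missed_rate < 1:
            raise ValueError(f"missed_rate must be in [0, 1), got {self.missed_rate}")


def resolve_thresholds(agent: AgentSpec, config: EnvironmentConfig) -> dict[str, float]:
    """Per-condition exit thresholds for an agent (fixed or fixed-point)."""
    thresholds = {}
    for cond in config.conditions:
        if agent.threshold_mode == "fixed":
            rho = agent.fixed_thresholds[cond.label]
        else:
            cost = agent.true_params.condition_cost(cond.effort_type, cond.effort_level)
            rho = self_consistent_threshold(cost, config)
        if not np.isfinite(rho):
            raise ValueError(f"threshold for condition {cond.label} is not finite: {rho}")
        thresholds[cond.label] = float(rho)
    return thresholds


def simulate_participant(
    agent: AgentSpec,
    config: EnvironmentConfig,
    rng: np.random.Generator | int,
    participant_id: str = "p0",
    block_order: list | None = None,
) -> pd.DataFrame:
    """Simulate one participant's full session and return the trial log.

    Each block opens with a fresh patch and a forced first harvest; free
    trials then harvest with probability logistic(beta * (R_e - rho)) or
    exit, paying the travel time before the next patch's forced harvest.
    The block stops once elapsed time reaches the block duration, so a block
    overruns by at most one trial's duration.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    beta = agent.true_params.inverse_temperature
    if not (np.isfinite(beta) and beta >= 0):
        raise ValueError(f"inverse_temperature must be finite and >= 0, got {beta}")
    thresholds = resolve_thresholds(agent, config)
    kappa = config.decay_mean

    blocks = [c for c in config.conditions for _ in range(config.n_blocks_per_condition)]
    if block_order is None:
        blocks = [blocks[i] for i in rng.permutation(len(blocks))]
    else:
        blocks = list(block_order)

    rows = []
    for block_id, cond in enumerate(blocks):
        rho = thresholds[cond.label]
        time = 0.0
        trial = 0

        def emit(action, last, exp_r, reward, first):
            rows.append(
                {
                    "participant_id": participant_id,
                    "block": block_id,
                    "effort_type": cond.effort_type,
                    "effort_level": cond.effort_level,
                    "trial": trial,
                    "last_reward": last,
                    "expected_reward": exp_r,
                    "action": action,
                    "first_harvest": first,
                    "reward": reward,
                    "time": time,
                }
            )

        patch = sample_patch(config, rng)
        emit("harvest", np.nan, np.nan, patch.current_reward, True)
        time += config.harvest_duration
        trial += 1

        while time < config.block_duration:
            last = patch.current_reward
            exp_r = last * kappa
            if agent.missed_rate > 0 and rng.random() < agent.missed_rate:
                emit("missed", last, exp_r, np.nan, False)
                time += config.harvest_duration
            elif rng.random() < 1.0 / (1.0 + math.exp(-beta * (exp_r - rho))):
                reward, patch = harvest_patch(patch, config, rng)
                emit("harvest", last, exp_r, reward, False)
                time += config.harvest_duration
            else:
                emit("exit", last, exp_r, np.nan, False)
                time += config.travel_duration
                trial += 1
                if time >= config.block_duration:
                    break
                patch = sample_patch(config, rng)
                emit("harvest", np.nan, np.nan, patch.current_reward, True)
                time += config.harvest_duration
            trial += 1

    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


@dataclass(frozen=True)
class GroupParams:
    """Generative distribution of model parameters within one group.

    ``means``/``sds`` map the five parameter names (costs on the apples
    scale, ``log_beta`` on the log scale) to group means and SDs.
    ``coupling`` maps ``(param_name, factor_name)`` to a slope: the
    participant's true parameter gains ``slope * latent`` for that latent
    symptom factor (true cost = a + b * latent).
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    coupling: dict = field(default_factory=dict)
    missed_rate: float = 0.0

    DEFAULT_MEANS = {
        "c_low_cognitive": 2.0,
        "c_high_cognitive": 3.0,
        "c_low_physical": 2.0,
        "c_high_physical": 3.0,
        "log_beta": math.log(2.5),
    }
    DEFAULT_SDS = {
        "c_low_cognitive": 8.0,
        "c_high_cognitive": 9.0,
        "c_low_physical": 8.0,
        "c_high_physical": 9.0,
        "log_beta": 0.3,
    }

    def mean(self, name: str) -> float:
        return self.means.get(name, self.DEFAULT_MEANS[name])

    def sd(self, name: str) -> float:
        return self.sds.get(name, self.DEFAULT_SDS[name])


DEFAULT_FACTORS = ("anxiety", "anhedonia", "behavioral_apathy")


def simulate_cohort(
    n_mdd: int,
    n_comparison: int,
    group_params: dict[str, GroupParams],
    config: EnvironmentConfig,
    rng: np.random.Generator | int,
    factor_names: tuple[str, ...] = DEFAULT_FACTORS,
    remitted_fraction: float = 0.15,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a two-group study; returns (trial log, truth table, participants).

    ``group_params`` maps group labels ('mdd', 'comparison') to their
    generative distributions.  Latent symptom factors are independent
    standard normals per participant; couplings add ``slope * latent`` to
    the named true parameter.  The truth table carries every true parameter,
    true per-condition thresholds, and the latent factors; the participant
    table carries demographics, medication, remission status, and travel
    task performance summaries.
    """
    if n_mdd <= 0 or n_comparison <= 0:
        raise ValueError(f"group sizes must be > 0, got n_mdd={n_mdd}, n_comparison={n_comparison}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    seeds = rng.spawn(n_mdd + n_comparison + 1)
    demo_rng = seeds[-1]

    logs, truth_rows, part_rows = [], [], []
    roster = [("mdd", i) for i in range(n_mdd)] + [("comparison", i) for i in range(n_comparison)]
    for k, (group, i) in enumerate(roster):
        sub = seeds[k]
        gp = group_params[group]
        pid = f"{group}_{i:03d}"

        latents = {f: float(sub.normal()) for f in factor_names}
        values = {}
        for name in PARAM_NAMES:
            v = gp.mean(name) + gp.sd(name) * sub.normal()
            for (pname, fname), slope in gp.coupling.items():
                if pname == name:
                    v += slope * latents[fname]
            values[name] = v
        params = MVTParams(
            c_low_cognitive=values["c_low_cognitive"],
            c_high_cognitive=values["c_high_cognitive"],
            c_low_physical=values["c_low_physical"],
            c_high_physical=values["c_high_physical"],
            inverse_temperature=math.exp(values["log_beta"]),
        )
        agent = AgentSpec(true_params=params, missed_rate=gp.missed_rate)
        thresholds = resolve_thresholds(agent, config)
        logs.append(simulate_participant(agent, config, sub, participant_id=pid))

        truth_rows.append(
            {
                "participant_id": pid,
                "group": group,
                **{n: values[n] for n in PARAM_NAMES},
                "beta": params.inverse_temperature,
                **{f"true_threshold_{c}": t for c, t in thresholds.items()},
                **{f"latent_{f}": v for f, v in latents.items()},
            }
        )
        part_rows.append(
            {
                "participant_id": pid,
                "group": group,
                "age": float(np.clip(demo_rng.normal(27.0, 10.0), 18, 65)),
                "education_years": float(np.clip(demo_rng.normal(15.0, 2.5), 8, 22)),
                "bmi": float(np.clip(demo_rng.normal(25.0, 4.0), 16, 45)),
                "medication": int(group == "mdd" and demo_rng.random() < 0.5),
                "remitted": int(group == "mdd" and demo_rng.random() < remitted_fraction),
                "dprime_3back": float(demo_rng.normal(2.2, 0.6)),
                "pct_presses_completed": float(np.clip(demo_rng.normal(90.0, 8.0), 30, 100)),
            }
        )

    trials = pd.concat(logs, ignore_index=True)
    return trials, pd.DataFrame(truth_rows), pd.DataFrame(part_rows)


@dataclass(frozen=True)
class SymptomGenConfig:
    """Synthetic symptom-item generator with a known factor structure.

    Each factor gets ``items_per_factor`` informative items (value =
    loading * latent + noise) plus ``n_bad_items`` near-zero-loading items,
    which should fall to the item-total filter downstream.
    """

    items_per_factor: int = 6
    loading: float = 0.8
    noise_sd: float = 0.5
    n_bad_items: int = 0
    bad_loading: float = 0.0
    bad_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.items_per_factor < 2:
            raise ValueError(f"items_per_factor must be >= 2, got {self.items_per_factor}")
        if not 0 <= self.loading <= 1:
            raise ValueError(f"loading must lie in [0, 1], got {self.loading}")
        if self.noise_sd < 0 or self.bad_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def generate_symptom_items(
    truth: pd.DataFrame,
    config: SymptomGenConfig,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Long-format item table from a cohort truth table's latent factors.

    Factors are read off the ``latent_*`` columns of the truth table.
    Returns columns: participant_id, instrument, item, value.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    factors = [c[len("latent_") :] for c in truth.columns if c.startswith("latent_")]
    if not factors:
        raise ValueError("truth table has no latent_* factor columns")

    rows = []
    n = len(truth)
    for factor in factors:
        latent = truth[f"latent_{factor}"].to_numpy()
        for j in range(config.items_per_factor):
            values = config.loading * latent + rng.normal(0.0, config.noise_sd, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": truth["participant_id"],
                        "instrument": f"synth_{factor}",
                        "item": f"{factor}_item{j}",
                        "value": values,
                    }
                )
            )
        for j in range(config.n_bad_items):
            values = config.bad_loading * latent + rng.normal(0.0, config.bad_noise_sd, size=n)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": truth["participant_id"],
                        "instrument": f"synth_{factor}",
                        "item": f"{factor}_bad{j}",
                        "value": values,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
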