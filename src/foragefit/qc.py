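"""Participant-level quality control and exclusions.

Two rules: participants who miss the response deadline on too large a
fraction of foraging trials are excluded entirely; participants with too
few exit trials in any condition of an effort type are excluded from that
effort type's analyses only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import validate_trial_log

__all__ = ["ExclusionConfig", "ExclusionOutcome", "apply_exclusions"]


@dataclass(frozen=True)
class ExclusionConfig:
    max_missed_fraction: float = 0.25
    min_exits_per_condition: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_fraction <= 1:
            raise ValueError(
                f"max_missed_fraction must lie in [0, 1], got {self.max_missed_fraction}"
            )
        if self.min_exits_per_condition < 1:
            raise ValueError(
                f"min_exits_per_condition must be >= 1, got {self.min_exits_per_condition}"
            )


@dataclass
class ExclusionOutcome:
    included: pd.DataFrame  # trial log restricted to retained participant/effort-type pairs
    report: pd.DataFrame  # one row per triggered rule
    fully_excluded: list[str]
    effort_type_excluded: dict[str, list[str]]  # participant -> effort types dropped


def apply_exclusions(trials: pd.DataFrame, config: ExclusionConfig | None = None) -> ExclusionOutcome:
    """Apply missed-trial and minimum-exit exclusions to a trial log.

    Exclusion is condition-aware: a participant can be dropped for one
    effort type and kept for the other.  Every triggered rule produces one
    report row with the participant, rule, scope, and measured value.
    """
    config = config or ExclusionConfig()
    validate_trial_log(trials)
    report_rows = []
    fully_excluded: list[str] = []
    type_excluded: dict[str, list[str]] = {}

    for pid, grp in trials.groupby("participant_id", sort=True):
        missed_frac = float((grp["action"] == "missed").mean())
        if missed_frac > config.max_missed_fraction:
            fully_excluded.append(pid)
            report_rows.append(
                {
                    "participant_id": pid,
                    "rule": "max_missed_fraction",
                    "scope": "all",
                    "value": missed_frac,
                    "threshold": config.max_missed_fraction,
                    "detail": f"missed {missed_frac:.1%} of trials",
                }
            )
            continue
        for etype, tgrp in grp.groupby("effort_type"):
            exits = tgrp.groupby("effort_level")["action"].apply(lambda a: int((a == "exit").sum()))
            worst_level = exits.idxmin()
            if exits.min() < config.min_exits_per_condition:
                type_excluded.setdefault(pid, []).append(etype)
                report_rows.append(
                    {
                        "participant_id": pid,
                        "rule": "min_exits_per_condition",
                        "scope": etype,
                        "value": float(exits.min()),
                        "threshold": config.min_exits_per_condition,
                        "detail": f"{int(exits.min())} exits in {etype} {worst_level} effort",
                    }
                )

    keep = ~trials["participant_id"].isin(fully_excluded)
    for pid, etypes in type_excluded.items():
        for etype in etypes:
            keep &= ~((trials["participant_id"] == pid) & (trials["effort_type"] == etype))
    report = pd.DataFrame(
        report_rows,
        columns=["participant_id", "rule", "scope", "value", "threshold", "detail"],
    )
    return ExclusionOutcome(
        included=trials[keep].reset_index(drop=True),
        report=report,
        fully_excluded=fully_excluded,
        effort_type_excluded=type_excluded,
    )
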