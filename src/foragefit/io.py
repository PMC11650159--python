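"""Trial-log schema and plain-text I/O."""

from __future__ import annotations

import pandas as pd

__all__ = ["TRIAL_LOG_COLUMNS", "read_trial_log", "write_trial_log", "validate_trial_log"]

# fixed header; reward and time are appended so condition totals (sum of
# obtained rewards, timestamps) can be recomputed from the log alone
TRIAL_LOG_COLUMNS = [
    "participant_id",
    "block",
    "effort_type",
    "effort_level",
    "trial",
    "last_reward",
    "expected_reward",
    "action",
    "first_harvest",
    "reward",
    "time",
]

ACTIONS = {"harvest", "exit", "missed"}


def validate_trial_log(trials: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log is missing columns: {missing}")
    bad = set(trials["action"].unique()) - ACTIONS
    if bad:
        raise ValueError(f"trial log contains unknown actions: {sorted(bad)}")
    return trials


def read_trial_log(path) -> pd.DataFrame:
    trials = pd.read_csv(
        path, dtype={"participant_id": str, "effort_type": str, "effort_level": str}
    )
    trials["first_harvest"] = trials["first_harvest"].astype(bool)
    return validate_trial_log(trials)


def write_trial_log(trials: pd.DataFrame, path) -> None:
    validate_trial_log(trials)
    trials.to_csv(path, index=False, columns=TRIAL_LOG_COLUMNS)
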