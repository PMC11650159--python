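"""Model-agnostic exit-threshold estimation.

Mixed-effects regression of log expected reward on exit trials: an
intercept plus an effort-level term (fit separately per effort type), with
a random intercept per participant.  Per-participant overall exit
thresholds come from the low-effort-only regression: the exponentiated
participant-level prediction (fixed intercept plus random effect).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .io import validate_trial_log

logger = logging.getLogger(__name__)

__all__ = ["ExitRegressionResult", "exit_regression", "overall_thresholds", "low_effort_thresholds"]


@dataclass
class ExitRegressionResult:
    """Fitted exit regression: fixed effects plus per-participant intercepts."""

    intercept: float
    intercept_se: float
    effort_coef: float | None
    effort_coef_se: float | None
    random_effects: pd.Series = field(repr=False)
    n_exits: int = 0
    mixed: bool = True
    effort_type: str | None = None

    @property
    def participant_intercepts(self) -> pd.Series:
        """Per-participant predicted log threshold at the low effort level."""
        return self.intercept + self.random_effects


def _exit_frame(trials: pd.DataFrame, effort_type, effort_levels) -> pd.DataFrame:
    validate_trial_log(trials)
    sub = trials[(trials["action"] == "exit") & ~trials["first_harvest"]]
    if effort_type is not None:
        sub = sub[sub["effort_type"] == effort_type]
    if effort_levels is not None:
        sub = sub[sub["effort_level"].isin(effort_levels)]
    sub = sub[sub["expected_reward"] > 0]
    if sub.empty:
        raise ValueError("no exit trials found for the requested subset")
    out = sub[["participant_id", "effort_level"]].copy()
    out["log_expected"] = np.log(sub["expected_reward"].to_numpy())
    out["effort_high"] = (sub["effort_level"] == "high").astype(float)
    return out


def exit_regression(
    trials: pd.DataFrame,
    effort_type: str | None = None,
    effort_levels: tuple[str, ...] | None = None,
) -> ExitRegressionResult:
    """Regress log expected reward at exit on effort level (natural log).

    Random intercept per participant; with a single participant the model
    falls back to ordinary least squares with a logged warning.  The effort
    term is included only when both effort levels are present in the subset.
    """
    df = _exit_frame(trials, effort_type, effort_levels)
    participants = df["participant_id"].unique()
    has_effort_term = df["effort_high"].nunique() > 1
    formula = "log_expected ~ effort_high" if has_effort_term else "log_expected ~ 1"

    if len(participants) < 2:
        logger.warning("single participant: falling back to fixed-effects OLS")
        ols = smf.ols(formula, data=df).fit()
        return ExitRegressionResult(
            intercept=float(ols.params["Intercept"]),
            intercept_se=float(ols.bse["Intercept"]),
            effort_coef=float(ols.params["effort_high"]) if has_effort_term else None,
            effort_coef_se=float(ols.bse["effort_high"]) if has_effort_term else None,
            random_effects=pd.Series(0.0, index=participants),
            n_exits=len(df),
            mixed=False,
            effort_type=effort_type,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MixedLM convergence chatter on clean data
        model = smf.mixedlm(formula, data=df, groups=df["participant_id"])
        res = model.fit(reml=True)
    try:
        re = pd.Series({k: float(v.iloc[0]) for k, v in res.random_effects.items()})
    except ValueError:
        # between-participant variance estimated at zero: every participant
        # shares the fixed intercept
        logger.warning("random-effect variance is zero; using shared intercept")
        re = pd.Series(0.0, index=participants)
    return ExitRegressionResult(
        intercept=float(res.params["Intercept"]),
        intercept_se=float(res.bse["Intercept"]),
        effort_coef=float(res.params["effort_high"]) if has_effort_term else None,
        effort_coef_se=float(res.bse["effort_high"]) if has_effort_term else None,
        random_effects=re,
        n_exits=len(df),
        mixed=True,
        effort_type=effort_type,
    )


def overall_thresholds(result: ExitRegressionResult) -> pd.DataFrame:
    """Per-participant exit thresholds on the apples scale.

    Exponentiates the participant-level prediction; ordering is identical on
    the log and apples scales.
    """
    log_t = result.participant_intercepts
    return pd.DataFrame(
        {
            "participant_id": log_t.index,
            "log_threshold": log_t.to_numpy(),
            "threshold": np.exp(log_t.to_numpy()),
        }
    ).reset_index(drop=True)


def low_effort_thresholds(trials: pd.DataFrame) -> pd.DataFrame:
    """Overall exit thresholds estimated from low-effort conditions only."""
    return overall_thresholds(exit_regression(trials, effort_levels=("low",)))
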