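"""Symptom-severity scoring from multi-instrument item tables.

Scoring rules: items assigned to a factor are filtered by corrected
item-total correlation (iteratively dropping the lowest item below 0.2),
the factor is gated on Cronbach's alpha >= 0.6, and the surviving items are
z-scored within the scoring population and averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "item_total_filter",
    "cronbach_alpha",
    "score_factors",
    "FactorReport",
    "pivot_items",
]


def pivot_items(items: pd.DataFrame) -> pd.DataFrame:
    """Long item table (participant_id, instrument, item, value) -> wide."""
    return items.pivot_table(index="participant_id", columns="item", values="value", aggfunc="mean")


def _corrected_item_total(wide: pd.DataFrame) -> pd.Series:
    """Correlation of each item with the mean of the remaining items."""
    corrs = {}
    for col in wide.columns:
        rest = wide.drop(columns=col).mean(axis=1)
        pair = pd.concat([wide[col], rest], axis=1).dropna()
        corrs[col] = pair.iloc[:, 0].corr(pair.iloc[:, 1])
    return pd.Series(corrs)


def item_total_filter(
    items: pd.DataFrame, item_ids: list[str], threshold: float = 0.2
) -> tuple[list[str], list[tuple[str, float]]]:
    """Iteratively drop items with corrected item-total correlation < threshold.

    Removal order is deterministic: the lowest-correlating item first, then
    re-evaluate.  Returns (retained item ids, dropped (item, correlation)
    pairs).  A factor reduced to fewer than two mutually consistent items
    comes back empty (flagged unscorable by the caller).
    """
    missing = [i for i in item_ids if i not in items["item"].unique()]
    if missing:
        raise ValueError(f"items not present in table: {missing}")
    if len(item_ids) < 2:
        raise ValueError("item_total_filter needs at least 2 items")
    wide = pivot_items(items[items["item"].isin(item_ids)])
    retained = list(item_ids)
    dropped: list[tuple[str, float]] = []
    while len(retained) >= 2:
        corrs = _corrected_item_total(wide[retained])
        worst = corrs.idxmin()
        if corrs[worst] >= threshold:
            break
        if len(retained) == 2:
            # neither of a mutually inconsistent pair can be kept
            dropped.extend((i, float(corrs[i])) for i in retained)
            retained = []
            break
        dropped.append((worst, float(corrs[worst])))
        retained.remove(worst)
    return retained, dropped


def cronbach_alpha(wide: pd.DataFrame) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum item variances / total variance)."""
    wide = wide.dropna()
    k = wide.shape[1]
    if k < 2:
        raise ValueError(f"cronbach_alpha needs >= 2 items, got {k}")
    if len(wide) < 3:
        raise ValueError(f"cronbach_alpha needs >= 3 respondents, got {len(wide)}")
    total_var = wide.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score variance is zero; alpha undefined")
    item_var = wide.var(ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass
class FactorReport:
    """Filtering and reliability outcome for one factor."""

    factor: str
    retained: list[str]
    dropped: list[tuple[str, float]]
    alpha: float | None
    status: str  # 'scored' | 'empty_after_filter' | 'low_alpha'
    notes: list[str] = field(default_factory=list)


def score_factors(
    items: pd.DataFrame,
    assignments: dict[str, list[str]],
    participants: list[str] | None = None,
    threshold: float = 0.2,
    alpha_min: float = 0.6,
    min_present: float = 0.5,
    method: str = "mean",
) -> tuple[pd.DataFrame, dict[str, FactorReport]]:
    """Score each factor as the mean of z-scored retained items.

    ``participants`` restricts the scoring population (z statistics are
    computed within it); None scores everyone.  A participant is scored on
    a factor only if at least ``min_present`` of its retained items are
    observed.  ``method='latent'`` substitutes the first principal component
    (sign-aligned with the mean score); the z-average is canonical.

    Returns a long score table (participant_id, factor, score) and a
    per-factor report of retained/dropped items, alpha, and status.
    """
    if method not in ("mean", "latent"):
        raise ValueError(f"method must be 'mean' or 'latent', got {method!r}")
    if participants is not None:
        items = items[items["participant_id"].isin(participants)]
        if items.empty:
            raise ValueError("no items for the requested scoring population")

    score_frames = []
    reports: dict[str, FactorReport] = {}
    for factor, item_ids in assignments.items():
        retained, dropped = item_total_filter(items, item_ids, threshold=threshold)
        if not retained:
            reports[factor] = FactorReport(factor, retained, dropped, None, "empty_after_filter")
            logger.warning("factor %s: no items survive the item-total filter", factor)
            continue
        wide = pivot_items(items[items["item"].isin(retained)])[retained]
        alpha = cronbach_alpha(wide)
        if alpha < alpha_min:
            reports[factor] = FactorReport(factor, retained, dropped, alpha, "low_alpha")
            logger.warning("factor %s excluded: alpha %.3f < %.2f", factor, alpha, alpha_min)
            continue

        z = (wide - wide.mean()) / wide.std(ddof=1)
        present = z.notna().mean(axis=1)
        score = z.mean(axis=1)
        if method == "latent":
            filled = z.fillna(0.0).to_numpy()
            _, _, vt = np.linalg.svd(filled - filled.mean(axis=0), full_matrices=False)
            pc = filled @ vt[0]
            if np.corrcoef(pc, score.to_numpy())[0, 1] < 0:
                pc = -pc
            score = pd.Series((pc - pc.mean()) / pc.std(ddof=1), index=score.index)
        n_partial = int(((present < 1.0) & (present >= min_present)).sum())
        notes = []
        if n_partial:
            notes.append(f"{n_partial} participants scored on partial items")
            logger.info("factor %s: %d participants scored on partial items", factor, n_partial)
        score = score.where(present >= min_present)
        reports[factor] = FactorReport(factor, retained, dropped, alpha, "scored", notes)
        score_frames.append(
            pd.DataFrame(
                {"participant_id": score.index, "factor": factor, "score": score.to_numpy()}
            )
        )

    scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(columns=["participant_id", "factor", "score"])
    )
    return scores, reports
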