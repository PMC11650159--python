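"""Covariate-adjusted association tests, FDR control, and correlation contrasts.

All regression inputs are standardized before fitting, so reported
coefficients are standardized and invariant to affine rescaling of the raw
variables.  Multiple-testing control across a battery of symptom models
uses Benjamini-Hochberg; specificity of an association to one effort type
uses the Meng-Rosenthal-Rubin z test for two dependent correlations that
share a variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionSpec",
    "fit_spec",
    "fdr_correct",
    "compare_dependent_correlations",
    "run_symptom_battery",
    "run_battery_with_sensitivity",
    "MengResult",
]


@dataclass(frozen=True)
class RegressionSpec:
    """One covariate-adjusted linear model on standardized variables."""

    outcome: str
    predictor: str
    covariates: tuple[str, ...] = ()
    population: str = "all"

    def columns(self) -> list[str]:
        return [self.outcome, self.predictor, *self.covariates]


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance columns cannot be standardized: {zero}")
    return (df - df.mean()) / sd


def fit_spec(spec: RegressionSpec, data: pd.DataFrame) -> dict:
    """OLS of the spec's outcome on predictor + covariates, all z-scored.

    Complete-case: rows with any missing model variable are dropped.
    Returns the standardized coefficient of the predictor with SE, t, p,
    and model R^2 / adjusted R^2.
    """
    cols = spec.columns()
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"data is missing model columns: {missing}")
    df = data[cols].dropna()
    if len(df) <= len(spec.covariates) + 2:
        raise ValueError(
            f"too few complete cases ({len(df)}) for {len(spec.covariates)} covariates"
        )
    z = _standardize(df.astype(float))
    X = sm.add_constant(z[[spec.predictor, *spec.covariates]])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = z[[spec.predictor, *spec.covariates]].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design matrix is rank deficient; most collinear pair: {worst}")
    res = sm.OLS(z[spec.outcome], X).fit()
    return {
        "outcome": spec.outcome,
        "predictor": spec.predictor,
        "population": spec.population,
        "n": int(len(df)),
        "coef": float(res.params[spec.predictor]),
        "se": float(res.bse[spec.predictor]),
        "t": float(res.tvalues[spec.predictor]),
        "p": float(res.pvalues[spec.predictor]),
        "r2": float(res.rsquared),
        "adj_r2": float(res.rsquared_adj),
    }


def fdr_correct(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, reject flags)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if not 1 <= m <= 1000:
        raise ValueError(f"number of p-values must lie in [1, 1000], got {m}")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    # reject all hypotheses up to the largest i with p_(i) <= q * i / m
    thresh = p[order] <= q * np.arange(1, m + 1) / m
    reject = np.zeros(m, dtype=bool)
    if thresh.any():
        k = np.flatnonzero(thresh).max()
        reject[order[: k + 1]] = True
    return adjusted, reject


class MengResult(NamedTuple):
    z: float
    p: float


def compare_dependent_correlations(r1: float, r2: float, r_x: float, n: int) -> MengResult:
    """Meng-Rosenthal-Rubin z for two dependent overlapping correlations.

    ``r1`` and ``r2`` correlate two different variables with a shared third
    on the same n participants; ``r_x`` is the correlation between the two
    non-shared variables.  Two-sided p.
    """
    for name, r in (("r1", r1), ("r2", r2), ("r_x", r_x)):
        if not abs(r) < 1:
            raise ValueError(f"{name} must satisfy |r| < 1, got {r}")
    if n <= 3:
        raise ValueError(f"n must be > 3, got {n}")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    r2bar = (r1**2 + r2**2) / 2.0
    f = min((1.0 - r_x) / (2.0 * (1.0 - r2bar)), 1.0)
    h = (1.0 - f * r2bar) / (1.0 - r2bar)
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 * (1.0 - r_x) * h))
    p = 2.0 * sps.norm.sf(abs(z))
    return MengResult(float(z), float(p))


def run_symptom_battery(
    data: pd.DataFrame,
    outcome: str,
    symptoms: list[str],
    covariates: tuple[str, ...] = (),
    q: float = 0.05,
    population: str = "all",
) -> pd.DataFrame:
    """One covariate-adjusted model per symptom, FDR-corrected across models.

    Symptoms whose column is missing or unusably sparse are skipped with a
    logged reason, shrinking the FDR family accordingly.
    """
    rows, skipped = [], []
    for symptom in symptoms:
        spec = RegressionSpec(outcome, symptom, tuple(covariates), population)
        try:
            rows.append({**fit_spec(spec, data), "symptom": symptom})
        except ValueError as err:
            skipped.append((symptom, str(err)))
            logger.warning("symptom model %s -> %s skipped: %s", symptom, outcome, err)
    if not rows:
        raise ValueError(f"no symptom model could be fitted; skipped: {skipped}")
    table = pd.DataFrame(rows)
    adjusted, reject = fdr_correct(table["p"].to_numpy(), q=q)
    table["p_fdr"] = adjusted
    table["significant_fdr"] = reject
    table.attrs["skipped"] = skipped
    return table


def run_battery_with_sensitivity(
    data: pd.DataFrame,
    outcome: str,
    symptoms: list[str],
    covariates: tuple[str, ...] = (),
    q: float = 0.05,
    group_col: str = "group",
    clinical_group: str = "mdd",
    remitted_col: str = "remitted",
    medication_col: str = "medication",
    anxiety_col: str | None = None,
) -> dict[str, pd.DataFrame]:
    """The symptom battery plus its sensitivity refits.

    Variants: main (clinical group only), current (remitted participants
    excluded), medication (medication flag added as covariate), all
    (every participant), and, when ``anxiety_col`` is given, an
    anxiety-adjusted battery over the remaining symptoms.
    """
    clinical = data[data[group_col] == clinical_group]
    out = {"main": run_symptom_battery(clinical, outcome, symptoms, covariates, q, "mdd")}
    if remitted_col in clinical:
        current = clinical[clinical[remitted_col] == 0]
        out["current"] = run_symptom_battery(current, outcome, symptoms, covariates, q,
                                             "current-mdd")
    if medication_col in clinical:
        out["medication"] = run_symptom_battery(
            clinical, outcome, symptoms, (*covariates, medication_col), q, "mdd"
        )
    out["all"] = run_symptom_battery(data, outcome, symptoms, covariates, q, "all")
    if anxiety_col is not None:
        others = [s for s in symptoms if s != anxiety_col]
        out["anxiety_adjusted"] = run_symptom_battery(
            clinical, outcome, others, (*covariates, anxiety_col), q, "mdd"
        )
    return out
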