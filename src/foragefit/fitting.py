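"""Hierarchical Bayesian estimation of effort costs and exit thresholds.

The model: on each free-choice trial the probability of harvesting is
``logistic(beta * (R_e - rho_condition))`` where the condition threshold is
``rho = (sum rewards - n_travels * c_condition) / T`` and the high-effort
travel cost is parameterized as a marginal increase over the low-effort
cost.  Because ``rho`` is linear in the cost, the likelihood of each
participant is a logistic regression in disguise; posterior sampling uses a
vectorized adaptive Metropolis-within-Gibbs scheme (componentwise random
walk over per-participant parameters, then over group-level parameters).

Group-level structure: independent normal priors for the low-effort costs
and log inverse temperature; a bivariate normal with an LKJ(2) correlation
prior over the two marginal high-effort costs, which exposes the posterior
of the cognitive-physical cost correlation.  An optional group-difference
variant adds a mean-shift parameter per model parameter.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import arviz as az
import numpy as np
import pandas as pd
from scipy import stats

from .environment import EnvironmentConfig
from .io import validate_trial_log
from .model import PARAM_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerSettings",
    "MVTFit",
    "PPCResult",
    "fit_hierarchical",
    "fit_group_difference",
    "posterior_predictive_check",
    "loglik_group_compare",
    "condition_summaries",
]

COND_LABELS = ("cognitive_low", "cognitive_high", "physical_low", "physical_high")
# which conditions each parameter component enters
_COMP_CONDS = {0: (0, 1), 1: (1,), 2: (2, 3), 3: (3,), 4: (0, 1, 2, 3)}
_COST_COMPS = (0, 1, 2, 3)
_PAIR = (1, 3)  # marginal high-effort costs share a bivariate prior


@dataclass(frozen=True)
class SamplerSettings:
    """MCMC settings; defaults follow a 4-chain, 1000+1000 schedule."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    sweeps: int = 3  # participant/group update sweeps per stored draw
    rhat_threshold: float = 1.01
    min_ess: float = 400.0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 1 or self.draws < 1:
            raise ValueError("chains, warmup and draws must all be >= 1")


def condition_summaries(trials: pd.DataFrame, config: EnvironmentConfig) -> pd.DataFrame:
    """Realized per-participant, per-condition totals defining thresholds."""
    validate_trial_log(trials)
    T = config.harvest_periods_per_condition
    rows = []
    for (pid, etype, elevel), grp in trials.groupby(
        ["participant_id", "effort_type", "effort_level"], sort=True
    ):
        harvests = grp[grp["action"] == "harvest"]
        rows.append(
            {
                "participant_id": pid,
                "condition": f"{etype}_{elevel}",
                "total_rewards": float(harvests["reward"].sum()),
                "n_travels": int((grp["action"] == "exit").sum()),
                "harvest_periods": T,
                "n_free_choices": int((~grp["first_harvest"] & (grp["action"] != "missed")).sum()),
            }
        )
    return pd.DataFrame(rows)


class _ChoiceData:
    """Padded per-condition choice arrays for vectorized likelihoods."""

    def __init__(self, trials: pd.DataFrame, config: EnvironmentConfig, min_exits: int):
        validate_trial_log(trials)
        self.config = config
        self.participants = sorted(trials["participant_id"].unique())
        n = len(self.participants)
        pindex = {p: i for i, p in enumerate(self.participants)}
        T = config.harvest_periods_per_condition

        self.re, self.y, self.mask = [], [], []
        self.a = np.zeros((4, n))
        self.b = np.zeros((4, n))
        self.n_exits = np.zeros((4, n), dtype=int)
        self.has_data = np.zeros((4, n), dtype=bool)
        self.include = np.ones((4, n), dtype=bool)

        for c, label in enumerate(COND_LABELS):
            etype, elevel = label.rsplit("_", 1)
            sub = trials[(trials["effort_type"] == etype) & (trials["effort_level"] == elevel)]
            free = sub[~sub["first_harvest"] & (sub["action"] != "missed")]
            counts = free.groupby("participant_id").size()
            m = int(counts.max()) if len(counts) else 0
            re = np.zeros((n, m))
            y = np.zeros((n, m), dtype=bool)
            mask = np.zeros((n, m))
            for pid, grp in free.groupby("participant_id"):
                i = pindex[pid]
                k = len(grp)
                re[i, :k] = grp["expected_reward"].to_numpy()
                y[i, :k] = (grp["action"] == "harvest").to_numpy()
                mask[i, :k] = 1.0
            self.re.append(re)
            self.y.append(y)
            self.mask.append(mask)
            for pid, grp in sub.groupby("participant_id"):
                i = pindex[pid]
                harvests = grp[grp["action"] == "harvest"]
                self.a[c, i] = harvests["reward"].sum() / T
                n_travel = int((grp["action"] == "exit").sum())
                self.b[c, i] = n_travel / T
                self.n_exits[c, i] = n_travel
                self.has_data[c, i] = True

        # too few exits in any condition of an effort type drops the
        # participant from that effort type (their trials leave the
        # likelihood; the cost parameters for that type follow the prior)
        self.excluded: dict[str, list[str]] = {}
        for etype, conds in (("cognitive", (0, 1)), ("physical", (2, 3))):
            bad = np.zeros(n, dtype=bool)
            for c in conds:
                # only conditions the participant actually encountered count
                bad |= self.has_data[c] & (self.n_exits[c] < min_exits)
            for c in conds:
                self.include[c] = ~bad
                self.mask[c] = self.mask[c] * self.include[c][:, None]
            for i in np.flatnonzero(bad):
                pid = self.participants[i]
                self.excluded.setdefault(pid, []).append(
                    f"{etype}: fewer than {min_exits} exits in a condition "
                    f"(exits={[int(self.n_exits[c, i]) for c in conds]})"
                )
        for pid, reasons in self.excluded.items():
            logger.info("participant %s dropped from %s", pid, "; ".join(reasons))

        self.n = n
        self.total_choices = sum(m.sum() for m in self.mask)

    def cond_cost(self, theta: np.ndarray, c: int) -> np.ndarray:
        if c == 0:
            return theta[:, 0]
        if c == 1:
            return theta[:, 0] + theta[:, 1]
        if c == 2:
            return theta[:, 2]
        return theta[:, 2] + theta[:, 3]

    def cond_loglik(self, theta: np.ndarray, c: int) -> np.ndarray:
        """Log likelihood of condition c's choices, per participant."""
        if self.re[c].shape[1] == 0:
            return np.zeros(self.n)
        beta = np.exp(theta[:, 4])
        cost = self.cond_cost(theta, c)
        z = beta[:, None] * (self.re[c] - self.a[c][:, None] + self.b[c][:, None] * cost[:, None])
        ll = np.where(self.y[c], -np.logaddexp(0.0, -z), -np.logaddexp(0.0, z))
        return (ll * self.mask[c]).sum(axis=1)

    def cond_pharvest(self, theta: np.ndarray, c: int) -> np.ndarray:
        beta = np.exp(theta[:, 4])
        cost = self.cond_cost(theta, c)
        z = beta[:, None] * (self.re[c] - self.a[c][:, None] + self.b[c][:, None] * cost[:, None])
        return np.exp(-np.logaddexp(0.0, -z))

    def thresholds(self, theta: np.ndarray, c: int) -> np.ndarray:
        return self.a[c] - self.b[c] * self.cond_cost(theta, c)


# ---------------------------------------------------------------------------
# priors


def _normal_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * math.log(2 * math.pi)


def _bvn_logpdf(x1, x2, m1, m2, s1, s2, r):
    d1 = (x1 - m1) / s1
    d2 = (x2 - m2) / s2
    om = 1.0 - r * r
    q = (d1 * d1 - 2.0 * r * d1 * d2 + d2 * d2) / om
    return -0.5 * q - np.log(2 * math.pi * s1 * s2) - 0.5 * np.log(om)


_HYPER = {
    "mu_cost_sd": 5.0,
    "mu_logbeta_sd": 2.0,
    "sigma_cost_scale": 2.5,
    "sigma_logbeta_scale": 1.0,
    "delta_sd": 10.0,
}

_FLAT_BOUNDS = {k: (-100.0, 100.0) for k in PARAM_NAMES[:4]}
_FLAT_BOUNDS["log_beta"] = (-7.0, 7.0)


class _State:
    """Mutable sampler state for one chain."""

    def __init__(self, data: _ChoiceData, hierarchical: bool, group_mode: bool, g: np.ndarray,
                 fixed: dict[int, float], bounds, rng: np.random.Generator):
        n = data.n
        self.data = data
        self.hierarchical = hierarchical
        self.group_mode = group_mode
        self.g = g
        self.fixed = fixed
        self.bounds = bounds
        self.theta = np.zeros((n, 5))
        self.theta[:, :4] += rng.normal(0, 0.5, size=(n, 4))
        self.theta[:, 4] += rng.normal(0, 0.2, size=n)
        for k, v in fixed.items():
            self.theta[:, k] = v
        self.mu = np.zeros(5)
        self.log_sigma = np.zeros(5)
        self.z_r = 0.0
        self.delta = np.zeros(5)
        self.ll = np.stack([data.cond_loglik(self.theta, c) for c in range(4)])
        # adaptive proposal scales
        self.theta_scale = np.full((n, 5), 1.0)
        self.theta_scale[:, 4] = 0.25
        self.phi_scale = {"mu": np.full(5, 0.5), "log_sigma": np.full(5, 0.3),
                          "z_r": 0.3, "delta": np.full(5, 0.5)}

    # -- priors ----------------------------------------------------------

    def _mean_eff(self) -> np.ndarray:
        m = self.mu[None, :] + self.delta[None, :] * self.g[:, None]
        return m

    def theta_logprior(self, theta: np.ndarray) -> np.ndarray:
        if not self.hierarchical:
            ok = np.ones(len(theta), dtype=bool)
            for k in range(5):
                lo, hi = self.bounds[PARAM_NAMES[k]]
                ok &= (theta[:, k] >= lo) & (theta[:, k] <= hi)
            return np.where(ok, 0.0, -np.inf)
        m = self._mean_eff()
        s = np.exp(self.log_sigma)
        r = math.tanh(self.z_r)
        lp = np.zeros(len(theta))
        for k in (0, 2, 4):
            lp += _normal_logpdf(theta[:, k], m[:, k], s[k])
        lp += _bvn_logpdf(theta[:, 1], theta[:, 3], m[:, 1], m[:, 3], s[1], s[3], r)
        return lp

    def phi_logprior(self) -> float:
        lp = 0.0
        for k in range(5):
            sd = _HYPER["mu_cost_sd"] if k < 4 else _HYPER["mu_logbeta_sd"]
            lp += _normal_logpdf(self.mu[k], 0.0, sd)
            scale = _HYPER["sigma_cost_scale"] if k < 4 else _HYPER["sigma_logbeta_scale"]
            sigma = math.exp(self.log_sigma[k])
            # half-normal on sigma plus the log-sigma Jacobian
            lp += -0.5 * (sigma / scale) ** 2 + self.log_sigma[k]
            if self.group_mode:
                lp += _normal_logpdf(self.delta[k], 0.0, _HYPER["delta_sd"])
        r = math.tanh(self.z_r)
        # LKJ(2) density on r plus the tanh Jacobian
        lp += 2.0 * math.log1p(-r * r)
        return lp


def _run_chain(
    data: _ChoiceData,
    settings: SamplerSettings,
    hierarchical: bool,
    group_mode: bool,
    g: np.ndarray,
    fixed: dict[int, float],
    bounds,
    rng: np.random.Generator,
) -> dict:
    st = _State(data, hierarchical, group_mode, g, fixed, bounds, rng)
    n = data.n
    free_comps = [k for k in range(5) if k not in fixed]
    n_iter = settings.warmup + settings.draws
    adapt_rate = 0.05

    out_theta = np.empty((settings.draws, n, 5))
    out_ll = np.empty((settings.draws, n))
    out_phi = {"mu": np.empty((settings.draws, 5)), "sigma": np.empty((settings.draws, 5)),
               "r": np.empty(settings.draws), "delta": np.empty((settings.draws, 5))}

    for it in range(n_iter):
        adapting = it < settings.warmup
        for _ in range(settings.sweeps):
            # ---- participant-level componentwise random-walk updates ----
            for k in free_comps:
                prop = st.theta.copy()
                prop[:, k] = st.theta[:, k] + st.theta_scale[:, k] * rng.normal(size=n)
                d_lp = st.theta_logprior(prop) - st.theta_logprior(st.theta)
                new_ll = {}
                for c in _COMP_CONDS[k]:
                    new_ll[c] = data.cond_loglik(prop, c)
                    d_lp = d_lp + new_ll[c] - st.ll[c]
                accept = np.log(rng.random(n)) < d_lp
                st.theta[accept, k] = prop[accept, k]
                for c in _COMP_CONDS[k]:
                    st.ll[c][accept] = new_ll[c][accept]
                if adapting:
                    st.theta_scale[:, k] *= np.exp(adapt_rate * (accept - 0.44))

            # ---- group-level updates ----
            if hierarchical:
                cur_prior = st.theta_logprior(st.theta).sum() + st.phi_logprior()
                for name, size in (("mu", 5), ("log_sigma", 5), ("z_r", 1), ("delta", 5)):
                    if name == "delta" and not group_mode:
                        continue
                    for k in range(size):
                        if name != "z_r" and (k in fixed):
                            continue
                        if name == "z_r":
                            old = st.z_r
                            st.z_r = old + st.phi_scale["z_r"] * rng.normal()
                        else:
                            vec = getattr(st, name)
                            old = vec[k]
                            vec[k] = old + st.phi_scale[name][k] * rng.normal()
                        new_prior = st.theta_logprior(st.theta).sum() + st.phi_logprior()
                        if math.log(rng.random()) < new_prior - cur_prior:
                            cur_prior = new_prior
                            acc = 1.0
                        else:
                            if name == "z_r":
                                st.z_r = old
                            else:
                                getattr(st, name)[k] = old
                            acc = 0.0
                        if adapting:
                            if name == "z_r":
                                st.phi_scale["z_r"] *= math.exp(adapt_rate * (acc - 0.44))
                            else:
                                st.phi_scale[name][k] *= math.exp(adapt_rate * (acc - 0.44))

        if not adapting:
            d = it - settings.warmup
            out_theta[d] = st.theta
            out_ll[d] = st.ll.sum(axis=0)
            out_phi["mu"][d] = st.mu
            out_phi["sigma"][d] = np.exp(st.log_sigma)
            out_phi["r"][d] = math.tanh(st.z_r)
            out_phi["delta"][d] = st.delta

    return {"theta": out_theta, "loglik": out_ll, **out_phi}


class MVTFit:
    """Posterior container with summaries, diagnostics, and point estimates."""

    def __init__(self, idata, data, config, settings, hierarchical, group_mode,
                 group_labels=None, groups=None):
        self.idata = idata
        self.data = data
        self.config = config
        self.settings = settings
        self.hierarchical = hierarchical
        self.group_mode = group_mode
        self.group_labels = group_labels
        self.groups = groups
        self.participants = data.participants
        self.excluded = data.excluded
        self.convergence_warnings: list[str] = []
        self._check_convergence()

    # -- diagnostics -----------------------------------------------------

    def rhat(self) -> pd.DataFrame:
        rh = az.rhat(self.idata)
        rows = []
        for var in rh.data_vars:
            vals = np.asarray(rh[var]).ravel()
            rows.append({"parameter": var, "rhat_max": float(np.nanmax(vals))})
        return pd.DataFrame(rows)

    def ess(self) -> pd.DataFrame:
        es = az.ess(self.idata)
        rows = []
        for var in es.data_vars:
            vals = np.asarray(es[var]).ravel()
            rows.append({"parameter": var, "ess_min": float(np.nanmin(vals))})
        return pd.DataFrame(rows)

    def _check_convergence(self) -> None:
        if self.idata.posterior.sizes["chain"] < 2:
            return
        rh = self.rhat()
        bad = rh[rh["rhat_max"] > self.settings.rhat_threshold]
        if len(bad):
            msg = (
                f"R-hat above {self.settings.rhat_threshold} for: "
                + ", ".join(f"{r.parameter} ({r.rhat_max:.3f})" for r in bad.itertuples())
            )
            self.convergence_warnings.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)

    @property
    def converged(self) -> bool:
        return not self.convergence_warnings

    # -- summaries -------------------------------------------------------

    def _post(self, var):
        return self.idata.posterior[var]

    def summary(self, hdi_prob: float = 0.95) -> pd.DataFrame:
        """Per-participant posterior mean/SD/HDI for every parameter."""
        rows = []
        vars_ = list(PARAM_NAMES[:4]) + ["beta"] + [f"threshold_{c}" for c in COND_LABELS]
        for var in vars_:
            da = self._post(var)
            flat = da.stack(sample=("chain", "draw")).transpose("participant", "sample").values
            hdi = az.hdi(da, hdi_prob=hdi_prob)[var].values
            for i, pid in enumerate(self.participants):
                rows.append(
                    {
                        "participant_id": pid,
                        "parameter": var,
                        "mean": float(flat[i].mean()),
                        "sd": float(flat[i].std(ddof=1)),
                        "hdi_lower": float(hdi[i, 0]),
                        "hdi_upper": float(hdi[i, 1]),
                    }
                )
        return pd.DataFrame(rows)

    def group_summary(self) -> dict:
        out = {}
        if self.hierarchical:
            mu = self._post("mu").values.reshape(-1, 5)
            sigma = self._post("sigma").values.reshape(-1, 5)
            out["mu_mean"] = dict(zip(PARAM_NAMES, mu.mean(axis=0)))
            out["sigma_mean"] = dict(zip(PARAM_NAMES, sigma.mean(axis=0)))
            corr_mean, lo, hi = self.cost_correlation()
            out["cost_correlation"] = {"mean": corr_mean, "hdi_lower": lo, "hdi_upper": hi}
        return out

    def cost_correlation(self, hdi_prob: float = 0.95) -> tuple[float, float, float]:
        """Posterior of the cognitive-physical marginal-cost correlation."""
        if not self.hierarchical:
            raise ValueError("cost correlation requires the hierarchical model")
        r = self._post("cost_correlation").values.ravel()
        lo, hi = az.hdi(r, hdi_prob=hdi_prob)
        return float(r.mean()), float(lo), float(hi)

    def group_shift_summary(self, hdi_prob: float = 0.95) -> pd.DataFrame:
        """Posterior group-mean shifts (group-difference variant only)."""
        if not self.group_mode:
            raise ValueError("fit was not run in group-difference mode")
        da = self._post("delta")
        rows = []
        for k, name in enumerate(PARAM_NAMES):
            d = da.sel(param=name).values.ravel()
            lo, hi = az.hdi(d, hdi_prob=hdi_prob)
            rows.append(
                {
                    "parameter": name,
                    "shift_mean": float(d.mean()),
                    "shift_sd": float(d.std(ddof=1)),
                    "hdi_lower": float(lo),
                    "hdi_upper": float(hi),
                    "covers_zero": bool(lo <= 0.0 <= hi),
                }
            )
        return pd.DataFrame(rows)

    def log_posterior_likelihood(self) -> pd.Series:
        """Per-participant posterior mean of the choice log likelihood."""
        ll = self.idata.log_likelihood["choices"]
        vals = ll.mean(dim=("chain", "draw")).values
        return pd.Series(vals, index=self.participants, name="log_posterior_likelihood")

    def point_estimates(self) -> pd.DataFrame:
        """Posterior-mean point estimates, one row per participant.

        Effort-type exclusions show as NaN in that type's cost and
        threshold columns.
        """
        post = self.idata.posterior
        cols = {"participant_id": self.participants}
        for var in list(PARAM_NAMES[:4]) + ["beta"] + [f"threshold_{c}" for c in COND_LABELS]:
            cols[var] = post[var].mean(dim=("chain", "draw")).values
        df = pd.DataFrame(cols)
        for etype, conds in (("cognitive", (0, 1)), ("physical", (2, 3))):
            inc = self.data.include[conds[0]]
            bad = ~inc
            if bad.any():
                df.loc[bad, [f"c_low_{etype}", f"c_high_{etype}"]] = np.nan
                for c in conds:
                    df.loc[bad, f"threshold_{COND_LABELS[c]}"] = np.nan
        df["overall_threshold_low"] = df[["threshold_cognitive_low", "threshold_physical_low"]].mean(
            axis=1
        )
        df = df.merge(
            self.log_posterior_likelihood().rename("log_posterior_likelihood"),
            left_on="participant_id",
            right_index=True,
        )
        return df


def _build_idata(chain_outputs, data: _ChoiceData, hierarchical, group_mode) -> az.InferenceData:
    theta = np.stack([c["theta"] for c in chain_outputs])  # (chain, draw, n, 5)
    ll = np.stack([c["loglik"] for c in chain_outputs])
    posterior = {}
    for k, name in enumerate(PARAM_NAMES[:4]):
        posterior[name] = theta[..., k]
    posterior["log_beta"] = theta[..., 4]
    posterior["beta"] = np.exp(theta[..., 4])
    nc, nd, n, _ = theta.shape
    flat = theta.reshape(-1, n, 5)
    for c, label in enumerate(COND_LABELS):
        th = np.stack([data.thresholds(t, c) for t in flat])
        posterior[f"threshold_{label}"] = th.reshape(nc, nd, n)
    if hierarchical:
        posterior["mu"] = np.stack([c["mu"] for c in chain_outputs])
        posterior["sigma"] = np.stack([c["sigma"] for c in chain_outputs])
        posterior["cost_correlation"] = np.stack([c["r"] for c in chain_outputs])
        if group_mode:
            posterior["delta"] = np.stack([c["delta"] for c in chain_outputs])
    dims = {name: ["participant"] for name in list(PARAM_NAMES[:4]) + ["log_beta", "beta"]}
    dims.update({f"threshold_{c}": ["participant"] for c in COND_LABELS})
    dims.update({"mu": ["param"], "sigma": ["param"], "delta": ["param"]})
    coords = {"participant": data.participants, "param": list(PARAM_NAMES)}
    return az.from_dict(
        posterior=posterior,
        log_likelihood={"choices": ll},
        dims={**dims, "choices": ["participant"]},
        coords=coords,
    )


def fit_hierarchical(
    trials: pd.DataFrame,
    config: EnvironmentConfig,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    prior: str = "hierarchical",
    fixed_params: dict[str, float] | None = None,
    min_exits_per_condition: int = 2,
    flat_bounds: dict[str, tuple[float, float]] | None = None,
    _groups: pd.Series | None = None,
) -> MVTFit:
    """Fit the choice model to a trial log by MCMC.

    ``prior='hierarchical'`` (default) places group-level priors over
    participants; ``prior='flat'`` samples each participant independently
    under bounded flat priors (used for exact small-instance checks).
    ``fixed_params`` pins named parameters (e.g. ``{'log_beta': 0.7}``) at a
    value for every participant.  Participants with fewer than
    ``min_exits_per_condition`` exits in any condition of an effort type are
    dropped from that effort type's likelihood and flagged.
    """
    settings = settings or SamplerSettings()
    if prior not in ("hierarchical", "flat"):
        raise ValueError(f"prior must be 'hierarchical' or 'flat', got {prior!r}")
    hierarchical = prior == "hierarchical"
    fixed_params = fixed_params or {}
    bad_names = set(fixed_params) - set(PARAM_NAMES)
    if bad_names:
        raise ValueError(f"unknown fixed parameters: {sorted(bad_names)}")
    fixed = {PARAM_NAMES.index(k): float(v) for k, v in fixed_params.items()}
    bounds = dict(_FLAT_BOUNDS)
    if flat_bounds:
        bounds.update(flat_bounds)

    data = _ChoiceData(trials, config, min_exits_per_condition)
    group_mode = _groups is not None
    if group_mode:
        labels = sorted(_groups.unique())
        if len(labels) != 2:
            raise ValueError(f"group-difference fit requires exactly 2 groups, got {labels}")
        g = np.array([float(_groups[p] == labels[1]) for p in data.participants])
    else:
        labels = None
        g = np.zeros(data.n)

    ss = np.random.SeedSequence(seed)
    chain_outputs = []
    for child in ss.spawn(settings.chains):
        rng = np.random.default_rng(child)
        chain_outputs.append(
            _run_chain(data, settings, hierarchical, group_mode, g, fixed, bounds, rng)
        )

    idata = _build_idata(chain_outputs, data, hierarchical, group_mode)
    return MVTFit(
        idata,
        data,
        config,
        settings,
        hierarchical,
        group_mode,
        group_labels=labels,
        groups=_groups,
    )


def fit_group_difference(
    trials: pd.DataFrame,
    groups: pd.Series | dict,
    config: EnvironmentConfig,
    settings: SamplerSettings | None = None,
    seed: int = 0,
    **kwargs,
) -> MVTFit:
    """Hierarchical fit with a per-parameter group mean-shift.

    ``groups`` maps participant id to one of exactly two labels; the shift
    applies to the second label in sorted order.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    return fit_hierarchical(
        trials, config, settings=settings, seed=seed, _groups=groups, **kwargs
    )


@dataclass
class PPCResult:
    """Posterior predictive check of the overall harvest rate."""

    observed_rate: float
    replicate_rates: np.ndarray
    pd_lower: float  # P(replicate <= observed)
    pd_upper: float  # P(replicate >= observed)
    exit_threshold_replicates: pd.DataFrame = field(repr=False)
    observed_exit_means: dict = field(default_factory=dict)

    @property
    def pd(self) -> float:
        """Tail probability of the observed rate under replicates."""
        return min(self.pd_lower, self.pd_upper)


def posterior_predictive_check(
    fit: MVTFit,
    trials: pd.DataFrame | None = None,
    n_rep: int = 500,
    rng: np.random.Generator | int = 0,
) -> PPCResult:
    """Simulate replicated choices from posterior draws at the fitted trials.

    The test statistic is the overall harvest rate across participants and
    free trials; per-condition mean expected reward on replicate exit trials
    is returned as well.  By default the observed statistics come from the
    fitted data; passing ``trials`` scores a different log's observed
    statistics against the same replicate distribution (misfit detection).
    """
    if n_rep <= 0:
        raise ValueError(f"n_rep must be > 0, got {n_rep}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    data = fit.data
    post = fit.idata.posterior
    theta = np.stack(
        [post[name].values for name in PARAM_NAMES[:4]] + [post["log_beta"].values], axis=-1
    )  # (chain, draw, n, 5)
    nc, nd = theta.shape[:2]
    flat = theta.reshape(nc * nd, data.n, 5)
    idx = rng.choice(nc * nd, size=n_rep, replace=n_rep > nc * nd)

    total_mask = sum(m.sum() for m in data.mask)
    if trials is None:
        obs_harvests = sum((data.y[c] * data.mask[c]).sum() for c in range(4))
        observed_rate = obs_harvests / total_mask
        obs_exit = {}
        for c, label in enumerate(COND_LABELS):
            m = data.mask[c] > 0
            sel = m & ~data.y[c]
            obs_exit[label] = float(data.re[c][sel].mean()) if sel.any() else float("nan")
    else:
        validate_trial_log(trials)
        free = trials[~trials["first_harvest"] & (trials["action"] != "missed")]
        observed_rate = float((free["action"] == "harvest").mean())
        obs_exit = {}
        for label in COND_LABELS:
            etype, elevel = label.rsplit("_", 1)
            sel = free[
                (free["effort_type"] == etype)
                & (free["effort_level"] == elevel)
                & (free["action"] == "exit")
            ]
            obs_exit[label] = float(sel["expected_reward"].mean()) if len(sel) else float("nan")

    rates = np.empty(n_rep)
    exit_rows = []
    for j, s in enumerate(idx):
        th = flat[s]
        harvests = 0.0
        row = {}
        for c, label in enumerate(COND_LABELS):
            if data.re[c].shape[1] == 0:
                row[label] = float("nan")
                continue
            p = data.cond_pharvest(th, c)
            y_rep = rng.random(p.shape) < p
            m = data.mask[c] > 0
            harvests += (y_rep & m).sum()
            exits = m & ~y_rep
            row[label] = float(data.re[c][exits].mean()) if exits.any() else float("nan")
        rates[j] = harvests / total_mask
        exit_rows.append(row)

    return PPCResult(
        observed_rate=float(observed_rate),
        replicate_rates=rates,
        pd_lower=float((rates <= observed_rate).mean()),
        pd_upper=float((rates >= observed_rate).mean()),
        exit_threshold_replicates=pd.DataFrame(exit_rows),
        observed_exit_means=obs_exit,
    )


class LoglikCompareResult(NamedTuple):
    t: float
    df: float
    p: float


def loglik_group_compare(fit, groups: pd.Series | dict) -> LoglikCompareResult:
    """Welch unpaired t test on per-participant log posterior likelihoods.

    ``fit`` may be an :class:`MVTFit` or a per-participant Series of log
    posterior likelihoods.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    ll = fit if isinstance(fit, pd.Series) else fit.log_posterior_likelihood()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly 2 groups required, got {labels}")
    a = ll[[p for p in ll.index if groups[p] == labels[0]]].to_numpy()
    b = ll[[p for p in ll.index if groups[p] == labels[1]]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 participants")
    res = stats.ttest_ind(a, b, equal_var=False)
    return LoglikCompareResult(float(res.statistic), float(res.df), float(res.pvalue))
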