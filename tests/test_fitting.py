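import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import foragefit as ff
from foragefit.fitting import COND_LABELS, condition_summaries


def _quiet_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ff.fit_hierarchical(*args, **kwargs)


def _quiet_group_fit(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return ff.fit_group_difference(*args, **kwargs)


FAST = ff.SamplerSettings(chains=2, warmup=150, draws=150)


class TestConditionSummaries:
    def test_totals_match_log(self, small_cohort, default_config):
        trials, _, _ = small_cohort
        summ = condition_summaries(trials, default_config)
        pid = summ["participant_id"].iloc[0]
        sub = trials[
            (trials["participant_id"] == pid)
            & (trials["effort_type"] == "cognitive")
            & (trials["effort_level"] == "low")
        ]
        row = summ[(summ["participant_id"] == pid) & (summ["condition"] == "cognitive_low")].iloc[0]
        assert row["total_rewards"] == pytest.approx(
            sub.loc[sub["action"] == "harvest", "reward"].sum()
        )
        assert row["n_travels"] == (sub["action"] == "exit").sum()
        assert row["harvest_periods"] == pytest.approx(280.0)


class TestFitHierarchical:
    def test_posterior_summary_contract(self, recovery_fit):
        summary = recovery_fit.summary()
        assert {"participant_id", "parameter", "mean", "sd", "hdi_lower", "hdi_upper"} <= set(
            summary.columns
        )
        assert (summary["hdi_lower"] <= summary["mean"] + 1e-9).all()
        assert (summary["mean"] <= summary["hdi_upper"] + 1e-9).all()
        # R-hat reported for every sampled parameter family
        rhat = recovery_fit.rhat()
        assert {"c_high_cognitive", "mu", "sigma", "cost_correlation"} <= set(rhat["parameter"])

    def test_point_estimates_are_posterior_means(self, recovery_fit):
        est = recovery_fit.point_estimates()
        post = recovery_fit.idata.posterior["c_high_cognitive"]
        np.testing.assert_allclose(
            est["c_high_cognitive"].to_numpy(), post.mean(dim=("chain", "draw")).values
        )

    def test_threshold_cost_rank_link(self, default_config):
        # larger fitted marginal cost <-> larger low-minus-high threshold
        # gap; isolated by holding the other generative parameters fixed
        gp = {
            "mdd": ff.GroupParams(sds={"c_low_cognitive": 0.0, "c_low_physical": 0.0,
                                       "log_beta": 0.0, "c_high_cognitive": 18.0}),
            "comparison": ff.GroupParams(),
        }
        trials, _, _ = ff.simulate_cohort(24, 1, gp, default_config, 314)
        fit = _quiet_fit(trials, default_config, ff.SamplerSettings(chains=2, warmup=250,
                                                                    draws=250), seed=7)
        est = fit.point_estimates()
        est = est[est["participant_id"].str.startswith("mdd")]
        gap = est["threshold_cognitive_low"] - est["threshold_cognitive_high"]
        rho = sps.spearmanr(est["c_high_cognitive"], gap).statistic
        assert rho >= 0.9

    def test_deterministic_limit_recovers_fixed_point_thresholds(self, default_config):
        # near-deterministic generator: fitted thresholds within 0.2 apples
        params = ff.MVTParams(2.0, 4.0, 1.0, 6.0, inverse_temperature=50.0)
        agent = ff.AgentSpec(params)
        truth = ff.resolve_thresholds(agent, default_config)
        logs = [
            ff.simulate_participant(agent, default_config, 500 + i, participant_id=f"p{i}")
            for i in range(6)
        ]
        trials = pd.concat(logs, ignore_index=True)
        fit = _quiet_fit(trials, default_config, FAST, seed=8)
        est = fit.point_estimates()
        for cond in COND_LABELS:
            np.testing.assert_allclose(
                est[f"threshold_{cond}"], truth[cond], atol=0.2
            )

    def test_few_exit_participants_dropped_per_effort_type(self, default_config):
        # an agent that practically never leaves cognitive patches
        sticky = ff.AgentSpec(
            ff.MVTParams(2.0, 3.0, 2.0, 3.0, inverse_temperature=5.0),
            threshold_mode="fixed",
            fixed_thresholds={
                "cognitive_low": -2.0,
                "cognitive_high": -2.0,
                "physical_low": 4.5,
                "physical_high": 4.2,
            },
        )
        normal = ff.AgentSpec(ff.MVTParams(2.0, 3.0, 2.0, 3.0, inverse_temperature=2.0))
        logs = [ff.simulate_participant(sticky, default_config, 1, participant_id="sticky")]
        logs += [
            ff.simulate_participant(normal, default_config, 10 + i, participant_id=f"n{i}")
            for i in range(3)
        ]
        trials = pd.concat(logs, ignore_index=True)
        fit = _quiet_fit(trials, default_config, FAST, seed=9)
        assert "sticky" in fit.excluded
        assert any("cognitive" in r for r in fit.excluded["sticky"])
        est = fit.point_estimates().set_index("participant_id")
        assert np.isnan(est.loc["sticky", "c_high_cognitive"])
        assert not np.isnan(est.loc["sticky", "c_high_physical"])

    def test_invalid_prior_and_fixed_params_rejected(self, small_cohort, default_config):
        trials, _, _ = small_cohort
        with pytest.raises(ValueError, match="prior"):
            ff.fit_hierarchical(trials, default_config, FAST, prior="informative")
        with pytest.raises(ValueError, match="fixed"):
            ff.fit_hierarchical(trials, default_config, FAST, fixed_params={"bogus": 1.0})

    def test_cost_correlation_hdi_covers_zero_across_replicates(self, default_config):
        # generator has independent cognitive/physical costs; the posterior
        # correlation HDI should cover 0 in >= 90% of replicate fits
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        covered = 0
        n_rep = 10
        for rep in range(n_rep):
            trials, _, _ = ff.simulate_cohort(
                6, 1, gp, default_config.with_overrides(n_blocks_per_condition=1), 3000 + rep
            )
            fit = _quiet_fit(
                trials,
                default_config.with_overrides(n_blocks_per_condition=1),
                ff.SamplerSettings(chains=2, warmup=120, draws=120),
                seed=rep,
            )
            _, lo, hi = fit.cost_correlation()
            covered += lo <= 0.0 <= hi
        assert covered >= 0.9 * n_rep


class TestGroupDifference:
    def test_single_group_rejected(self, small_cohort, default_config):
        trials, _, parts = small_cohort
        groups = pd.Series("mdd", index=parts["participant_id"])
        with pytest.raises(ValueError, match="2 groups"):
            ff.fit_group_difference(trials, groups, default_config, FAST)

    def test_planted_shift_recovered(self, default_config):
        gp = {
            "mdd": ff.GroupParams(means={"c_high_physical": 12.0}),
            "comparison": ff.GroupParams(means={"c_high_physical": 3.0}),
        }
        trials, _, parts = ff.simulate_cohort(10, 10, gp, default_config, 77)
        groups = parts.set_index("participant_id")["group"]
        fit = _quiet_group_fit(trials, groups, default_config,
                               ff.SamplerSettings(chains=2, warmup=250, draws=250), seed=5)
        shifts = fit.group_shift_summary().set_index("parameter")
        # reference group is alphabetically first ('comparison'); mdd is +9
        est = shifts.loc["c_high_physical", "shift_mean"]
        assert abs(est - 9.0) <= 4.5  # within 50% of the planted shift

    def test_permuted_labels_center_near_zero(self, default_config):
        gp = {
            "mdd": ff.GroupParams(means={"c_high_physical": 12.0}),
            "comparison": ff.GroupParams(means={"c_high_physical": 3.0}),
        }
        trials, _, parts = ff.simulate_cohort(10, 10, gp, default_config, 78)
        rng = np.random.default_rng(0)
        permuted = pd.Series(
            rng.permutation(parts["group"].to_numpy()), index=parts["participant_id"]
        )
        fit = _quiet_group_fit(trials, permuted, default_config, FAST, seed=6)
        shifts = fit.group_shift_summary().set_index("parameter")
        assert abs(shifts.loc["c_high_physical", "shift_mean"]) < 4.0
        assert shifts.loc["c_high_physical", "covers_zero"]


class TestPosteriorPredictiveCheck:
    @pytest.fixture(scope="class")
    def ppc_fit(self, small_cohort, default_config):
        trials, _, _ = small_cohort
        return _quiet_fit(trials, default_config, FAST, seed=10)

    def test_model_generated_data_inside_replicates(self, ppc_fit):
        ppc = ff.posterior_predictive_check(ppc_fit, n_rep=300, rng=1)
        lo, hi = np.quantile(ppc.replicate_rates, [0.025, 0.975])
        assert lo <= ppc.observed_rate <= hi
        assert ppc.pd > 0.025

    def test_random_exit_data_detected_as_misfit(self, ppc_fit, small_cohort, rng):
        trials, _, _ = small_cohort
        corrupted = trials.copy()
        free = ~corrupted["first_harvest"] & (corrupted["action"] != "missed")
        flips = free & (rng.random(len(corrupted)) < 0.5)
        corrupted.loc[flips, "action"] = "exit"
        ppc = ff.posterior_predictive_check(ppc_fit, trials=corrupted, n_rep=300, rng=2)
        assert ppc.observed_rate < ppc.replicate_rates.min()
        assert ppc.pd == 0.0

    def test_zero_replicates_rejected(self, ppc_fit):
        with pytest.raises(ValueError, match="n_rep"):
            ff.posterior_predictive_check(ppc_fit, n_rep=0)

    def test_exit_threshold_replicates_reported(self, ppc_fit):
        ppc = ff.posterior_predictive_check(ppc_fit, n_rep=50, rng=3)
        assert set(ppc.exit_threshold_replicates.columns) == set(COND_LABELS)
        assert len(ppc.exit_threshold_replicates) == 50


class TestLoglikGroupCompare:
    def test_welch_df_non_integer_and_shift_detected(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.normal(-100, 3, size=20), index=[f"a{i}" for i in range(20)])
        b = pd.Series(rng.normal(-100, 3, size=20) + 5.0, index=[f"b{i}" for i in range(20)])
        ll = pd.concat([a, b])
        groups = pd.Series(["x"] * 20 + ["y"] * 20, index=ll.index)
        res = ff.loglik_group_compare(ll, groups)
        assert res.p < 0.05
        assert res.df != int(res.df)  # Welch df is fractional

    def test_null_p_uniform_over_replicates(self):
        rng = np.random.default_rng(5)
        pvals = []
        idx = [f"p{i}" for i in range(30)]
        groups = pd.Series(["x"] * 15 + ["y"] * 15, index=idx)
        for _ in range(300):
            ll = pd.Series(rng.normal(-100, 5, size=30), index=idx)
            pvals.append(ff.loglik_group_compare(ll, groups).p)
        assert sps.kstest(pvals, "uniform").pvalue > 0.01

    def test_tiny_group_rejected(self):
        ll = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        groups = pd.Series(["x", "x", "y"], index=ll.index)
        with pytest.raises(ValueError, match="at least 2"):
            ff.loglik_group_compare(ll, groups)
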