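import numpy as np
import pandas as pd
import pytest

import foragefit as ff
from foragefit.io import TRIAL_LOG_COLUMNS


def _agent(beta=2.0, **costs):
    defaults = dict(c_low_cognitive=2.0, c_high_cognitive=3.0,
                    c_low_physical=2.0, c_high_physical=3.0)
    defaults.update(costs)
    return ff.AgentSpec(ff.MVTParams(**defaults, inverse_temperature=beta))


class TestSimulateParticipant:
    def test_log_is_schema_complete(self, default_config):
        log = ff.simulate_participant(_agent(), default_config, 0)
        assert list(log.columns) == TRIAL_LOG_COLUMNS
        assert set(log["action"]) <= {"harvest", "exit"}
        assert log["first_harvest"].any()
        # every block of every condition appears
        assert log.groupby(["effort_type", "effort_level"])["block"].nunique().eq(2).all()

    def test_same_seed_identical_log(self, default_config):
        a = ff.simulate_participant(_agent(), default_config, 42)
        b = ff.simulate_participant(_agent(), default_config, 42)
        pd.testing.assert_frame_equal(a, b)

    def test_block_time_never_exceeds_duration_plus_one_trial(self, default_config):
        log = ff.simulate_participant(_agent(), default_config, 5)
        max_trial = max(default_config.harvest_duration, default_config.travel_duration)
        for _, block in log.groupby("block"):
            assert block["time"].max() < default_config.block_duration
            assert block["time"].max() + max_trial <= default_config.block_duration + max_trial

    def test_deterministic_limit_exits_at_threshold(self, default_config):
        # near-deterministic agent: never exits while R_e > rho, and the
        # exit trial's expected reward is within one decay step of rho
        agent = _agent(beta=200.0)
        thresholds = ff.resolve_thresholds(agent, default_config)
        log = ff.simulate_participant(agent, default_config, 7)
        kappa = default_config.decay_mean
        for (etype, elevel), grp in log.groupby(["effort_type", "effort_level"]):
            rho = thresholds[f"{etype}_{elevel}"]
            exits = grp[grp["action"] == "exit"]
            assert len(exits) > 0
            # exits happen exactly at the first crossing below rho ...
            assert (exits["expected_reward"] < rho + 1e-9).all()
            harvests = grp[~grp["first_harvest"] & (grp["action"] == "harvest")]
            assert (harvests["expected_reward"] >= rho - 1e-9).all()
            # ... i.e. within one realized decay step of the last super-
            # threshold expectation: R_e(exit) = kappa * obtained(prev)
            np.testing.assert_allclose(
                exits["expected_reward"], exits["last_reward"] * kappa
            )

    def test_zero_beta_harvests_half_the_time(self, default_config):
        agent = ff.AgentSpec(ff.MVTParams(inverse_temperature=0.0))
        log = ff.simulate_participant(agent, default_config, 11)
        free = log[~log["first_harvest"]]
        rate = (free["action"] == "harvest").mean()
        assert abs(rate - 0.5) < 0.05

    def test_missed_rate_emits_missed_trials(self, default_config):
        agent = ff.AgentSpec(ff.MVTParams(inverse_temperature=2.0), missed_rate=0.3)
        log = ff.simulate_participant(agent, default_config, 3)
        frac = (log["action"] == "missed").mean()
        assert 0.1 < frac < 0.5

    def test_nonfinite_threshold_rejected(self, default_config):
        agent = ff.AgentSpec(
            ff.MVTParams(inverse_temperature=2.0),
            threshold_mode="fixed",
            fixed_thresholds={c.label: np.nan for c in default_config.conditions},
        )
        with pytest.raises(ValueError, match="threshold"):
            ff.simulate_participant(agent, default_config, 0)

    def test_expected_reward_consistency(self, default_config):
        log = ff.simulate_participant(_agent(), default_config, 13)
        free = log[~log["first_harvest"]]
        np.testing.assert_allclose(
            free["expected_reward"],
            free["last_reward"] * default_config.decay_mean,
        )

    def test_higher_marginal_cost_lowers_high_effort_exit_threshold(self, default_config):
        # >= 50 simulated block pairs per agent
        def mean_exit(agent, seed):
            vals = []
            for s in range(25):  # 25 sessions x 2 high-effort cognitive blocks
                log = ff.simulate_participant(agent, default_config, seed + s)
                exits = log[(log["action"] == "exit") & (log["effort_type"] == "cognitive")
                            & (log["effort_level"] == "high")]
                vals.append(exits["expected_reward"].mean())
            return np.mean(vals)

        cheap = _agent(c_high_cognitive=0.0)
        costly = _agent(c_high_cognitive=15.0)
        assert mean_exit(costly, 100) < mean_exit(cheap, 100)

    def test_threshold_gap_monotone_in_marginal_cost(self, default_config):
        gaps = []
        for c_high in (-5.0, 0.0, 5.0, 10.0, 15.0):
            agent = _agent(c_high_cognitive=c_high)
            th = ff.resolve_thresholds(agent, default_config)
            gaps.append(th["cognitive_high"] - th["cognitive_low"])
        assert all(a > b for a, b in zip(gaps, gaps[1:]))


class TestSimulateCohort:
    def test_shapes_and_determinism(self, default_config):
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        t1, truth1, p1 = ff.simulate_cohort(3, 2, gp, default_config, 99)
        t2, truth2, p2 = ff.simulate_cohort(3, 2, gp, default_config, 99)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(truth1, truth2)
        pd.testing.assert_frame_equal(p1, p2)
        assert truth1["group"].value_counts().to_dict() == {"mdd": 3, "comparison": 2}
        assert {"latent_anxiety", "true_threshold_cognitive_low", "beta"} <= set(truth1.columns)

    def test_invalid_sizes_rejected(self, default_config):
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        with pytest.raises(ValueError, match="group sizes"):
            ff.simulate_cohort(0, 2, gp, default_config, 0)

    def test_zero_coupling_gives_null_slope(self, default_config):
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        _, truth, _ = ff.simulate_cohort(150, 1, gp, default_config.with_overrides(
            n_blocks_per_condition=0), 5)
        mdd = truth[truth["group"] == "mdd"]
        slope = np.polyfit(mdd["latent_anxiety"], mdd["c_high_cognitive"], 1)[0]
        assert abs(slope) < 2.5  # ~2 SE at n=150, cost SD 9

    def test_coupling_shifts_true_costs(self, default_config):
        coupled = ff.GroupParams(coupling={("c_high_physical", "anhedonia"): 6.0})
        gp = {"mdd": coupled, "comparison": ff.GroupParams()}
        _, truth, _ = ff.simulate_cohort(150, 1, gp, default_config.with_overrides(
            n_blocks_per_condition=0), 6)
        mdd = truth[truth["group"] == "mdd"]
        r = mdd["latent_anhedonia"].corr(mdd["c_high_physical"])
        assert r > 0.3


class TestGenerateSymptomItems:
    def test_noise_free_items_equal_latent(self, default_config):
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        _, truth, _ = ff.simulate_cohort(10, 5, gp, default_config.with_overrides(
            n_blocks_per_condition=0), 8)
        items = ff.generate_symptom_items(
            truth, ff.SymptomGenConfig(items_per_factor=2, loading=1.0, noise_sd=0.0), 0
        )
        wide = items.pivot_table(index="participant_id", columns="item", values="value")
        merged = wide.join(truth.set_index("participant_id"))
        np.testing.assert_allclose(merged["anxiety_item0"], merged["latent_anxiety"])

    def test_two_item_alpha_matches_spearman_brown(self, default_config):
        # loading 0.8, noise 0.6: implied inter-item r = l^2/(l^2 + s^2)
        loading, noise = 0.8, 0.6
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        _, truth, _ = ff.simulate_cohort(2500, 1, gp, default_config.with_overrides(
            n_blocks_per_condition=0), 9)
        items = ff.generate_symptom_items(
            truth, ff.SymptomGenConfig(items_per_factor=2, loading=loading, noise_sd=noise), 1
        )
        wide = items.pivot_table(index="participant_id", columns="item", values="value")
        pair = wide[["anxiety_item0", "anxiety_item1"]]
        alpha = ff.cronbach_alpha(pair)
        r = loading**2 / (loading**2 + noise**2)
        assert alpha == pytest.approx(2 * r / (1 + r), abs=0.05)

    def test_bad_items_removed_downstream_with_high_probability(self, default_config):
        gp = {"mdd": ff.GroupParams(), "comparison": ff.GroupParams()}
        env = default_config.with_overrides(n_blocks_per_condition=0)
        removed = 0
        n_rep = 40
        for rep in range(n_rep):
            _, truth, _ = ff.simulate_cohort(40, 1, gp, env, 1000 + rep)
            items = ff.generate_symptom_items(
                truth,
                ff.SymptomGenConfig(items_per_factor=5, loading=0.8, noise_sd=0.4, n_bad_items=1),
                rep,
            )
            ids = sorted(items.loc[items["instrument"] == "synth_anxiety", "item"].unique())
            retained, dropped = ff.item_total_filter(items, ids)
            if "anxiety_bad0" in {d[0] for d in dropped}:
                removed += 1
        assert removed >= 0.9 * n_rep

    def test_config_validation(self):
        with pytest.raises(ValueError, match="items_per_factor"):
            ff.SymptomGenConfig(items_per_factor=1)
        with pytest.raises(ValueError, match="loading"):
            ff.SymptomGenConfig(loading=1.4)
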