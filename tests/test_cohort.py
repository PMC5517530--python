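"""Synthetic cohort: choice policies, structure, determinism, neural model."""

import numpy as np
import pandas as pd
import pytest

from voiredist import (
    AffectGenParams,
    AgentPolicy,
    CohortConfig,
    Condition,
    NeuralGenParams,
    RULES,
    Rule,
    choice_distribution,
    generate_cohort,
    generate_neural,
    session_attitude_table,
)
from voiredist.cohort import DEFAULT_POLICY_MIXTURE


def rule_prob(probs, rule):
    return probs[RULES.index(rule)]


class TestChoiceDistribution:
    def test_probabilities_normalised(self, scheme):
        for _, policy in DEFAULT_POLICY_MIXTURE:
            for cond in Condition:
                p = choice_distribution(policy, cond, scheme)
                assert p.sum() == pytest.approx(1.0)
                assert (p >= 0).all()

    def test_selfish_high_prefers_inequality_at_low_temperature(self, scheme):
        policy = AgentPolicy(w_self=1.0, temperature=1e-6)
        p = choice_distribution(policy, Condition.HIGH, scheme)
        assert rule_prob(p, Rule.INEQUALITY) > 0.999

    def test_maximin_behind_voi_prefers_equality(self, scheme):
        # worst-off payoffs are 700 / 1000 / 1300: equality maximises the min
        policy = AgentPolicy(w_self=1.0, risk="maximin", temperature=1e-6)
        p = choice_distribution(policy, Condition.VOI, scheme)
        assert rule_prob(p, Rule.EQUALITY) > 0.999

    def test_expected_value_behind_voi_prefers_inequality(self, scheme):
        # per-capita expected payoffs 4100/3 > 4000/3 > 3900/3
        policy = AgentPolicy(w_self=1.0, risk="expected_value", temperature=1e-6)
        p = choice_distribution(policy, Condition.VOI, scheme)
        assert rule_prob(p, Rule.INEQUALITY) > 0.999

    def test_tremble_mixes_towards_uniform(self, scheme):
        sharp = AgentPolicy(w_self=1.0, temperature=1e-6, tremble=0.3)
        p = choice_distribution(sharp, Condition.HIGH, scheme)
        assert rule_prob(p, Rule.EQUALITY) == pytest.approx(0.1)

    def test_invalid_policy_parameters_rejected(self):
        with pytest.raises(ValueError):
            AgentPolicy(temperature=0.0)
        with pytest.raises(ValueError):
            AgentPolicy(risk="risk_neutral")


class TestCohortStructure:
    def test_dimensions(self, default_dataset):
        dec = default_dataset.decisions
        assert dec["participant_id"].nunique() == 33
        assert dec.groupby("participant_id")["session_id"].nunique().eq(4).all()
        per_session = dec.groupby(["participant_id", "session_id"]).size()
        assert per_session.eq(24).all()  # 18 decisions + 6 lotteries

    def test_structural_coverage(self, default_dataset):
        """Outside self-dictator rounds every (class, societal outcome) pair
        is experienced in every session."""
        dec = default_dataset.decisions
        scheduled = dec.loc[(~dec["is_lottery"]) & (dec["decider"] != "self_dictator")]
        cover = scheduled.groupby(["participant_id", "session_id"]).apply(
            lambda g: g.groupby(["assigned_class", "society_rule"]).size().ge(1).sum(),
            include_groups=False,
        )
        assert cover.eq(9).all()

    def test_income_bookkeeping(self, default_dataset):
        totals = default_dataset.decisions.groupby(
            ["participant_id", "session_id"]
        )["payoff"].sum()
        inc = default_dataset.incomes.set_index(["participant_id", "session_id"])
        assert np.allclose(totals, inc.loc[totals.index, "participant_total"])

    def test_payoffs_follow_society_rule(self, default_dataset, scheme):
        from voiredist import payoff

        dec = default_dataset.decisions
        rounds = dec.loc[~dec["is_lottery"]]
        expected = [
            payoff(scheme, Rule(r), c)
            for r, c in zip(rounds["society_rule"], rounds["assigned_class"])
        ]
        assert np.allclose(rounds["payoff"], expected)

    def test_voi_condition_hides_class(self, default_dataset):
        dec = default_dataset.decisions
        voi = dec.loc[dec["info_type"] == "voi"]
        assert (voi["condition"] == "voi").all()
        informed = dec.loc[(dec["info_type"] == "informed") & (~dec["is_lottery"])]
        assert (informed["condition"] == informed["assigned_class"]).all()

    def test_dictator_fraction(self, default_dataset):
        dec = default_dataset.decisions
        dic = dec.loc[(dec["session_type"] == "dictatorship") & (~dec["is_lottery"])]
        frac = (
            dic.groupby(["participant_id", "session_id"])["decider"]
            .apply(lambda s: (s == "self_dictator").mean())
        )
        assert np.allclose(frac, 1 / 3)

    def test_ratings_in_range(self, default_dataset):
        aff = default_dataset.affect
        for col in ("rating_i", "rating_ii", "rating_iii"):
            assert aff[col].between(0, 100).all()

    def test_determinism(self):
        cfg = CohortConfig(n_participants=5, seed=42)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        for name in ("decisions", "affect", "incomes", "neural"):
            assert getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(
                index=False
            )

    def test_rounds_not_multiple_of_nine_rejected(self):
        with pytest.raises(ValueError, match="multiple of 9"):
            CohortConfig(rounds_per_session=10)

    def test_mixture_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortConfig(policy_mixture=((0.5, AgentPolicy()),))


class TestCalibration:
    def test_voi_nonequality_share_in_sanity_band(self):
        """Mean VoI non-equality share over seeds stays within +/-10
        percentage points of the reference 72.3% level."""
        shares = []
        for seed in range(20):
            cfg = CohortConfig(n_participants=33, seed=seed)
            ds = generate_cohort(cfg)
            voi = ds.decisions.loc[
                (ds.decisions["condition"] == "voi") & (~ds.decisions["is_lottery"])
            ]
            shares.append((voi["chosen_rule"] != "equality").mean())
        assert abs(np.mean(shares) - 0.723) < 0.10


class TestNeuralModel:
    def _attitudes(self, dataset):
        return session_attitude_table(dataset.affect, dataset.incomes)

    def test_null_model_cell_means_near_zero(self, small_dataset):
        params = NeuralGenParams(
            mu=0.0,
            equality_effect=0.0,
            voi_effect=0.0,
            interaction_effect=0.0,
            attitude_effect=0.0,
            income_slope=0.0,
            random_effect_sd=0.0,
            noise_sd=1.0,
        )
        rng = np.random.default_rng(0)
        neural = generate_neural(
            small_dataset.decisions, self._attitudes(small_dataset), params, rng
        )
        cells = neural.groupby(["condition", "chosen_rule"])["signal"].agg(["mean", "size"])
        for _, row in cells.iterrows():
            assert abs(row["mean"]) <= 4.0 / np.sqrt(row["size"])

    def test_interaction_contrast_exact_without_noise(self, small_dataset):
        """With noise off, the VoI equality-vs-non-equality contrast equals
        the equality effect plus the interaction coefficient exactly."""
        a, c = 0.3, 1.0
        params = NeuralGenParams(
            mu=0.1,
            equality_effect=a,
            voi_effect=-0.2,
            interaction_effect=c,
            attitude_effect=0.0,
            income_slope=0.0,
            random_effect_sd=0.0,
            noise_sd=0.0,
        )
        rng = np.random.default_rng(0)
        neural = generate_neural(
            small_dataset.decisions, self._attitudes(small_dataset), params, rng
        )
        voi = neural.loc[neural["condition"] == "voi"]
        eq = voi.loc[voi["chosen_rule"] == "equality", "signal"].mean()
        non_eq = voi.loc[voi["chosen_rule"] != "equality", "signal"].mean()
        assert eq - non_eq == pytest.approx(a + c)

    def test_negative_income_slope_induces_negative_correlation(self, small_dataset):
        params = NeuralGenParams(
            mu=0.0,
            equality_effect=0.0,
            voi_effect=0.0,
            interaction_effect=0.0,
            attitude_effect=0.0,
            income_slope=-1.0,
            random_effect_sd=0.0,
            noise_sd=0.0,
        )
        rng = np.random.default_rng(0)
        att = self._attitudes(small_dataset)
        neural = generate_neural(small_dataset.decisions, att, params, rng)
        merged = neural.merge(att, on=["participant_id", "session_id"])
        voi_eq = merged.loc[
            (merged["condition"] == "voi") & (merged["chosen_rule"] == "equality")
        ]
        r = np.corrcoef(voi_eq["relative_income"], voi_eq["signal"])[0, 1]
        assert r < 0

    def test_missing_attitude_raises(self, small_dataset):
        att = self._attitudes(small_dataset).iloc[:2]
        with pytest.raises(ValueError, match="missing attitude"):
            generate_neural(
                small_dataset.decisions, att, NeuralGenParams(), np.random.default_rng(0)
            )

    def test_one_outcome_per_non_lottery_trial(self, small_dataset):
        n_trials = (~small_dataset.decisions["is_lottery"]).sum()
        assert len(small_dataset.neural) == n_trials
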