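"""Behavioural summaries, test statistics vs textbook oracles, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from voiredist import (
    chi2_2x2,
    choice_proportion_summary,
    cluster_bootstrap,
    ever_chose_summary,
    pearson_r,
    two_sample_t_test,
)


def simple_decisions(choices_by_pid, condition="voi"):
    rows = []
    for pid, choices in choices_by_pid.items():
        for k, rule in enumerate(choices):
            rows.append(
                dict(
                    participant_id=pid,
                    condition=condition,
                    chosen_rule=rule,
                    is_lottery=False,
                )
            )
    return pd.DataFrame(rows)


class TestChoiceSummaries:
    def test_single_participant_proportion(self):
        dec = simple_decisions({"p1": ["equality"] * 3 + ["inequality"] * 6})
        s = choice_proportion_summary(dec, "voi", ["equality"])
        assert s.mean == pytest.approx(1 / 3)
        assert s.n == 1

    def test_all_selfish_mean_one_sem_zero(self):
        dec = simple_decisions(
            {f"p{i}": ["inequality"] * 4 for i in range(5)}, condition="high"
        )
        s = choice_proportion_summary(dec, "high", "non_equality_selfish")
        assert s.mean == 1.0 and s.sem == 0.0

    def test_partition_complement(self, default_dataset):
        dec = default_dataset.decisions
        for cond in ("voi", "high", "low"):
            a = choice_proportion_summary(dec, cond, "equality_selfless")
            b = choice_proportion_summary(dec, cond, "non_equality_selfish")
            assert a.mean + b.mean == pytest.approx(1.0)
            per = a.per_participant + b.per_participant
            assert np.allclose(per, 1.0)

    def test_lottery_rounds_excluded(self, default_dataset):
        dec = default_dataset.decisions
        s = choice_proportion_summary(dec, "voi", ["equality"])
        voi = dec.loc[(dec["condition"] == "voi") & (~dec["is_lottery"])]
        direct = (
            voi.groupby("participant_id")["chosen_rule"]
            .apply(lambda x: (x == "equality").mean())
            .mean()
        )
        assert s.mean == pytest.approx(direct)

    def test_ever_chose_extremes(self):
        dec = simple_decisions(
            {"p1": ["equality", "inequality"], "p2": ["equality"] * 2}
        )
        s = ever_chose_summary(dec, "voi", ["equality"])
        assert s.mean == 1.0
        none = ever_chose_summary(dec, "voi", ["intermediate"])
        assert none.mean == 0.0

    def test_ever_chose_matches_enumeration(self, default_dataset):
        dec = default_dataset.decisions
        s = ever_chose_summary(dec, "high", "equality_selfless")
        voi = dec.loc[(dec["condition"] == "high") & (~dec["is_lottery"])]
        direct = voi.groupby("participant_id")["chosen_rule"].apply(
            lambda x: x.isin(["intermediate", "equality"]).any()
        )
        assert s.mean == pytest.approx(direct.mean())
        p, n = s.mean, s.n
        assert s.sem == pytest.approx(np.sqrt(p * (1 - p) / n))

    def test_participants_without_trials_are_dropped(self, caplog):
        dec = simple_decisions({"p1": ["equality"]})
        other = simple_decisions({"p2": ["equality"]}, condition="high")
        both = pd.concat([dec, other], ignore_index=True)
        with caplog.at_level("WARNING"):
            s = choice_proportion_summary(both, "voi", ["equality"])
        assert s.n == 1
        assert "dropped" in caplog.text


class TestTTest:
    def test_identical_samples(self):
        t, p = two_sample_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_clear_separation(self):
        a = [0.0, 0.001, -0.001, 0.0005]
        b = [1.0, 1.001, 0.999, 1.0005]
        _, p = two_sample_t_test(a, b)
        assert p < 1e-6

    def test_welch_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 2, 9)
        t, p = two_sample_t_test(a, b)
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert t == pytest.approx(t_hand)
        from scipy import stats

        df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))

    def test_pooled_variant_available(self):
        a, b = [1.0, 2, 3, 4], [2.0, 3, 4, 5, 6]
        t_w, _ = two_sample_t_test(a, b, equal_var=False)
        t_p, _ = two_sample_t_test(a, b, equal_var=True)
        assert t_w != t_p  # unbalanced unequal-variance design

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t_test([1.0], [1.0, 2.0])


class TestChi2:
    def test_uncorrected_matches_hand_formula(self):
        # N(ad - bc)^2 / (row and column products)
        a, b, c, d = 6, 13, 2, 29
        n = a + b + c + d
        hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        stat, p = chi2_2x2([[6, 13], [2, 29]], correction=False)
        assert stat == pytest.approx(hand)
        assert stat == pytest.approx(5.534, abs=1e-3)

    def test_yates_correction_shrinks_statistic(self):
        stat_u, _ = chi2_2x2([[6, 13], [2, 29]], correction=False)
        stat_c, _ = chi2_2x2([[6, 13], [2, 29]], correction=True)
        assert stat_c < stat_u

    def test_balanced_table_is_null(self):
        stat, p = chi2_2x2([[5, 5], [5, 5]])
        assert stat == 0.0 and p == 1.0

    def test_proportional_rows_independent(self):
        stat, _ = chi2_2x2([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi2_2x2([[0, 0], [5, 5]])


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_independent_large_n_small_r(self):
        rng = np.random.default_rng(0)
        r, _ = pearson_r(rng.normal(size=5000), rng.normal(size=5000))
        assert abs(r) < 0.05

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=40), rng.normal(size=40)
        r, _ = pearson_r(x, y)
        hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(hand)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def cluster_frame(values_by_pid):
    rows = []
    for pid, vals in values_by_pid.items():
        for v in vals:
            rows.append(dict(participant_id=pid, value=v))
    return pd.DataFrame(rows)


class TestClusterBootstrap:
    def test_identical_clusters_zero_width(self):
        data = cluster_frame({f"p{i}": [1.0, 2.0, 3.0] for i in range(6)})
        res = cluster_bootstrap(
            data, lambda df: df["value"].mean(), B=200, seed=0
        )
        assert res.ci_low == res.ci_high == res.estimate == 2.0

    def test_determinism(self):
        rng = np.random.default_rng(1)
        data = cluster_frame({f"p{i}": rng.normal(size=4) for i in range(10)})
        a = cluster_bootstrap(data, lambda df: df["value"].mean(), B=300, seed=9)
        b = cluster_bootstrap(data, lambda df: df["value"].mean(), B=300, seed=9)
        assert np.array_equal(a.replicates, b.replicates)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_cluster_integrity(self):
        """No replicate ever contains a partial participant."""
        rng = np.random.default_rng(2)
        sizes = {f"p{i}": rng.integers(2, 6) for i in range(8)}
        data = cluster_frame(
            {pid: rng.normal(size=n) for pid, n in sizes.items()}
        )

        def check_whole_clusters(df):
            counts = df.groupby("participant_id").size()
            for pid, n in counts.items():
                assert n % sizes[pid] == 0
            return df["value"].mean()

        cluster_bootstrap(data, check_whole_clusters, B=150, seed=4)

    def test_failing_replicates_redrawn(self):
        data = cluster_frame({f"p{i}": [float(i)] for i in range(5)})
        calls = {"n": 0}

        def flaky(df):
            calls["n"] += 1
            if calls["n"] % 7 == 3:
                raise ValueError("degenerate replicate")
            return df["value"].mean()

        res = cluster_bootstrap(data, flaky, B=100, seed=0, max_retries=100)
        assert len(res.replicates) == 100
        assert res.n_failures > 0

    def test_b_floor_enforced(self):
        data = cluster_frame({"p1": [1.0], "p2": [2.0]})
        with pytest.raises(ValueError, match="at least 100"):
            cluster_bootstrap(data, lambda df: 0.0, B=50, seed=0)
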