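"""Tukey HSD and interaction-importance scoring, checked against
independent oracles (pooled t-test, scipy's tukey_hsd, exhaustive
enumeration)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import tukey_hsd, ttest_ind

import metplast as mp
from conftest import exact_noise, grid_dataset, make_plot_frame


def bruteforce_scores(data, trait, alpha=0.05):
    """Exhaustive enumeration oracle for interaction-importance scoring.

    Significance per environment from scipy.stats.tukey_hsd (an
    implementation independent of the package's studentized-range
    formulation); pair/environment-pair loops written naively.
    """
    df = data.obs[["hybrid", "environment", trait]].dropna(subset=[trait])
    envs = sorted(df["environment"].unique())
    hybrids = sorted(df["hybrid"].unique())
    means, sig = {}, {}
    for env in envs:
        sub = df[df["environment"] == env]
        present = sorted(sub["hybrid"].unique())
        samples = [sub[sub["hybrid"] == h][trait].to_numpy() for h in present]
        res = tukey_hsd(*samples)
        for i, h in enumerate(present):
            means[(h, env)] = samples[i].mean()
            for j, h2 in enumerate(present):
                if i < j:
                    sig[frozenset((h, h2)), env] = res.pvalue[i, j] < alpha
    out = {}
    for ha, hb in itertools.combinations(hybrids, 2):
        shared = [e for e in envs if (ha, e) in means and (hb, e) in means]
        n_e = len(shared)
        raw = 0
        for e1, e2 in itertools.combinations(shared, 2):
            d1 = means[(ha, e1)] - means[(hb, e1)]
            d2 = means[(ha, e2)] - means[(hb, e2)]
            if abs(d1) > 1e-9 and abs(d2) > 1e-9 and d1 * d2 < 0:
                raw += int(sig[frozenset((ha, hb)), e1]) + int(sig[frozenset((ha, hb)), e2])
        out[(ha, hb)] = (n_e, raw, n_e * (n_e - 1))
    return out


class TestTukeyPairwise:
    def test_identical_groups_not_significant(self):
        rows = []
        for h in ("A", "B"):
            for k, v in enumerate([5.0, 5.4, 4.6, 5.2]):
                rows.append((h, "L", 2022, "medium", k + 1, v))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        sig = mp.tukey_pairwise(ds, "yield", "2022 L medium")
        assert sig.table["diff"].iloc[0] == pytest.approx(0.0)
        assert sig.table["p_adj"].iloc[0] == pytest.approx(1.0)
        assert not sig.table["significant"].iloc[0]

    def test_two_group_tukey_equals_pooled_t_test(self):
        """At k = 2 the studentized range collapses to q = t*sqrt(2)."""
        rng = np.random.default_rng(0)
        rows = []
        for h, mu in (("A", 5.0), ("B", 6.1)):
            for k in range(6):
                rows.append((h, "L", 2022, "medium", k + 1, mu + rng.normal(0, 0.8)))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        sig = mp.tukey_pairwise(ds, "yield", "2022 L medium")
        ya = ds.obs[ds.obs["hybrid"] == "A"]["yield"]
        yb = ds.obs[ds.obs["hybrid"] == "B"]["yield"]
        t_p = ttest_ind(ya, yb).pvalue
        assert sig.table["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-6)

    def test_three_group_matches_reference_hsd(self):
        """One shifted genotype: its two comparisons significant, the
        third not; p-values match scipy's independent HSD."""
        sd = 0.4
        noise = exact_noise(4, sd)
        rows = []
        for h, mu in (("A", 5.0), ("B", 5.2), ("C", 5.1 + 10 * sd)):
            for k in range(4):
                rows.append((h, "L", 2022, "medium", k + 1, mu + noise[k]))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        sig = mp.tukey_pairwise(ds, "yield", "2022 L medium")
        tab = sig.table.set_index(["hybrid_a", "hybrid_b"])
        assert not tab.loc[("A", "B"), "significant"]
        assert tab.loc[("A", "C"), "significant"]
        assert tab.loc[("B", "C"), "significant"]
        samples = [
            ds.obs[ds.obs["hybrid"] == h]["yield"].to_numpy() for h in ("A", "B", "C")
        ]
        ref = tukey_hsd(*samples)
        assert tab.loc[("A", "B"), "p_adj"] == pytest.approx(ref.pvalue[0, 1], abs=1e-9)
        assert tab.loc[("A", "C"), "p_adj"] == pytest.approx(ref.pvalue[0, 2], abs=1e-9)
        assert tab.loc[("B", "C"), "p_adj"] == pytest.approx(ref.pvalue[1, 2], abs=1e-9)

    def test_unequal_replication_uses_tukey_kramer(self):
        rng = np.random.default_rng(5)
        rows = []
        for h, mu, n in (("A", 5.0, 3), ("B", 6.0, 7), ("C", 5.5, 5)):
            for k in range(n):
                rows.append((h, "L", 2022, "medium", k + 1, mu + rng.normal(0, 0.5)))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        sig = mp.tukey_pairwise(ds, "yield", "2022 L medium")
        samples = [
            ds.obs[ds.obs["hybrid"] == h]["yield"].to_numpy() for h in ("A", "B", "C")
        ]
        ref = tukey_hsd(*samples)
        tab = sig.table.set_index(["hybrid_a", "hybrid_b"])
        for (i, a), (j, b) in itertools.combinations(enumerate("ABC"), 2):
            assert tab.loc[(a, b), "p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-9)

    def test_zero_residual_df_raises(self):
        ds = mp.TrialDataset(
            obs=make_plot_frame(
                [("A", "L", 2022, "medium", 1, 5.0), ("B", "L", 2022, "medium", 1, 6.0)]
            )
        )
        with pytest.raises(mp.DesignError):
            mp.tukey_pairwise(ds, "yield", "2022 L medium")


class TestScorePairEnvironmentPair:
    @pytest.mark.parametrize(
        "m1a, m1b, m2a, m2b, s1, s2, expected",
        [
            (6.0, 5.0, 7.0, 6.5, True, True, 0),    # no rank change
            (6.0, 5.0, 5.0, 6.0, True, False, 1),   # change, one significant
            (6.0, 5.0, 5.0, 6.0, True, True, 2),    # change, both significant
            (6.0, 5.0, 5.0, 6.0, False, False, 0),  # change, none significant
            (5.0, 5.0, 5.0, 6.0, True, True, 0),    # tie -> no change
        ],
    )
    def test_scoring_rules(self, m1a, m1b, m2a, m2b, s1, s2, expected):
        assert mp.score_pair_environmentpair(m1a, m1b, m2a, m2b, s1, s2) == expected


class TestScoreAllPairs:
    def test_worked_four_environment_pair(self):
        """Pair co-occurring in 4 environments, rank change with
        one-environment significance in 4 of the 6 environment pairs:
        raw 4, max 4 x 3 = 12, normalized 1/3."""
        means = pd.DataFrame(
            {
                "E1": {"A": 9.0, "B": 6.0, "C": 7.5},
                "E2": {"A": 9.0, "B": 6.0, "C": 7.5},
                "E3": {"A": 6.75, "B": 7.0, "C": 6.9},
                "E4": {"A": 6.75, "B": 7.0, "C": 6.9},
            }
        )
        ds = grid_dataset(means, n_rep=8, sd=0.25)
        scores = mp.score_all_pairs(ds, "yield")
        row = scores.pairs.set_index(["hybrid_a", "hybrid_b"]).loc[("A", "B")]
        assert row["n_env"] == 4
        assert row["raw_score"] == 4
        assert row["max_score"] == 12
        assert row["normalized"] == pytest.approx(1 / 3)

    def test_no_rank_changes_all_zero(self):
        means = pd.DataFrame(
            {
                "E1": {"A": 9.0, "B": 6.0, "C": 7.5},
                "E2": {"A": 10.0, "B": 7.0, "C": 8.5},
                "E3": {"A": 5.0, "B": 2.0, "C": 3.5},
            }
        )
        ds = grid_dataset(means)
        scores = mp.score_all_pairs(ds, "yield")
        assert (scores.pairs["normalized"] == 0).all()

    def test_matches_bruteforce_on_engineered_fixture(self):
        rng = np.random.default_rng(12)
        hybrids = [f"H{i}" for i in range(5)]
        means = pd.DataFrame(
            rng.uniform(5, 9, (5, 4)), index=hybrids,
            columns=["E1", "E2", "E3", "E4"],
        )
        means.iloc[0, 2] = np.nan  # sporadic missingness
        ds = grid_dataset(means, n_rep=4, sd=0.6)
        scores = mp.score_all_pairs(ds, "yield")
        oracle = bruteforce_scores(ds, "yield")
        for _, r in scores.pairs.iterrows():
            n_e, raw, mx = oracle[(r["hybrid_a"], r["hybrid_b"])]
            assert r["n_env"] == n_e
            assert r["raw_score"] == raw
            assert r["max_score"] == mx

    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), nh=st.integers(3, 6), ne=st.integers(2, 4))
    def test_matches_bruteforce_on_random_fixtures(self, seed, nh, ne):
        rng = np.random.default_rng(seed)
        means = pd.DataFrame(
            rng.uniform(4, 10, (nh, ne)),
            index=[f"H{i}" for i in range(nh)],
            columns=[f"E{j}" for j in range(ne)],
        )
        ds = grid_dataset(means, n_rep=3, sd=float(rng.uniform(0.2, 1.5)))
        scores = mp.score_all_pairs(ds, "yield")
        oracle = bruteforce_scores(ds, "yield")
        for _, r in scores.pairs.iterrows():
            n_e, raw, mx = oracle[(r["hybrid_a"], r["hybrid_b"])]
            assert (r["n_env"], r["raw_score"], r["max_score"]) == (n_e, raw, mx)

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        means = pd.DataFrame(
            rng.uniform(5, 9, (4, 3)), index=list("ABCD"), columns=["E1", "E2", "E3"]
        )
        ds = grid_dataset(means, n_rep=4, sd=0.5)
        s1 = mp.score_all_pairs(ds, "yield")
        # relabel environments (location names reversed) and rescore
        obs2 = ds.obs.copy()
        obs2["location"] = obs2["location"].map({"E1": "Z9", "E2": "Z8", "E3": "Z7"})
        ds2 = mp.TrialDataset(obs=obs2.drop(columns=["location_year", "environment"]))
        s2 = mp.score_all_pairs(ds2, "yield")
        merged = s1.pairs.merge(s2.pairs, on=["hybrid_a", "hybrid_b"])
        assert (merged["raw_score_x"] == merged["raw_score_y"]).all()
        assert (merged["normalized_x"] == merged["normalized_y"]).all()

    def test_undefined_pairs_excluded_from_summary(self):
        # A and B never co-occur
        means = pd.DataFrame(
            {
                "E1": {"A": 8.0, "C": 7.0, "D": 6.0},
                "E2": {"B": 8.0, "C": 7.5, "D": 6.5},
                "E3": {"A": 7.0, "C": 6.5, "D": 7.5},
            }
        )
        ds = grid_dataset(means, n_rep=3, sd=0.3)
        scores = mp.score_all_pairs(ds, "yield")
        ab = scores.pairs.set_index(["hybrid_a", "hybrid_b"]).loc[("A", "B")]
        assert ab["n_env"] < 2 and np.isnan(ab["normalized"])
        s = scores.summary()
        assert s["n_pairs_undefined"] >= 1
        assert s["n_pairs_defined"] + s["n_pairs_undefined"] == s["n_pairs"]

    def test_detail_scores_bounded_and_consistent(self):
        means = pd.DataFrame(
            {
                "E1": {"A": 9.0, "B": 6.0},
                "E2": {"A": 6.0, "B": 9.0},
                "E3": {"A": 7.0, "B": 7.5},
            }
        )
        ds = grid_dataset(means, n_rep=4, sd=0.3)
        scores = mp.score_all_pairs(ds, "yield", detail=True)
        assert set(scores.detail["score"]).issubset({0, 1, 2})
        raw_from_detail = scores.detail.groupby(["hybrid_a", "hybrid_b"])["score"].sum()
        merged = scores.pairs.set_index(["hybrid_a", "hybrid_b"])["raw_score"]
        for key, v in raw_from_detail.items():
            assert merged[key] == v
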