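"""Finlay-Wilkinson regression, rank-change prediction, percent-mean
plasticity and BLUP ranking."""

import numpy as np
import pandas as pd
import pytest

import metplast as mp
from conftest import make_plot_frame


def dataset_from_lines(coefs, index_values, n_rep=1):
    """Noiseless plots where hybrid i's value in env j is a_i + b_i * h_j.

    ``coefs``: {hybrid: (intercept, slope)}; ``index_values``: the
    intended environment means. Only consistent (self-reproducing)
    constructions are passed in: the population mean in env j must equal
    h_j, i.e. mean(a) + mean(b) * h_j == h_j.
    """
    rows = []
    for j, h in enumerate(index_values):
        for hyb, (a, b) in coefs.items():
            for k in range(n_rep):
                rows.append((hyb, f"L{j}", 2022, "medium", k + 1, a + b * h))
    return mp.TrialDataset(obs=make_plot_frame(rows))


class TestFitFW:
    def test_population_tracking_hybrid_has_unit_slope(self):
        # both hybrids sit exactly at the environment mean
        ds = dataset_from_lines({"A": (0.0, 1.0), "B": (0.0, 1.0)}, [4.0, 6.0, 9.0])
        fit = mp.fit_fw(ds, "yield")
        assert fit.slopes["A"] == pytest.approx(1.0, abs=1e-12)
        assert fit.coef.loc["A", "intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_slopes_against_normal_equation_oracle(self):
        # mean slope 1 and mean intercept 0 keep the construction
        # self-consistent: population mean in env j equals h_j
        coefs = {"A": (1.0, 0.8), "B": (0.0, 1.0), "C": (-1.0, 1.2)}
        h_true = [3.0, 6.0, 8.0, 11.0]
        ds = dataset_from_lines(coefs, h_true, n_rep=2)
        fit = mp.fit_fw(ds, "yield")
        for hyb, (a, b) in coefs.items():
            assert fit.slopes[hyb] == pytest.approx(b, abs=1e-10)
            assert fit.coef.loc[hyb, "intercept"] == pytest.approx(a, abs=1e-10)
        # independent oracle: explicit normal equations per hybrid
        cell = ds.obs.groupby(["hybrid", "environment"])["yield"].mean()
        h = ds.obs.groupby("environment")["yield"].mean()
        for hyb in coefs:
            y = cell[hyb].reindex(h.index).to_numpy()
            x = np.column_stack([np.ones(len(h)), h.to_numpy()])
            beta = np.linalg.solve(x.T @ x, x.T @ y)
            assert fit.coef.loc[hyb, "intercept"] == pytest.approx(beta[0], abs=1e-9)
            assert fit.slopes[hyb] == pytest.approx(beta[1], abs=1e-9)

    def test_environment_exclusion_drops_outlier_location_year(self, sim_default):
        data, _ = sim_default
        excl_ly = data.location_years()[0]
        fit = mp.fit_fw(data, "yield", exclude_environments=(excl_ly,))
        assert not any(e.startswith(excl_ly) for e in fit.environments)

    def test_balanced_presence_weighted_mean_slope_is_one(self, sim_noiseless):
        data, _ = sim_noiseless
        fit = mp.fit_fw(data, "yield")
        w = fit.coef["n_env"]
        assert float((fit.slopes * w).sum() / w.sum()) == pytest.approx(1.0, abs=1e-10)

    def test_residuals_orthogonal_to_index(self, sim_default):
        data, _ = sim_default
        fit = mp.fit_fw(data, "yield")
        cell = data.obs.groupby(["hybrid", "environment"])["yield"].mean()
        h = fit.env_index
        for hyb in fit.hybrids[:10]:
            envs = cell[hyb].index.intersection(h.index)
            resid = (
                cell[hyb][envs]
                - fit.coef.loc[hyb, "intercept"]
                - fit.slopes[hyb] * h[envs]
            )
            hc = h[envs] - h[envs].mean()
            assert float(resid @ hc) == pytest.approx(0.0, abs=1e-8)

    def test_underobserved_hybrid_excluded_not_fatal(self, three_env_dataset):
        obs = three_env_dataset.obs
        extra = obs[obs["hybrid"] == "A"].copy()
        singleton = extra.iloc[:1].assign(hybrid="Z")
        ds = mp.TrialDataset(obs=pd.concat([obs, singleton], ignore_index=True))
        fit = mp.fit_fw(ds, "yield")
        assert "Z" in fit.excluded_hybrids
        assert "Z" not in fit.hybrids

    def test_single_environment_raises(self, two_hybrid_csv):
        ds = mp.read_plot_table(two_hybrid_csv)
        with pytest.raises(mp.DesignError):
            mp.fit_fw(ds, "yield")

    def test_constant_index_raises(self):
        ds = dataset_from_lines({"A": (0.0, 1.0), "B": (0.0, 1.0)}, [5.0, 5.0, 5.0])
        with pytest.raises(mp.DesignError):
            mp.fit_fw(ds, "yield")

    def test_als_refinement_agrees_on_noiseless_data(self, sim_noiseless):
        data, truth = sim_noiseless
        fit = mp.fit_fw(data, "yield", refine=True)
        true = truth.hybrids.set_index("hybrid")["slope"]
        assert np.abs(fit.slopes - true.reindex(fit.slopes.index)).max() < 1e-6
        assert fit.n_iterations >= 1

    def test_fitted_defined_for_absent_hybrid_environment_pairs(self, sim_default):
        data, _ = sim_default
        fit = mp.fit_fw(data, "yield")
        present = set(map(tuple, data.obs[["hybrid", "environment"]].drop_duplicates().values))
        for hyb in fit.hybrids:
            for env in fit.environments:
                if (hyb, env) not in present:
                    assert np.isfinite(fit.fitted(hyb, env))
                    return
        pytest.skip("design happened to be complete")


class TestRankChanges:
    def test_parallel_lines_never_change_rank(self):
        ds = dataset_from_lines({"A": (1.0, 1.0), "B": (-1.0, 1.0)}, [4.0, 8.0])
        rc = mp.predict_rank_changes(mp.fit_fw(ds, "yield"))
        assert rc.pairs_changing_rank == 0

    def test_crossing_lines_detected_with_hand_computed_fit(self):
        # A: a=2, b=0.8; B: a=0, b=1.2 over index [2, 8]:
        # at h=2 A=3.6 > B=2.4; at h=8 A=8.4 < B=9.6 -> change
        ds = dataset_from_lines({"A": (2.0, 0.8), "B": (0.0, 1.2)}, [2.0, 5.0, 8.0])
        fit = mp.fit_fw(ds, "yield")
        rc = mp.predict_rank_changes(fit)
        assert rc.pairs_changing_rank == 1
        row = rc.pairs.iloc[0]
        assert row["fitted_low_a"] == pytest.approx(3.6, abs=1e-9)
        assert row["fitted_high_b"] == pytest.approx(9.6, abs=1e-9)
        assert row["gap_high"] == pytest.approx(1.2, abs=1e-9)

    def test_all_crossing_triple(self):
        # slopes 0.9 / 1.0 / 1.1 all crossing inside the index range
        coefs = {"A": (0.6, 0.9), "B": (0.0, 1.0), "C": (-0.6, 1.1)}
        ds = dataset_from_lines(coefs, [2.0, 6.0, 10.0])
        rc = mp.predict_rank_changes(mp.fit_fw(ds, "yield"))
        assert rc.pairs_evaluated == 3
        assert rc.pairs_changing_rank == 3

    def test_agrees_with_bruteforce_line_evaluation(self, sim_default):
        data, _ = sim_default
        fit = mp.fit_fw(data, "yield")
        rc = mp.predict_rank_changes(fit)
        lo, hi = rc.low_env, rc.high_env
        expected = 0
        hybs = fit.hybrids
        for i in range(len(hybs)):
            for j in range(i + 1, len(hybs)):
                d1 = fit.fitted(hybs[i], lo) - fit.fitted(hybs[j], lo)
                d2 = fit.fitted(hybs[i], hi) - fit.fitted(hybs[j], hi)
                if abs(d1) > 1e-9 and abs(d2) > 1e-9 and d1 * d2 < 0:
                    expected += 1
        assert rc.pairs_changing_rank == expected

    def test_gap_fraction(self):
        # one changing pair with gap 1.2 > 0.63, threshold respected
        ds = dataset_from_lines({"A": (2.0, 0.8), "B": (0.0, 1.2)}, [2.0, 5.0, 8.0])
        rc = mp.predict_rank_changes(mp.fit_fw(ds, "yield"), gap_threshold=0.63)
        assert rc.fraction_changing_above_gap == 1.0
        rc2 = mp.predict_rank_changes(mp.fit_fw(ds, "yield"), gap_threshold=2.0)
        assert rc2.fraction_changing_above_gap == 0.0


class TestPercentMeanPlasticity:
    def test_constant_tracking_gives_unit_slope_and_100pct(self):
        ds = dataset_from_lines({"A": (0.0, 1.0), "B": (0.0, 1.0)}, [4.0, 6.0, 9.0])
        pmp = mp.percent_mean_plasticity(ds, "yield")
        assert pmp.table["slope_pct"].tolist() == pytest.approx([1.0, 1.0], abs=1e-10)
        assert pmp.table["mean_pct_performance"].tolist() == pytest.approx(
            [100.0, 100.0], abs=1e-10
        )

    def test_sign_matches_constructed_percent_decline(self):
        """A hybrid whose percent-of-mean declines with environment mean
        has slope_pct < 1; oracle = per-hybrid OLS of percent response."""
        h_vals = [5.0, 8.0, 11.0]
        rows = []
        for j, h in enumerate(h_vals):
            # A's percent of mean declines 110% -> 90%; B compensates
            pct_a = 110.0 - 2.5 * (h - 5.0)
            ya = pct_a / 100.0 * h
            yb = 2 * h - ya
            rows.append(("A", f"L{j}", 2022, "medium", 1, ya))
            rows.append(("B", f"L{j}", 2022, "medium", 1, yb))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        pmp = mp.percent_mean_plasticity(ds, "yield")
        # oracle: direct OLS of A's percent response on environment mean,
        # then the +1 recentering
        x = np.array(h_vals)
        y = np.array([110.0 - 2.5 * (h - 5.0) for h in h_vals])
        oracle_slope = np.polyfit(x, y, 1)[0]  # -2.5 percent points per MT/ha
        assert pmp.table.loc["A", "slope_pct"] == pytest.approx(oracle_slope + 1.0, abs=1e-9)
        assert pmp.table.loc["A", "slope_pct"] < 1.0 < pmp.table.loc["B", "slope_pct"]

    def test_population_weighted_slope_near_one(self, sim_default):
        data, _ = sim_default
        pmp = mp.percent_mean_plasticity(data, "yield")
        w = pmp.table["n_env"]
        pop = float((pmp.table["slope_pct"] * w).sum() / w.sum())
        assert pop == pytest.approx(1.0, abs=0.05)


class TestBlupRank:
    def test_balanced_data_blup_order_equals_mean_order(self):
        rng = np.random.default_rng(0)
        rows = []
        effects = {"A": -1.0, "B": 0.0, "C": 0.6, "D": 1.4}
        for j, e in enumerate([0.0, 2.0, 4.0]):
            for hyb, g in effects.items():
                for k in (1, 2):
                    rows.append((hyb, f"L{j}", 2022, "medium", k,
                                 8 + g + e + rng.normal(0, 0.3)))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        ranks = mp.blup_rank(ds, "yield")
        raw = ds.obs.groupby("hybrid")["yield"].mean().sort_values()
        assert list(ranks.sort_values("rank").index) == list(raw.index)

    def test_ranks_are_a_permutation(self, sim_default):
        data, _ = sim_default
        ranks = mp.blup_rank(data, "yield")
        assert sorted(ranks["rank"]) == list(range(1, len(ranks) + 1))

    def test_unbalanced_best_environment_hybrid_demoted(self):
        """A hybrid seen only in the best environments ranks lower by
        BLUP than by raw mean (environment fixed effect adjusts it)."""
        rng = np.random.default_rng(1)
        rows = []
        envs = [0.0, 1.0, 2.0, 6.0, 7.0]
        for j, e in enumerate(envs):
            for hi, hyb in enumerate(["A", "B", "C", "D", "E"]):
                g = {"A": -0.5, "B": -0.2, "C": 0.0, "D": 0.2, "E": 0.0}[hyb]
                if hyb == "E" and e < 5.0:
                    continue  # E only appears in the two best environments
                for k in (1, 2):
                    rows.append((hyb, f"L{j}", 2022, "medium", k,
                                 6 + g + e + rng.normal(0, 0.2)))
        ds = mp.TrialDataset(obs=make_plot_frame(rows))
        ranks = mp.blup_rank(ds, "yield")
        raw_rank = ds.obs.groupby("hybrid")["yield"].mean().rank()
        assert raw_rank["E"] == 5.0  # raw mean puts E on top
        assert ranks.loc["E", "rank"] < 5  # BLUP does not
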