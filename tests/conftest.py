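"""Shared fixtures: small hand-built trials and reusable simulations."""

import numpy as np
import pandas as pd
import pytest

import metplast as mp


def make_plot_frame(records):
    """Rows of (hybrid, location, year, nitrogen_level, block, yield)."""
    df = pd.DataFrame(
        records, columns=["hybrid", "location", "year", "nitrogen_level", "block", "yield"]
    )
    return df


@pytest.fixture
def two_hybrid_csv(tmp_path):
    """2 hybrids x 1 environment x 2 blocks."""
    path = tmp_path / "plots.csv"
    make_plot_frame(
        [
            ("A", "Ames", 2022, "medium", 1, 9.1),
            ("A", "Ames", 2022, "medium", 2, 9.5),
            ("B", "Ames", 2022, "medium", 1, 8.2),
            ("B", "Ames", 2022, "medium", 2, 8.6),
        ]
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def three_env_dataset():
    """3 hybrids x 2 environments (hand-countable)."""
    return mp.TrialDataset(
        obs=make_plot_frame(
            [
                ("A", "Ames", 2022, "low", 1, 8.0),
                ("A", "Ames", 2022, "low", 2, 8.4),
                ("A", "Lincoln", 2022, "low", 1, 6.0),
                ("B", "Ames", 2022, "low", 1, 9.0),
                ("B", "Lincoln", 2022, "low", 1, 7.0),
                ("C", "Ames", 2022, "low", 1, 7.5),
                ("C", "Lincoln", 2022, "low", 1, 5.5),
            ]
        )
    )


def exact_noise(n, sd):
    """A length-n pattern with exact zero mean and exact sample sd
    (ddof=0) — deterministic replicate 'noise' for Tukey fixtures."""
    pat = np.arange(n, dtype=float)
    pat -= pat.mean()
    pat /= pat.std()
    return pat * sd


def grid_dataset(mean_table, n_rep=8, sd=0.25):
    """Plot data from a hybrid x environment table of designed means.

    Replicates get the deterministic exact-variance noise pattern, so
    group means and the pooled MSE equal their designed values exactly.
    ``mean_table``: DataFrame indexed by hybrid, columns = location
    names (all year 2022, single nitrogen level, blocks 1..n_rep).
    """
    noise = exact_noise(n_rep, sd)
    rows = []
    for hyb, row in mean_table.iterrows():
        for loc, m in row.items():
            if pd.isna(m):
                continue
            for k in range(n_rep):
                rows.append((hyb, loc, 2022, "medium", k + 1, m + noise[k]))
    return mp.TrialDataset(obs=make_plot_frame(rows))


@pytest.fixture(scope="session")
def sim_default():
    """Mid-sized simulated trial with default (study-like) noise."""
    cfg = mp.SimulationConfig(n_hybrids=60, n_location_years=6, seed=42)
    return mp.simulate_trial(cfg)


@pytest.fixture(scope="session")
def sim_noiseless():
    """Balanced noise-free trial: exact recovery territory."""
    cfg = mp.SimulationConfig(
        n_hybrids=20, n_location_years=5, presence_fraction=1.0,
        sigma_gxe_residual=0.0, sigma_plot=0.0, sigma_block=0.0, seed=7,
    )
    return mp.simulate_trial(cfg)
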