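"""Synthetic multi-environment maize hybrid trials with known ground truth.

The generator emulates a replicated hybrid panel of the kind used to
study yield plasticity: ~120 hybrids grown in location-years that each
carry one or more nitrogen fertilization levels, in a randomized
complete block design with two blocks, with unbalanced hybrid presence.
Plot yields follow an additive reaction-norm model

    Y_ijk = mu + g_i + b_i * e_j + eta_ij + beta_jk + eps_ijk

where g_i is the genotype intercept, e_j the (centered) environment
quality effect, b_i the Finlay-Wilkinson slope of hybrid i (centered at
1), eta_ij the non-systematic G-by-E remainder, beta_jk a block effect,
and eps_ijk plot noise. Genotype intercepts and slopes are correlated
with a mean-parent-release-year covariate spanning 1934-2000, and the
slope deviations carry an additive parental (general combining ability)
component, so parameter recovery is testable for every downstream stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DataError, DesignError, TrialDataset

_LEVEL_NAMES = ("low", "medium", "high")

#: Smallest yield the generator will emit (MT/ha); real combine yields
#: are bounded well away from zero.
YIELD_FLOOR = 0.1


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trial.

    Defaults describe a study-sized panel: 120 hybrids, 10 location-years
    each split into three nitrogen environments (84/168/252 kg N/ha),
    two blocks, ~90% hybrid presence with at least four environments per
    hybrid, environment quality effects with sd 2.5 MT/ha and plot noise
    0.7 MT/ha.
    """

    n_hybrids: int = 120
    n_location_years: int = 10
    nitrogen_levels: tuple = (84.0, 168.0, 252.0)  # kg N/ha
    n_blocks: int = 2
    mu: float = 9.0                      # grand mean yield, MT/ha
    env_quality_spread: float = 2.5      # sd of environment effects, MT/ha
    sigma_g: float = 0.6                 # sd of genotype intercepts, MT/ha
    sigma_slope: float = 0.15            # sd of FW slope deviations
    slope_year_correlation: float = 0.5  # corr(slope dev, release year); also intercepts
    slope_gca_fraction: float = 0.5      # parental-additive share of non-year slope variance
    sigma_gxe_residual: float = 0.25     # sd of eta_ij, MT/ha
    sigma_plot: float = 0.7              # sd of plot noise, MT/ha
    sigma_block: float | None = None     # sd of block effects; None -> sigma_plot / 2
    nitrogen_response_per_level: tuple = (0.0, 1.5, 2.25)  # cumulative MT/ha by level
    presence_fraction: float = 0.9
    min_env_per_hybrid: int = 4
    seed: int = 0
    trait_name: str = "yield"

    def __post_init__(self) -> None:
        for name in ("env_quality_spread", "sigma_g", "sigma_slope",
                     "sigma_gxe_residual", "sigma_plot"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")
        if self.n_blocks < 1:
            raise DataError("n_blocks must be >= 1")
        if abs(self.slope_year_correlation) > 1:
            raise DataError("|slope_year_correlation| must be <= 1")
        if not (0 < self.presence_fraction <= 1):
            raise DataError("presence_fraction must be in (0, 1]")
        if len(self.nitrogen_response_per_level) != len(self.nitrogen_levels):
            raise DataError(
                "nitrogen_response_per_level must match nitrogen_levels in length"
            )


@dataclass
class GroundTruth:
    """Generating values of one simulated trial.

    ``hybrids``: per hybrid g (intercept), slope (b, centered at 1),
    mean_parent_release_year, parents. ``environments``: per environment
    the centered quality effect e. ``gxe``: long table of eta_ij.
    ``nitrogen_slopes`` (nitrogen studies only): per hybrid x
    location-year nitrogen-response slope.
    """

    mu: float
    hybrids: pd.DataFrame
    environments: pd.DataFrame
    gxe: pd.DataFrame
    nitrogen_slopes: pd.DataFrame = field(default_factory=pd.DataFrame)


def _level_name(i: int, n: int) -> str:
    if n == 1:
        return "medium"
    if n <= 3:
        return _LEVEL_NAMES[i]
    return f"N{i + 1}"


def _centered(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def _make_pedigree(cfg: SimulationConfig, rng: np.random.Generator):
    """Inbred parent pool, hybrid crosses, release years, GCA effects."""
    n_par = max(4, int(round(cfg.n_hybrids * 0.45)))
    parents = [f"P{i + 1:03d}" for i in range(n_par)]
    release = rng.uniform(1934, 2000, size=n_par)
    gca = rng.standard_normal(n_par)  # unit-variance parental slope effects
    ear_idx = rng.integers(0, n_par, size=cfg.n_hybrids)
    pol_idx = np.array(
        [rng.choice([j for j in range(n_par) if j != e]) for e in ear_idx]
    )
    ped = pd.DataFrame(
        {
            "hybrid": [f"H{i + 1:03d}" for i in range(cfg.n_hybrids)],
            "ear_parent": [parents[i] for i in ear_idx],
            "pollen_parent": [parents[i] for i in pol_idx],
            "ear_parent_release_year": release[ear_idx].round(0),
            "pollen_parent_release_year": release[pol_idx].round(0),
        }
    )
    ped["mean_parent_release_year"] = (
        ped["ear_parent_release_year"] + ped["pollen_parent_release_year"]
    ) / 2.0
    ped["is_check"] = False
    gca_sum = (gca[ear_idx] + gca[pol_idx]) / math.sqrt(2.0)
    return ped, gca_sum


def _genetic_effects(cfg: SimulationConfig, rng: np.random.Generator,
                     ped: pd.DataFrame, gca_sum: np.ndarray):
    """Intercepts and FW slopes, correlated with mean parent release year.

    Correlation is induced by a Gaussian-copula-style mix: the release
    year covariate is standardized and blended with independent (partly
    parental-additive) normals at the configured correlation. Deviations
    are exactly centered so the sample means of g and (b - 1) are 0.
    """
    yr = ped["mean_parent_release_year"].to_numpy(float)
    z_year = (yr - yr.mean()) / (yr.std() if yr.std() > 0 else 1.0)
    rho = cfg.slope_year_correlation
    f_gca = cfg.slope_gca_fraction
    indep = (
        math.sqrt(f_gca) * gca_sum
        + math.sqrt(1 - f_gca) * rng.standard_normal(cfg.n_hybrids)
    )
    slope_dev = cfg.sigma_slope * (rho * z_year + math.sqrt(1 - rho**2) * indep)
    g = cfg.sigma_g * (rho * z_year
                       + math.sqrt(1 - rho**2) * rng.standard_normal(cfg.n_hybrids))
    return _centered(g), 1.0 + _centered(slope_dev)


def _environment_frame(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_levels = len(cfg.nitrogen_levels)
    n_env = cfg.n_location_years * n_levels
    if n_env < 2:
        raise DesignError("design implies < 2 environments; FW regression needs >= 2")
    nresp = np.asarray(cfg.nitrogen_response_per_level, float)
    var_n = nresp.var() if n_levels > 1 else 0.0
    sd_base = math.sqrt(max(cfg.env_quality_spread**2 - var_n, 1e-4))
    rows = []
    for ly in range(cfg.n_location_years):
        base = rng.normal(0.0, sd_base)
        year = 2022 + ly % 2
        loc = f"SimSite{ly + 1:02d}"
        for li, rate in enumerate(cfg.nitrogen_levels):
            rows.append(
                {
                    "location": loc,
                    "year": year,
                    "irrigation": "",
                    "nitrogen_level": _level_name(li, n_levels),
                    "nitrogen_rate": float(rate),
                    "location_year": f"{year} {loc}",
                    "ly_base": base,
                    "n_effect": nresp[li] - nresp.mean(),
                    "level_index": li,
                }
            )
    env = pd.DataFrame(rows)
    e = _centered((env["ly_base"] + env["n_effect"]).to_numpy())
    # Pin the realized spread: the config states the sample sd of the
    # environment effects, not just its expectation.
    sd = e.std()
    if sd > 0:
        e = e * (cfg.env_quality_spread / sd)
    env["e"] = e
    env["environment"] = env["location_year"] + " " + env["nitrogen_level"]
    return env


def _presence(cfg: SimulationConfig, rng: np.random.Generator, n_env: int) -> np.ndarray:
    """Boolean hybrid x environment presence mask.

    Each hybrid keeps each environment with probability
    ``presence_fraction`` but always retains at least
    ``min_env_per_hybrid`` environments (topped up at random).
    """
    need = min(cfg.min_env_per_hybrid, n_env)
    mask = rng.random((cfg.n_hybrids, n_env)) < cfg.presence_fraction
    for i in range(cfg.n_hybrids):
        deficit = need - int(mask[i].sum())
        if deficit > 0:
            absent = np.flatnonzero(~mask[i])
            mask[i, rng.choice(absent, size=deficit, replace=False)] = True
    return mask


def _assemble(cfg, rng, ped, g, env, eta, mask, slope_for_env):
    """Build the plot table. ``slope_for_env(i, j)`` returns the slope
    multiplying e_j for hybrid i (constant for overall trials,
    location-year-specific for nitrogen studies)."""
    n_env = len(env)
    e = env["e"].to_numpy()
    sigma_block = cfg.sigma_plot / 2.0 if cfg.sigma_block is None else cfg.sigma_block
    block_eff = rng.normal(0.0, sigma_block, size=(n_env, cfg.n_blocks))
    hyb_ids = ped["hybrid"].to_numpy()
    ii, jj = np.nonzero(mask)
    rows = []
    for i, j in zip(ii, jj):
        base = cfg.mu + g[i] + slope_for_env(i, j) * e[j] + eta[i, j]
        for k in range(cfg.n_blocks):
            y = base + block_eff[j, k] + rng.normal(0.0, cfg.sigma_plot)
            rows.append((hyb_ids[i], j, k + 1, max(y, YIELD_FLOOR)))
    obs = pd.DataFrame(rows, columns=["hybrid", "_env_idx", "block", cfg.trait_name])
    env_cols = ["location", "year", "irrigation", "nitrogen_level", "nitrogen_rate",
                "location_year", "environment"]
    obs = obs.join(env[env_cols], on="_env_idx").drop(columns="_env_idx")
    obs = obs[env_cols[:5] + ["hybrid", "block", cfg.trait_name,
                              "location_year", "environment"]]
    return TrialDataset(
        obs=obs.reset_index(drop=True),
        pedigree=ped.copy(),
        trait_registry={cfg.trait_name: "MT/ha"},
    )


def simulate_trial(config: SimulationConfig) -> tuple[TrialDataset, GroundTruth]:
    """Simulate one multi-environment trial; deterministic for a fixed seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    ped, gca_sum = _make_pedigree(cfg, rng)
    g, b = _genetic_effects(cfg, rng, ped, gca_sum)
    env = _environment_frame(cfg, rng)
    eta = rng.normal(0.0, cfg.sigma_gxe_residual, size=(cfg.n_hybrids, len(env)))
    mask = _presence(cfg, rng, len(env))
    data = _assemble(cfg, rng, ped, g, env, eta, mask, lambda i, j: b[i])

    hyb = ped[["hybrid", "ear_parent", "pollen_parent",
               "mean_parent_release_year"]].copy()
    hyb["g"] = g
    hyb["slope"] = b
    gxe = pd.DataFrame(
        {
            "hybrid": np.repeat(ped["hybrid"].to_numpy(), len(env)),
            "environment": np.tile(env["environment"].to_numpy(), cfg.n_hybrids),
            "eta": eta.ravel(),
        }
    )
    truth = GroundTruth(
        mu=cfg.mu,
        hybrids=hyb,
        environments=env[["environment", "location_year", "nitrogen_level", "e"]].copy(),
        gxe=gxe,
    )
    return data, truth


def simulate_nitrogen_study(
    config: SimulationConfig, repeatable_fraction: float
) -> tuple[TrialDataset, GroundTruth]:
    """Simulate a nitrogen dose-response trial with tunable repeatability.

    Each hybrid's nitrogen-response slope in a location-year blends a
    hybrid-level component (shared across location-years) with an
    independent location-year-specific component:

        b_il = 1 + sigma_slope * (sqrt(f) * u_i + sqrt(1 - f) * w_il)

    ``repeatable_fraction`` f = 1 makes nitrogen plasticity perfectly
    repeatable across location-years; f = 0 makes it independent. The
    slope multiplies the full environment effect, whose within-location-
    year spread is the nitrogen dose response, so a Finlay-Wilkinson fit
    restricted to one location-year's nitrogen environments recovers
    b_il.
    """
    cfg = config
    if not (0.0 <= repeatable_fraction <= 1.0):
        raise DataError("repeatable_fraction must be in [0, 1]")
    if cfg.n_location_years < 2 or len(cfg.nitrogen_levels) < 3:
        raise DesignError(
            "nitrogen study needs >= 2 location-years with >= 3 nitrogen levels"
        )
    rng = np.random.default_rng(cfg.seed)
    ped, gca_sum = _make_pedigree(cfg, rng)
    g, _ = _genetic_effects(cfg, rng, ped, gca_sum)
    env = _environment_frame(cfg, rng)
    n_ly = cfg.n_location_years

    f = repeatable_fraction
    u = _centered(rng.standard_normal(cfg.n_hybrids))
    w = np.apply_along_axis(_centered, 0, rng.standard_normal((cfg.n_hybrids, n_ly)))
    b_il = 1.0 + cfg.sigma_slope * (
        math.sqrt(f) * u[:, None] + math.sqrt(1.0 - f) * w
    )

    eta = rng.normal(0.0, cfg.sigma_gxe_residual, size=(cfg.n_hybrids, len(env)))
    mask_ly = _presence_by_ly(cfg, rng, n_ly)
    ly_index = env["location_year"].factorize(sort=True)[0]
    mask = mask_ly[:, ly_index]
    data = _assemble(
        cfg, rng, ped, g, env, eta, mask,
        lambda i, j: b_il[i, ly_index[j]],
    )

    hyb = ped[["hybrid", "ear_parent", "pollen_parent",
               "mean_parent_release_year"]].copy()
    hyb["g"] = g
    hyb["slope"] = b_il.mean(axis=1)
    lys = sorted(env["location_year"].unique())
    nslopes = pd.DataFrame(b_il, index=ped["hybrid"], columns=lys)
    truth = GroundTruth(
        mu=cfg.mu,
        hybrids=hyb,
        environments=env[["environment", "location_year", "nitrogen_level", "e"]].copy(),
        gxe=pd.DataFrame(),
        nitrogen_slopes=nslopes,
    )
    return data, truth


def _presence_by_ly(cfg: SimulationConfig, rng: np.random.Generator, n_ly: int):
    """Thin presence wholesale per (hybrid, location-year), keeping >= 2."""
    mask = rng.random((cfg.n_hybrids, n_ly)) < cfg.presence_fraction
    need = min(2, n_ly)
    for i in range(cfg.n_hybrids):
        deficit = need - int(mask[i].sum())
        if deficit > 0:
            absent = np.flatnonzero(~mask[i])
            mask[i, rng.choice(absent, size=deficit, replace=False)] = True
    return mask


def write_ground_truth(truth: GroundTruth, hybrids_path, environments_path) -> None:
    """Write ground-truth tables to companion CSVs."""
    truth.hybrids.to_csv(hybrids_path, index=False)
    truth.environments.to_csv(environments_path, index=False)
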