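"""Repeatability of plasticity and nitrogen-response plasticity.

Nitrogen plasticity of a hybrid is its Finlay-Wilkinson slope fitted
over the nitrogen environments of a single location-year — meaningful
only where the population actually responded to fertilization, i.e.
location-years whose population-level yield increases across ordered
nitrogen levels. The mean nitrogen plasticity (MNP) averages a hybrid's
slopes over the qualifying location-years.

Repeatability of any plasticity measure is estimated by a split-block
design: two FW fits on disjoint halves of the plots (block 1 of every
environment vs block 2), compared by Spearman rank correlation over the
hybrids common to both halves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .core import DataError, DesignError, EstimationError, TrialDataset
from .fw import fit_fw

logger = logging.getLogger("metplast")

#: Spearman correlations over fewer common hybrids than this are
#: reported as undefined rather than a spurious value.
MIN_COMMON_HYBRIDS = 3


@dataclass
class NitrogenPlasticityTable:
    """Per-hybrid nitrogen slopes by location-year, and their mean (MNP)."""

    trait: str
    slopes: pd.DataFrame          # hybrids x location-years
    qualifying_location_years: list
    require_complete: bool = True

    @property
    def mnp(self) -> pd.Series:
        """Mean nitrogen plasticity. By default defined only for hybrids
        with a slope in every qualifying location-year."""
        if self.require_complete:
            full = self.slopes.dropna()
            return full.mean(axis=1).rename("mnp")
        return self.slopes.mean(axis=1).rename("mnp")


@dataclass
class RepeatabilityReport:
    trait: str
    split_design: str
    rho: float
    n_hybrids: int
    per_location_year: dict = field(default_factory=dict)


def qualifying_location_years(
    data: TrialDataset, trait: str, statistic: str = "median"
) -> list[str]:
    """Location-years with a population-level positive nitrogen response.

    A location-year qualifies iff it has >= 2 nitrogen levels and the
    population ``median`` (or ``mean``) of the trait increases strictly
    across its nitrogen levels ordered by application rate.
    """
    if statistic not in ("median", "mean"):
        raise DataError("statistic must be 'median' or 'mean'")
    out = []
    df = data.obs.dropna(subset=[trait])
    for ly, grp in df.groupby("location_year"):
        if "nitrogen_rate" in grp.columns and grp["nitrogen_rate"].notna().any():
            order = grp.groupby("nitrogen_level")["nitrogen_rate"].mean().sort_values()
        else:
            known = ["low", "medium", "high"]
            levels = [l for l in known if l in set(grp["nitrogen_level"])]
            order = pd.Series(range(len(levels)), index=levels)
        if len(order) < 2:
            continue
        stat = getattr(grp.groupby("nitrogen_level")[trait], statistic)()
        vals = stat.reindex(order.index).to_numpy()
        if np.all(np.diff(vals) > 0):
            out.append(ly)
    return sorted(out)


def nitrogen_plasticity(
    data: TrialDataset, trait: str, location_year: str
) -> pd.Series:
    """FW slopes fitted over one location-year's nitrogen environments.

    Hybrids present in fewer than two of the location-year's nitrogen
    environments are dropped (they cannot support a slope). Slopes use
    the same +1 convention as the overall FW fit.
    """
    sub = data.obs[data.obs["location_year"] == location_year]
    if sub.empty:
        raise DataError(f"unknown location-year {location_year!r}")
    if sub["environment"].nunique() < 2:
        raise DesignError(
            f"location-year {location_year!r} has < 2 nitrogen environments"
        )
    from dataclasses import replace
    fit = fit_fw(replace(data, obs=sub.copy()), trait)
    return fit.slopes.rename(location_year)


def nitrogen_plasticity_table(
    data: TrialDataset,
    trait: str,
    location_years: list[str] | None = None,
    require_complete: bool = True,
) -> NitrogenPlasticityTable:
    """Nitrogen slopes for every qualifying location-year, plus MNP."""
    if location_years is None:
        location_years = qualifying_location_years(data, trait)
    if not location_years:
        return NitrogenPlasticityTable(
            trait=trait, slopes=pd.DataFrame(),
            qualifying_location_years=[], require_complete=require_complete,
        )
    cols = [nitrogen_plasticity(data, trait, ly) for ly in location_years]
    slopes = pd.concat(cols, axis=1)
    return NitrogenPlasticityTable(
        trait=trait,
        slopes=slopes,
        qualifying_location_years=list(location_years),
        require_complete=require_complete,
    )


def cross_locationyear_correlation(table: NitrogenPlasticityTable) -> pd.DataFrame:
    """Spearman correlation matrix of nitrogen slopes across location-years.

    Each pairwise rho uses the hybrids with slopes in both location-years
    (complete observations); pairs sharing fewer than three hybrids are
    reported as missing. The matrix is symmetric with unit diagonal.
    """
    lys = list(table.slopes.columns)
    if len(lys) < 2:
        raise DesignError("cross-location-year correlation needs >= 2 location-years")
    out = pd.DataFrame(np.eye(len(lys)), index=lys, columns=lys)
    for i, a in enumerate(lys):
        for j in range(i + 1, len(lys)):
            b = lys[j]
            common = table.slopes[[a, b]].dropna()
            if len(common) < MIN_COMMON_HYBRIDS:
                rho = np.nan
            else:
                rho = float(spearmanr(common[a], common[b]).statistic)
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def _split_halves(
    obs: pd.DataFrame, mode: str, seed: int | None
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Assign each environment's blocks to half A / half B.

    ``mode='blocks'``: lowest block id -> A, second -> B (deterministic).
    ``mode='random'``: a seeded random block-to-half assignment per
    environment, for sensitivity checks. Environments with < 2 blocks
    are excluded with a warning.
    """
    rng = np.random.default_rng(seed)
    a_parts, b_parts, excluded = [], [], []
    for env, grp in obs.groupby("environment"):
        blocks = sorted(grp["block"].unique())
        if len(blocks) < 2:
            excluded.append(env)
            continue
        if mode == "random":
            blocks = list(rng.permutation(blocks))
        half = len(blocks) // 2
        a_blocks, b_blocks = set(blocks[:half]), set(blocks[half:])
        a_parts.append(grp[grp["block"].isin(a_blocks)])
        b_parts.append(grp[grp["block"].isin(b_blocks)])
    if not a_parts:
        raise DesignError("no environment has >= 2 blocks; cannot split")
    if excluded:
        logger.warning("split-block excluded %d single-block environment(s)", len(excluded))
    return pd.concat(a_parts), pd.concat(b_parts), excluded


def split_block_repeatability(
    data: TrialDataset,
    trait: str,
    scope: str = "all",
    exclude_environments: tuple = (),
    mode: str = "blocks",
    seed: int | None = None,
) -> RepeatabilityReport:
    """Split-block repeatability of FW linear plasticity.

    Fits two FW models on disjoint halves of the plots — one block of
    every in-scope environment per half — and reports the Spearman rho
    between the two slope vectors over common hybrids. ``scope`` is
    ``"all"`` (every environment; overall plasticity repeatability) or a
    location-year id (nitrogen-plasticity repeatability within that
    location-year, one block per nitrogen treatment in each half).
    """
    from dataclasses import replace

    obs = data.obs
    if scope != "all":
        obs = obs[obs["location_year"] == scope]
        if obs.empty:
            raise DataError(f"unknown location-year {scope!r}")
    half_a, half_b, _ = _split_halves(obs, mode, seed)
    fit_a = fit_fw(replace(data, obs=half_a.copy()), trait,
                   exclude_environments=exclude_environments)
    fit_b = fit_fw(replace(data, obs=half_b.copy()), trait,
                   exclude_environments=exclude_environments)
    common = fit_a.slopes.index.intersection(fit_b.slopes.index)
    if len(common) < MIN_COMMON_HYBRIDS:
        raise DataError("fewer than 3 hybrids common to both halves")
    rho = float(spearmanr(fit_a.slopes[common], fit_b.slopes[common]).statistic)
    return RepeatabilityReport(
        trait=trait,
        split_design=f"scope={scope}, mode={mode}: one half-block set per environment",
        rho=rho,
        n_hybrids=len(common),
    )


def nitrogen_split_block_repeatability(
    data: TrialDataset,
    trait: str,
    location_years: list[str] | None = None,
    mode: str = "blocks",
    seed: int | None = None,
) -> RepeatabilityReport:
    """Within-location-year repeatability of nitrogen plasticity.

    For each qualifying location-year, nitrogen plasticities are
    estimated twice with one block per nitrogen treatment per half; the
    (hybrid, location-year) slope pairs from all location-years are
    stacked into a single Spearman correlation.
    """
    if location_years is None:
        location_years = qualifying_location_years(data, trait)
    if not location_years:
        raise DesignError("no qualifying location-years for nitrogen repeatability")
    from dataclasses import replace

    xs, ys = [], []
    per_ly = {}
    for ly in location_years:
        obs = data.obs[data.obs["location_year"] == ly]
        if obs.empty:
            raise DataError(f"unknown location-year {ly!r}")
        half_a, half_b, _ = _split_halves(obs, mode, seed)
        fa = fit_fw(replace(data, obs=half_a.copy()), trait)
        fb = fit_fw(replace(data, obs=half_b.copy()), trait)
        common = fa.slopes.index.intersection(fb.slopes.index)
        if len(common) >= MIN_COMMON_HYBRIDS:
            per_ly[ly] = float(spearmanr(fa.slopes[common], fb.slopes[common]).statistic)
        xs.append(fa.slopes[common])
        ys.append(fb.slopes[common])
    x = pd.concat(xs)
    y = pd.concat(ys)
    rho = float(spearmanr(x, y).statistic)
    return RepeatabilityReport(
        trait=trait,
        split_design="one block per nitrogen treatment per half, stacked over "
                     f"{len(location_years)} location-year(s)",
        rho=rho,
        n_hybrids=len(x),
        per_location_year=per_ly,
    )


def trend_regression(
    slopes, overall_means: pd.Series, pedigree: pd.DataFrame
) -> dict:
    """Mean performance regressed on linear plasticity and breeding era.

    OLS of each hybrid's overall trait mean on its FW slope and its mean
    parent release year, with sequential (type-I) ANOVA p-values in both
    predictor orders — the reversed order gives the plasticity effect
    when controlling for release year. Returns a dict with the
    coefficient table and both ANOVA tables (as DataFrames).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if hasattr(slopes, "coef"):
        slopes = slopes.coef["slope"]
    df = pd.DataFrame({"plasticity": pd.Series(slopes), "mean": pd.Series(overall_means)})
    ped = pedigree.set_index("hybrid")
    df = df.join(ped["mean_parent_release_year"].rename("release_year"), how="inner")
    df = df.dropna()
    if len(df) < 10:
        raise DataError("trend regression needs >= 10 hybrids with all three values")
    if df["plasticity"].std() < 1e-12 or df["release_year"].std() < 1e-12:
        raise EstimationError("a predictor is constant: rank-deficient design")
    fit = smf.ols("mean ~ plasticity + release_year", df).fit()
    fit_rev = smf.ols("mean ~ release_year + plasticity", df).fit()
    coef = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    anova_fwd = sm.stats.anova_lm(fit, typ=1)
    anova_rev = sm.stats.anova_lm(fit_rev, typ=1)
    return {
        "coefficients": coef,
        "anova_plasticity_first": anova_fwd,
        "anova_release_year_first": anova_rev,
        "n_hybrids": len(df),
    }
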