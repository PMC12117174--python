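"""Finlay-Wilkinson joint regression and derived plasticity statistics.

Finlay-Wilkinson (FW) regression summarizes a genotype's reaction norm
by regressing its per-environment performance on an environment index —
the population-level mean performance in each environment. The slope is
the *linear plasticity* of the genotype, reported here in the direct
parameterization where the population-average response equals 1
(equivalent to fitting environment-mean deviations and adding 1 to the
deviation slope): b > 1 marks hybrids more responsive than average to
improved environments, b < 1 more stable ones.

The module implements the classical two-step estimator — environment
index = environment mean of all plots, then per-hybrid ordinary least
squares — which is deterministic and matches the verbal definition of
joint regression. An optional alternating-least-squares refinement
re-estimates the index from the model itself. On top of the fit it
provides: predicted rank-order changes between the poorest and best
environments, plasticity on a percent-of-environment-mean basis, and an
overall hybrid ranking from a mixed-model BLUP with environment as a
fixed effect.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    DataError,
    DesignError,
    EstimationError,
    TrialDataset,
    match_environments,
)

logger = logging.getLogger("metplast")

#: Fitted-value differences smaller than this (trait units) are treated
#: as ties and never count as rank changes.
RANK_TIE_EPS = 1e-9


@dataclass
class FWFit:
    """Result of a Finlay-Wilkinson joint regression for one trait.

    ``env_index`` maps each environment to its population-level mean
    performance h_j. ``coef`` holds one row per hybrid: ``intercept``
    (a_i, trait units), ``slope`` (b_i, unitless, centered near 1) and
    ``n_env``. ``cell_means`` are the per (hybrid, environment) means
    the regression was fit to. Hybrids observed in fewer than two
    environments are listed in ``excluded_hybrids``.
    """

    trait: str
    env_index: pd.Series
    coef: pd.DataFrame
    cell_means: pd.DataFrame
    excluded_hybrids: list = field(default_factory=list)
    n_iterations: int = 0

    @property
    def hybrids(self) -> list[str]:
        return list(self.coef.index)

    @property
    def environments(self) -> list[str]:
        return list(self.env_index.index)

    @property
    def slopes(self) -> pd.Series:
        return self.coef["slope"]

    def fitted(self, hybrid: str, environment: str) -> float:
        """Regression-fitted value a_i + b_i * h_j — defined for every
        hybrid x environment pair in the fit's span, including
        environments where the hybrid was absent."""
        row = self.coef.loc[hybrid]
        return float(row["intercept"] + row["slope"] * self.env_index[environment])

    def fitted_matrix(self) -> pd.DataFrame:
        a = self.coef["intercept"].to_numpy()[:, None]
        b = self.coef["slope"].to_numpy()[:, None]
        h = self.env_index.to_numpy()[None, :]
        return pd.DataFrame(a + b * h, index=self.coef.index, columns=self.env_index.index)


@dataclass
class RankChangeReport:
    """Predicted rank-order changes between the extreme environments."""

    trait: str
    low_env: str
    high_env: str
    pairs: pd.DataFrame  # hybrid_a, hybrid_b, diff_low, diff_high, changes, gap_high
    gap_threshold: float

    @property
    def pairs_evaluated(self) -> int:
        return int(len(self.pairs))

    @property
    def pairs_changing_rank(self) -> int:
        return int(self.pairs["changes"].sum())

    @property
    def fraction_changing(self) -> float:
        return self.pairs_changing_rank / self.pairs_evaluated if len(self.pairs) else 0.0

    @property
    def fraction_changing_above_gap(self) -> float:
        """Among rank-changing pairs, the fraction whose fitted-yield gap
        in the best environment exceeds the gap threshold."""
        ch = self.pairs[self.pairs["changes"]]
        if ch.empty:
            return 0.0
        return float((ch["gap_high"] > self.gap_threshold).mean())


@dataclass
class PercentMeanPlasticity:
    """Plasticity of performance expressed as percent of environment mean."""

    trait: str
    table: pd.DataFrame  # per hybrid: slope_pct, mean_pct_performance, n_env


def _restrict(data: TrialDataset, trait: str, exclude_environments) -> pd.DataFrame:
    if trait not in data.obs.columns:
        raise ConfigError(f"unknown trait {trait!r}")
    df = data.obs[["hybrid", "environment", trait]].dropna(subset=[trait])
    if exclude_environments:
        excl = match_environments(data, exclude_environments)
        df = df[~df["environment"].isin(excl)]
    if df.empty:
        raise DataError(f"no observations for trait {trait!r} after exclusions")
    return df


def fit_fw(
    data: TrialDataset,
    trait: str,
    exclude_environments: tuple = (),
    refine: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> FWFit:
    """Fit the Finlay-Wilkinson joint regression for one trait.

    The environment index h_j is the mean of all plot values of the
    trait in environment j (over the hybrids present there); each
    hybrid's per-environment means are then regressed on h_j by OLS.
    Slopes are reported directly (population slope = 1). Low-yield
    outlier environments can be excluded by id, location-year, or
    ``"Location:year"`` pattern before indexing.

    With ``refine=True`` the index is re-estimated from the fitted model
    by alternating least squares (index update given slopes, slope
    update given index, rescaled so the presence-weighted mean slope is
    1), iterated to ``tol`` or ``max_iter``.
    """
    df = _restrict(data, trait, exclude_environments)
    if df["environment"].nunique() < 2:
        raise DesignError("FW regression needs >= 2 environments after exclusions")

    h = df.groupby("environment")[trait].mean().sort_index()
    if float(h.max() - h.min()) < 1e-12:
        raise DesignError("environment index is constant; joint regression is degenerate")
    cell = (
        df.groupby(["hybrid", "environment"])[trait]
        .mean()
        .rename("mean")
        .reset_index()
    )

    coef, excluded = _per_hybrid_ols(cell, h)
    n_iter = 0
    if refine:
        h, coef, n_iter = _als_refine(cell, h, coef, tol, max_iter)
    if excluded:
        logger.warning(
            "excluded %d hybrid(s) with < 2 environments for trait %r",
            len(excluded), trait,
        )
    return FWFit(
        trait=trait,
        env_index=h,
        coef=coef,
        cell_means=cell,
        excluded_hybrids=excluded,
        n_iterations=n_iter,
    )


def _per_hybrid_ols(cell: pd.DataFrame, h: pd.Series):
    x_all = cell["environment"].map(h).to_numpy()
    y_all = cell["mean"].to_numpy()
    codes, hybrids = cell["hybrid"].factorize(sort=True)
    rows, excluded = [], []
    for gi, hyb in enumerate(hybrids):
        sel = codes == gi
        x, y = x_all[sel], y_all[sel]
        if len(x) < 2 or float(x.max() - x.min()) < 1e-12:
            excluded.append(hyb)
            continue
        xm, ym = x.mean(), y.mean()
        sxx = float(((x - xm) ** 2).sum())
        slope = float(((x - xm) * (y - ym)).sum()) / sxx
        rows.append((hyb, ym - slope * xm, slope, len(x)))
    if not rows:
        raise DesignError("no hybrid present in >= 2 environments")
    coef = pd.DataFrame(rows, columns=["hybrid", "intercept", "slope", "n_env"])
    return coef.set_index("hybrid"), excluded


def _als_refine(cell, h, coef, tol, max_iter):
    """Alternating least squares on the joint regression.

    Given slopes/intercepts, the index minimizing the residual sum of
    squares for environment j is
    h_j = sum_i b_i (ybar_ij - a_i) / sum_i b_i^2; the identification
    (location/scale of h) is pinned by rescaling so the
    presence-weighted mean slope is 1 and mean(h) is unchanged.
    """
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        merged = cell.join(coef, on="hybrid", how="inner")
        num = (merged["slope"] * (merged["mean"] - merged["intercept"])).groupby(
            merged["environment"]
        ).sum()
        den = (merged["slope"] ** 2).groupby(merged["environment"]).sum()
        h_new = (num / den).sort_index()
        coef_new, _ = _per_hybrid_ols(cell, h_new)
        w = coef_new["n_env"]
        b_bar = float((coef_new["slope"] * w).sum() / w.sum())
        mean_h = float(h_new.mean())
        h_new = mean_h + (h_new - mean_h) * b_bar
        coef_new, _ = _per_hybrid_ols(cell, h_new)
        delta = float(np.max(np.abs(h_new - h.reindex(h_new.index))))
        h, coef = h_new, coef_new
        if delta < tol:
            break
    return h, coef, n_iter


def predict_rank_changes(
    fit: FWFit, gap_threshold: float = 0.63, tie_eps: float = RANK_TIE_EPS
) -> RankChangeReport:
    """Predict hybrid-pair rank-order changes between the lowest- and
    highest-index environments from the regression-fitted values.

    A pair changes rank iff the sign of the fitted difference flips
    between the two extreme environments; differences within ``tie_eps``
    at either endpoint count as no change. ``gap_threshold`` (trait
    units; 0.63 MT/ha is the 10 bu/acre convention for yield) feeds the
    among-changing-pairs gap fraction.
    """
    if len(fit.env_index) < 2:
        raise DesignError("rank-change prediction needs >= 2 environments")
    low_env = fit.env_index.idxmin()
    high_env = fit.env_index.idxmax()
    a = fit.coef["intercept"].to_numpy()
    b = fit.coef["slope"].to_numpy()
    f_low = a + b * float(fit.env_index[low_env])
    f_high = a + b * float(fit.env_index[high_env])
    hybrids = np.array(fit.hybrids)
    ia, ib = np.triu_indices(len(hybrids), k=1)
    d_low = f_low[ia] - f_low[ib]
    d_high = f_high[ia] - f_high[ib]
    changes = (np.abs(d_low) > tie_eps) & (np.abs(d_high) > tie_eps) & (d_low * d_high < 0)
    pairs = pd.DataFrame(
        {
            "hybrid_a": hybrids[ia],
            "hybrid_b": hybrids[ib],
            "fitted_low_a": f_low[ia],
            "fitted_low_b": f_low[ib],
            "fitted_high_a": f_high[ia],
            "fitted_high_b": f_high[ib],
            "diff_low": d_low,
            "diff_high": d_high,
            "changes": changes,
            "gap_high": np.abs(d_high),
        }
    )
    return RankChangeReport(
        trait=fit.trait,
        low_env=low_env,
        high_env=high_env,
        pairs=pairs,
        gap_threshold=gap_threshold,
    )


def percent_mean_plasticity(
    data: TrialDataset, trait: str, exclude_environments: tuple = ()
) -> PercentMeanPlasticity:
    """Linear plasticity of performance as a percentage of environment mean.

    Each plot's response is 100 * value / (environment mean of the
    trait). A hybrid's ``slope_pct`` is its regression slope of this
    percent response on the environment mean, plus 1 — identical to the
    hybrid-by-environment-mean interaction coefficient plus the shared
    environment-mean coefficient plus 1 in the single interaction model,
    and centered near 1 for the population. A hybrid sitting exactly at
    the environment mean everywhere has slope_pct = 1 and
    mean_pct_performance = 100.
    """
    df = _restrict(data, trait, exclude_environments)
    if df["environment"].nunique() < 2:
        raise DesignError("percent-mean plasticity needs >= 2 environments")
    m = df.groupby("environment")[trait].mean()
    if (m <= 0).any():
        raise DataError("environment means must be positive for percent-of-mean response")
    df = df.assign(_m=df["environment"].map(m), _pct=lambda d: 100.0 * d[trait] / d["_m"])

    rows, excluded = [], []
    for hyb, grp in df.groupby("hybrid"):
        x = grp["_m"].to_numpy()
        if grp["environment"].nunique() < 2:
            excluded.append(hyb)
            continue
        y = grp["_pct"].to_numpy()
        xm, ym = x.mean(), y.mean()
        sxx = float(((x - xm) ** 2).sum())
        if sxx < 1e-12:
            excluded.append(hyb)
            continue
        slope = float(((x - xm) * (y - ym)).sum()) / sxx
        mean_pct = float(grp.groupby("environment")["_pct"].mean().mean())
        rows.append((hyb, slope + 1.0, mean_pct, grp["environment"].nunique()))
    table = pd.DataFrame(
        rows, columns=["hybrid", "slope_pct", "mean_pct_performance", "n_env"]
    ).set_index("hybrid")
    if excluded:
        logger.warning("percent-mean plasticity excluded %d hybrid(s)", len(excluded))
    return PercentMeanPlasticity(trait=trait, table=table)


def blup_rank(
    data: TrialDataset, trait: str, exclude_environments: tuple = ()
) -> pd.DataFrame:
    """Overall hybrid ranking by genotype BLUP.

    Fits a mixed model with environment as a fixed effect and genotype
    as a random effect (REML) and ranks hybrids in ascending order of
    their predicted genotype effects — rank 1 is the minimum BLUP. Ties
    are broken lexicographically by hybrid id.

    Returns a DataFrame indexed by hybrid with columns ``blup`` and
    ``rank``.
    """
    import statsmodels.formula.api as smf

    df = _restrict(data, trait, exclude_environments).rename(columns={trait: "y"})
    if df["hybrid"].nunique() < 2:
        raise DesignError("BLUP ranking needs >= 2 hybrids")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm("y ~ C(environment)", df, groups=df["hybrid"])
            res = model.fit(reml=True)
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise EstimationError(f"BLUP mixed model failed: {exc}") from exc
    blups = pd.Series(
        {k: float(v.iloc[0]) for k, v in res.random_effects.items()}, name="blup"
    )
    out = blups.rename_axis("hybrid").reset_index().sort_values(
        ["blup", "hybrid"], kind="mergesort"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("hybrid")
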