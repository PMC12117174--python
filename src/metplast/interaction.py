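"""Interaction-importance scoring of hybrid pairs across environment pairs.

A genotype-by-environment interaction only matters for selection when it
flips the rank order of two hybrids between environments *and* the
hybrids are distinguishable in at least one of them. The scoring
procedure quantifies this per hybrid pair:

1. In every environment, a one-way ANOVA with genotype as the sole
   predictor pools within-genotype variance, and Tukey's HSD
   (Tukey-Kramer under unequal replication) tests all pairwise mean
   differences at alpha = 0.05.
2. For every pair of environments in which both hybrids were present,
   the pair scores 0 if their mean rank order is unchanged; if the order
   flips, the score is the number of the two environments (0, 1, or 2)
   in which the pair differed significantly.
3. Scores are summed over all environment pairs and normalized by the
   total possible score n_E x (n_E - 1), where n_E is the number of
   environments in which the pair co-occurred (two points per
   environment pair).

A normalized score of 0 means no selection-relevant interaction; scores
approaching 1 mean the pair's ranking reverses verifiably almost
everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .core import DataError, DesignError, TrialDataset, match_environments

logger = logging.getLogger("metplast")

#: Mean differences below this (trait units) are exact ties: a tie
#: cannot evidence a crossover, so tied pairs never change rank.
MEAN_TIE_EPS = 1e-9


@dataclass
class PairwiseSignificance:
    """All-pairs Tukey HSD result within one environment."""

    environment: str
    trait: str
    alpha: float
    means: pd.Series              # per-hybrid mean
    n_plots: pd.Series            # per-hybrid replication
    table: pd.DataFrame           # hybrid_a, hybrid_b, diff, p_adj, significant
    mse: float
    df_resid: int
    n_groups: int

    def significant(self, hybrid_a: str, hybrid_b: str) -> bool:
        a, b = sorted((hybrid_a, hybrid_b))
        row = self.table[(self.table["hybrid_a"] == a) & (self.table["hybrid_b"] == b)]
        if row.empty:
            raise DataError(f"pair ({hybrid_a}, {hybrid_b}) not in {self.environment}")
        return bool(row["significant"].iloc[0])


@dataclass
class PairScoreMatrix:
    """Raw and normalized interaction-importance scores per hybrid pair."""

    trait: str
    alpha: float
    pairs: pd.DataFrame  # hybrid_a, hybrid_b, n_env, raw_score, max_score, normalized
    detail: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> dict:
        """Distribution summaries over pairs with a defined score
        (pairs co-occurring in >= 2 environments)."""
        defined = self.pairs.dropna(subset=["normalized"])
        n = len(defined)
        out = {
            "n_pairs": int(len(self.pairs)),
            "n_pairs_defined": n,
            "n_pairs_undefined": int(len(self.pairs) - n),
        }
        if n:
            norm = defined["normalized"]
            out.update(
                {
                    "fraction_zero": float((norm == 0).mean()),
                    "fraction_lt_5pct": float((norm < 0.05).mean()),
                    "fraction_ge_10pct": float((norm >= 0.10).mean()),
                    "fraction_ge_20pct": float((norm >= 0.20).mean()),
                }
            )
        return out


def _tukey_table(values: pd.Series, groups: pd.Series, alpha: float,
                 pvalues: bool = True):
    """Tukey-Kramer all-pairs comparison from plot values.

    Returns (means, n_per_group, table, mse, df_resid, k). The
    studentized-range statistic for a pair is
    q = |m_a - m_b| / sqrt(MSE/2 * (1/n_a + 1/n_b)) with k = number of
    genotypes and the one-way ANOVA residual df. With ``pvalues=False``
    significance is decided against the single critical value
    q_crit = isf(alpha; k, df) and adjusted p-values are not computed
    (orders of magnitude faster when only the alpha decision is needed,
    as in all-pairs scoring; the decisions are identical because the
    studentized-range sf is monotone in q).
    """
    means = values.groupby(groups).mean().sort_index()
    ns = values.groupby(groups).size().sort_index()
    k = len(means)
    if k < 2:
        raise DesignError("Tukey comparison needs >= 2 genotypes")
    n_total = int(ns.sum())
    df_resid = n_total - k
    if df_resid < 1:
        raise DesignError("zero residual degrees of freedom in one-way ANOVA")
    resid = values - means.reindex(groups).to_numpy()
    mse = float((resid**2).sum()) / df_resid

    hybrids = means.index.to_numpy()
    m = means.to_numpy()
    n = ns.to_numpy(float)
    ia, ib = np.triu_indices(k, 1)
    diff = m[ia] - m[ib]
    se = np.sqrt(mse / 2.0 * (1.0 / n[ia] + 1.0 / n[ib]))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.abs(diff) / se
    if pvalues:
        # Degenerate pooled variance: identical replicates give se = 0.
        p = np.where(
            se > 0,
            studentized_range.sf(np.where(se > 0, q, 0.0), k, df_resid),
            np.where(np.abs(diff) > MEAN_TIE_EPS, 0.0, 1.0),
        )
        p = np.clip(p, 0.0, 1.0)
        significant = p < alpha
    else:
        q_crit = float(studentized_range.isf(alpha, k, df_resid))
        significant = np.where(
            se > 0, q > q_crit, np.abs(diff) > MEAN_TIE_EPS
        )
        p = np.full_like(q, np.nan)
    table = pd.DataFrame(
        {
            "hybrid_a": hybrids[ia],
            "hybrid_b": hybrids[ib],
            "diff": diff,
            "p_adj": p,
            "significant": significant,
        }
    )
    return means, ns, table, mse, df_resid, k


def tukey_pairwise(
    data: TrialDataset, trait: str, environment: str, alpha: float = 0.05
) -> PairwiseSignificance:
    """One-way ANOVA + Tukey HSD over all hybrid pairs in one environment."""
    df = data.obs[data.obs["environment"] == environment][["hybrid", trait]].dropna()
    if df.empty:
        raise DataError(f"no observations for {trait!r} in {environment!r}")
    means, ns, table, mse, df_resid, k = _tukey_table(df[trait], df["hybrid"], alpha)
    return PairwiseSignificance(
        environment=environment,
        trait=trait,
        alpha=alpha,
        means=means,
        n_plots=ns,
        table=table,
        mse=mse,
        df_resid=df_resid,
        n_groups=k,
    )


def score_pair_environmentpair(
    mean_a_env1: float,
    mean_b_env1: float,
    mean_a_env2: float,
    mean_b_env2: float,
    significant_env1: bool,
    significant_env2: bool,
    tie_eps: float = MEAN_TIE_EPS,
) -> int:
    """Score one hybrid pair in one environment pair (0, 1, or 2).

    0 if the mean rank order of the two hybrids is the same in both
    environments (exact ties count as no change); otherwise the number
    of the two environments in which the pair differs significantly.
    """
    d1 = mean_a_env1 - mean_b_env1
    d2 = mean_a_env2 - mean_b_env2
    if abs(d1) <= tie_eps or abs(d2) <= tie_eps or d1 * d2 > 0:
        return 0
    return int(significant_env1) + int(significant_env2)


def score_all_pairs(
    data: TrialDataset,
    trait: str,
    alpha: float = 0.05,
    exclude_environments: tuple = (),
    detail: bool = False,
) -> PairScoreMatrix:
    """Interaction-importance scores for every unordered hybrid pair.

    For each pair, n_E counts the environments where both hybrids have
    data for the trait; all C(n_E, 2) environment pairs are scored and
    the raw sum is divided by n_E x (n_E - 1). Pairs with n_E < 2 get an
    undefined (NaN) normalized score and are excluded from the
    distribution summaries. With ``detail=True`` a per-environment-pair
    score table is attached (quadratic in environments — intended for
    small analyses).
    """
    df = data.obs[["hybrid", "environment", trait]].dropna(subset=[trait])
    if exclude_environments:
        excl = match_environments(data, exclude_environments)
        df = df[~df["environment"].isin(excl)]
    envs = sorted(df["environment"].unique())
    if len(envs) < 2:
        raise DesignError("interaction scoring needs >= 2 environments")
    hybrids = sorted(df["hybrid"].unique())
    nh, ne = len(hybrids), len(envs)
    hidx = {h: i for i, h in enumerate(hybrids)}

    M = np.full((nh, ne), np.nan)
    S = np.zeros((nh, nh, ne), dtype=bool)
    for j, env in enumerate(envs):
        sub = df[df["environment"] == env]
        means, ns, table, *_ = _tukey_table(
            sub[trait], sub["hybrid"], alpha, pvalues=False
        )
        for h, mval in means.items():
            M[hidx[h], j] = mval
        sig = table[table["significant"]]
        for ha, hb in zip(sig["hybrid_a"], sig["hybrid_b"]):
            S[hidx[ha], hidx[hb], j] = True
            S[hidx[hb], hidx[ha], j] = True

    present = ~np.isnan(M)
    n_env_pair = present.astype(int) @ present.astype(int).T
    raw = np.zeros((nh, nh), dtype=int)
    detail_rows = []
    for j1 in range(ne):
        for j2 in range(j1 + 1, ne):
            d1 = M[:, j1][:, None] - M[:, j1][None, :]
            d2 = M[:, j2][:, None] - M[:, j2][None, :]
            with np.errstate(invalid="ignore"):
                change = (
                    (np.abs(d1) > MEAN_TIE_EPS)
                    & (np.abs(d2) > MEAN_TIE_EPS)
                    & (d1 * d2 < 0)
                )
            change &= present[:, j1][:, None] & present[:, j1][None, :]
            change &= present[:, j2][:, None] & present[:, j2][None, :]
            score = np.where(
                change, S[:, :, j1].astype(int) + S[:, :, j2].astype(int), 0
            )
            raw += score
            if detail:
                ia, ib = np.triu_indices(nh, 1)
                both = (
                    present[:, j1][ia] & present[:, j1][ib]
                    & present[:, j2][ia] & present[:, j2][ib]
                )
                for t in np.flatnonzero(both):
                    detail_rows.append(
                        (
                            hybrids[ia[t]], hybrids[ib[t]], envs[j1], envs[j2],
                            int(score[ia[t], ib[t]]), bool(change[ia[t], ib[t]]),
                        )
                    )

    ia, ib = np.triu_indices(nh, 1)
    n_e = n_env_pair[ia, ib]
    max_score = n_e * (n_e - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(max_score > 0, raw[ia, ib] / max_score, np.nan)
    pairs = pd.DataFrame(
        {
            "hybrid_a": np.array(hybrids)[ia],
            "hybrid_b": np.array(hybrids)[ib],
            "n_env": n_e,
            "raw_score": raw[ia, ib],
            "max_score": max_score,
            "normalized": normalized,
        }
    )
    detail_df = pd.DataFrame(
        detail_rows,
        columns=["hybrid_a", "hybrid_b", "env_a", "env_b", "score", "rank_change"],
    ) if detail else pd.DataFrame()
    return PairScoreMatrix(trait=trait, alpha=alpha, pairs=pairs, detail=detail_df)
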