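"""Variance partitioning for multi-environment trials.

Two random-effects decompositions are provided:

* :func:`partition_gxe` — plot values decomposed into genotype,
  environment, genotype-by-environment interaction, and plot residual
  (all independent Gaussian random effects), with proportions of total
  phenotypic variance per component.
* :func:`partition_gca_of_plasticity` — per-hybrid linear plasticity
  values decomposed into ear-parent and pollen-parent random effects
  (general combining ability) plus residual; the parental GCA
  proportion is the sum of the two parental proportions, which is how
  parents used on both sides of crosses are accounted for.

Both are estimated by REML. For the plot-level model the likelihood is
evaluated exactly through an orthogonal split of the data into
within-cell replicate contrasts (which depend only on the residual
variance) and cell means (whose covariance involves all components),
with Woodbury identities keeping every solve at the size of the number
of genotypes plus environments. This makes a study-sized fit
(hundreds of hybrids x tens of environments x 2 blocks) essentially
instant, which a naive n x n covariance formulation is not.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .core import DataError, DesignError, EstimationError, TrialDataset

logger = logging.getLogger("metplast")

_REML_MAX_ITER = 200
_REML_TOL = 1e-8
#: Variances below this fraction of total are reported as exactly 0
#: (REML boundary).
_BOUNDARY_FRACTION = 1e-6


@dataclass
class VarianceDecomposition:
    """Proportions of phenotypic variance attributed to named effects.

    ``components`` maps each of ``genotype``, ``environment``, ``gxe``,
    ``residual`` to ``{"variance": ..., "proportion": ...}``. Total
    phenotypic variance is the sum of the four estimated variances;
    proportions are non-negative and sum to 1.
    """

    trait: str
    components: dict
    converged: bool = True
    boundary: bool = False

    @property
    def proportions(self) -> dict:
        return {k: v["proportion"] for k, v in self.components.items()}


@dataclass
class GCADecomposition:
    """GCA decomposition of per-hybrid plasticity values."""

    trait: str
    components: dict  # ear_parent / pollen_parent / residual
    n_hybrids: int = 0
    n_excluded_checks: int = 0
    converged: bool = True

    @property
    def parental_gca_proportion(self) -> float:
        return (
            self.components["ear_parent"]["proportion"]
            + self.components["pollen_parent"]["proportion"]
        )


# ---------------------------------------------------------------------------
# REML engine
# ---------------------------------------------------------------------------

def _minimize_reml(neg2, x0, bounds):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            neg2, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": _REML_MAX_ITER, "ftol": _REML_TOL},
        )
        if not res.success:
            res2 = optimize.minimize(
                neg2, res.x, method="Nelder-Mead",
                options={"maxiter": 2000, "fatol": 1e-9, "xatol": 1e-9},
            )
            if res2.fun <= res.fun:
                res = res2
    return res


def _gxe_neg2_reml(phi, n_cell, hc, ec, a, b, y, ss_w, df_w):
    """-2 REML log-likelihood (up to a constant) of the plot-level model.

    ``phi`` = log(vg, ve, vh, vr). Cell-mean covariance is
    D + vg Zg Zg' + ve Ze Ze' with D = diag(vh + vr / n_cell); the
    replicate contrasts contribute df_w * log(vr) + ss_w / vr.
    """
    vg, ve, vh, vr = np.exp(phi)
    d = vh + vr / n_cell
    dinv = 1.0 / d
    # A = Z' D^-1 Z + G^-1 with Z = [Zg Ze]; Zg'D^-1 Zg and Ze'D^-1 Ze
    # are diagonal because each cell has exactly one hybrid and one env.
    A = np.zeros((a + b, a + b))
    A[np.arange(a), np.arange(a)] = np.bincount(hc, weights=dinv, minlength=a) + 1.0 / vg
    A[a + np.arange(b), a + np.arange(b)] = (
        np.bincount(ec, weights=dinv, minlength=b) + 1.0 / ve
    )
    cross = np.zeros((a, b))
    np.add.at(cross, (hc, ec), dinv)
    A[:a, a:] = cross
    A[a:, :a] = cross.T
    try:
        cho = linalg.cho_factor(A, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet_A = 2.0 * np.log(np.diag(cho[0])).sum()
    logdet_V = logdet_A + a * np.log(vg) + b * np.log(ve) + np.log(d).sum()

    def vinv(v):
        t = np.concatenate(
            [
                np.bincount(hc, weights=dinv * v, minlength=a),
                np.bincount(ec, weights=dinv * v, minlength=b),
            ]
        )
        s = linalg.cho_solve(cho, t, check_finite=False)
        return dinv * v - dinv * (s[:a][hc] + s[a:][ec])

    viy = vinv(y)
    vi1 = vinv(np.ones_like(y))
    xvix = vi1.sum()
    if xvix <= 0:
        return 1e12
    xviy = viy.sum()
    quad = float(y @ viy) - xviy**2 / xvix
    return (
        df_w * np.log(vr) + ss_w / vr
        + logdet_V + np.log(xvix) + quad
    )


def partition_gxe(data: TrialDataset, trait: str) -> VarianceDecomposition:
    """REML variance partition of plot values into G, E, GxE and residual.

    Requires at least two genotypes, two environments, and some
    within-cell replication (without replicates the interaction and the
    plot residual are confounded). Negative components are handled by
    the log parameterization: they shrink to the boundary and are
    reported as zero variance.
    """
    if trait not in data.obs.columns:
        raise DataError(f"unknown trait {trait!r}")
    df = data.obs[["hybrid", "environment", trait]].dropna(subset=[trait])
    if df["hybrid"].nunique() < 2 or df["environment"].nunique() < 2:
        raise DesignError("variance partition needs >= 2 genotypes and >= 2 environments")
    grp = df.groupby(["hybrid", "environment"])[trait]
    cells = grp.agg(n="size", mean="mean").reset_index()
    ss_w = float(((df[trait] - grp.transform("mean")) ** 2).sum())
    df_w = int((cells["n"] - 1).sum())
    if df_w < 1:
        raise EstimationError(
            "no within-cell replication: interaction and residual are confounded"
        )

    y = cells["mean"].to_numpy(float)
    hc, hybrids = cells["hybrid"].factorize(sort=True)
    ec, envs = cells["environment"].factorize(sort=True)
    a, b = len(hybrids), len(envs)
    n_cell = cells["n"].to_numpy(float)

    s2 = float(df[trait].var())
    if s2 <= 0:
        raise EstimationError("trait has zero variance")
    vr0 = max(ss_w / df_w, s2 * 1e-4)
    v0 = max((s2 - vr0) / 3.0, s2 * 1e-3)
    x0 = np.log([v0, v0, v0 / 2.0, vr0])
    lo, hi = np.log(s2 * 1e-8), np.log(s2 * 1e4)
    res = _minimize_reml(
        lambda phi: _gxe_neg2_reml(phi, n_cell, hc, ec, a, b, y, ss_w, df_w),
        x0, [(lo, hi)] * 4,
    )
    v = np.exp(res.x)
    total = v.sum()
    boundary = bool((v / total < _BOUNDARY_FRACTION).any())
    v = np.where(v / total < _BOUNDARY_FRACTION, 0.0, v)
    total = v.sum()
    names = ("genotype", "environment", "gxe", "residual")
    comp = {
        nm: {"variance": float(vi), "proportion": float(vi / total)}
        for nm, vi in zip(names, v)
    }
    if not res.success:
        logger.warning("REML did not report convergence for trait %r: %s",
                       trait, res.message)
    return VarianceDecomposition(
        trait=trait, components=comp, converged=bool(res.success), boundary=boundary
    )


# ---------------------------------------------------------------------------
# GCA of plasticity
# ---------------------------------------------------------------------------

def _dense_neg2_reml(phi, y, Zs):
    """-2 REML log-likelihood with V = sum_k v_k Z_k Z_k' + vr I (dense)."""
    v = np.exp(phi)
    n = len(y)
    V = np.eye(n) * v[-1]
    for vk, Z in zip(v[:-1], Zs):
        V += vk * (Z @ Z.T)
    try:
        cho = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return 1e12
    logdet_V = 2.0 * np.log(np.diag(cho[0])).sum()
    viy = linalg.cho_solve(cho, y, check_finite=False)
    vi1 = linalg.cho_solve(cho, np.ones(n), check_finite=False)
    xvix = vi1.sum()
    if xvix <= 0:
        return 1e12
    quad = float(y @ viy) - viy.sum() ** 2 / xvix
    return logdet_V + np.log(xvix) + quad


def partition_gca_of_plasticity(
    slopes, pedigree: pd.DataFrame, trait: str = ""
) -> GCADecomposition:
    """Partition per-hybrid plasticity into parental GCA components.

    ``slopes`` is either an :class:`~metplast.fw.FWFit` or a Series of
    per-hybrid slopes indexed by hybrid id. Each hybrid's slope is
    modelled as an ear-parent effect plus a pollen-parent effect plus
    residual, all random; a parent used on both sides of different
    crosses contributes to both parental populations, and the reported
    ``parental_gca_proportion`` sums the two parental proportions.
    Hybrids without a resolvable pedigree (commercial checks) are
    excluded with a logged count.
    """
    if hasattr(slopes, "coef"):
        trait = trait or slopes.trait
        slopes = slopes.coef["slope"]
    s = pd.Series(slopes).rename("slope")
    ped = pedigree.set_index("hybrid")
    joined = s.to_frame().join(ped[["ear_parent", "pollen_parent"]], how="left")
    n_before = len(joined)
    joined = joined.dropna()
    n_checks = n_before - len(joined)
    if n_checks:
        logger.info("excluded %d hybrid(s) without resolvable parents", n_checks)
    if len(joined) < 3:
        raise DataError("too few hybrids with pedigree for GCA partition")

    y = joined["slope"].to_numpy(float)
    ear_c, ears = joined["ear_parent"].factorize(sort=True)
    pol_c, pols = joined["pollen_parent"].factorize(sort=True)
    n_parents = len(set(ears) | set(pols))
    if len(joined) < n_parents + 2:
        raise EstimationError(
            f"under-identified: {len(joined)} hybrids for {n_parents} parents"
        )
    Z_ear = np.zeros((len(y), len(ears)))
    Z_ear[np.arange(len(y)), ear_c] = 1.0
    Z_pol = np.zeros((len(y), len(pols)))
    Z_pol[np.arange(len(y)), pol_c] = 1.0

    yc = y - y.mean()
    s2 = float(np.var(yc, ddof=1))
    if s2 <= 0:
        raise EstimationError("plasticity values have zero variance")
    x0 = np.log([s2 / 3.0, s2 / 3.0, s2 / 2.0])
    lo, hi = np.log(s2 * 1e-8), np.log(s2 * 1e4)
    res = _minimize_reml(
        lambda phi: _dense_neg2_reml(phi, y, (Z_ear, Z_pol)), x0, [(lo, hi)] * 3
    )
    v = np.exp(res.x)
    total = v.sum()
    v = np.where(v / total < _BOUNDARY_FRACTION, 0.0, v)
    total = v.sum()
    names = ("ear_parent", "pollen_parent", "residual")
    comp = {
        nm: {"variance": float(vi), "proportion": float(vi / total)}
        for nm, vi in zip(names, v)
    }
    return GCADecomposition(
        trait=trait,
        components=comp,
        n_hybrids=len(joined),
        n_excluded_checks=n_checks,
        converged=bool(res.success),
    )
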