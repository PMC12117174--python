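"""End-to-end orchestration: ingest -> filter -> FW -> variance components
-> interaction scores -> repeatability -> trend, with a single config and
a deterministic results bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ConfigError,
    DataError,
    DesignError,
    MetplastError,
    TrialDataset,
    filter_min_environments,
    read_pedigree_table,
    read_plot_table,
    remove_extreme_values,
)
from .fw import blup_rank, fit_fw, percent_mean_plasticity, predict_rank_changes
from .interaction import score_all_pairs
from .nitrogen import (
    cross_locationyear_correlation,
    nitrogen_plasticity_table,
    nitrogen_split_block_repeatability,
    qualifying_location_years,
    split_block_repeatability,
    trend_regression,
)
from .varcomp import partition_gca_of_plasticity, partition_gxe

logger = logging.getLogger("metplast")


class PipelineError(MetplastError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    ``exclude_environments`` defaults to nothing; pass the low-yield
    outlier location-year (e.g. ``"Lincoln:2022"``) to mirror the usual
    practice of dropping an environment whose population mean is far
    below all others. ``min_env=3`` removes hybrids observed in fewer
    than three environments; ``gap_threshold`` is in trait units
    (0.63 MT/ha = 10 bu/acre for yield).
    """

    plot_table: str = ""
    pedigree_table: str = ""
    column_map: dict = field(default_factory=dict)
    traits: list = field(default_factory=lambda: ["yield"])
    trait: str = "yield"          # primary trait for FW / scoring stages
    exclude_environments: list = field(default_factory=list)
    alpha: float = 0.05
    min_env: int = 3
    gap_threshold: float = 0.63
    bounds: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str = ""

    def __post_init__(self) -> None:
        if not self.traits:
            raise ConfigError("trait list must be non-empty")
        if self.alpha <= 0 or self.alpha >= 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_env < 1 or self.gap_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if self.trait not in self.traits:
            self.traits = [self.trait] + [t for t in self.traits if t != self.trait]

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except MetplastError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: AnalysisConfig, data: TrialDataset | None = None) -> dict:
    """Run the full analysis; returns the results bundle as a dict.

    ``data`` may be supplied directly (e.g. from the simulator); if
    omitted the plot and pedigree tables named in the config are read.
    Deterministic given config + seed. When ``config.outdir`` is set,
    per-stage CSVs and ``summary.json`` are written there.
    """
    summary: dict = {"manifest": {
        "config_hash": config.hash(),
        "version": __version__,
        "seed": config.seed,
    }}
    tables: dict[str, pd.DataFrame] = {}
    stage = "ingest"
    try:
        if data is None:
            data = read_plot_table(config.plot_table, config.column_map)
            if config.pedigree_table:
                data.pedigree = read_pedigree_table(config.pedigree_table)
        if config.bounds:
            stage = "remove_extreme_values"
            data = remove_extreme_values(data, config.bounds)
            summary["removal_fractions"] = data.info.get("removal_fractions", {})
        stage = "filter_min_environments"
        data = filter_min_environments(data, config.min_env)
        summary["manifest"]["counts"] = data.summary()
        summary["manifest"]["removed_hybrids"] = data.info.get("removed_hybrids", [])

        trait = config.trait
        excl = tuple(config.exclude_environments)

        stage = "fw"
        fit = fit_fw(data, trait, exclude_environments=excl)
        tables["fw_slopes"] = fit.coef.reset_index()
        tables["fw_env_index"] = fit.env_index.rename("index").reset_index()

        stage = "rank_changes"
        rc = predict_rank_changes(fit, gap_threshold=config.gap_threshold)
        tables["rank_changes"] = rc.pairs
        summary["rank_changes"] = {
            "low_env": rc.low_env,
            "high_env": rc.high_env,
            "pairs_evaluated": rc.pairs_evaluated,
            "pairs_changing_rank": rc.pairs_changing_rank,
            "fraction_changing": rc.fraction_changing,
            "fraction_changing_above_gap": rc.fraction_changing_above_gap,
        }

        stage = "blup_rank"
        ranks = blup_rank(data, trait, exclude_environments=excl)
        tables["blup_ranks"] = ranks.reset_index()
        changing = rc.pairs[rc.pairs["changes"]]
        if len(changing):
            ra = ranks["rank"].reindex(changing["hybrid_a"]).to_numpy()
            rb = ranks["rank"].reindex(changing["hybrid_b"]).to_numpy()
            dist = np.abs(ra - rb)
            summary["rank_changes"]["max_overall_rank_distance"] = int(np.nanmax(dist))
        else:
            summary["rank_changes"]["max_overall_rank_distance"] = 0

        stage = "percent_mean_plasticity"
        pmp = percent_mean_plasticity(data, trait, exclude_environments=excl)
        tables["percent_mean_plasticity"] = pmp.table.reset_index()

        stage = "variance_components"
        summary["variance_components"] = {}
        for t in config.traits:
            vd = partition_gxe(data, t)
            summary["variance_components"][t] = vd.proportions

        stage = "gca"
        if len(data.pedigree):
            gca = partition_gca_of_plasticity(fit, data.pedigree, trait=trait)
            summary["gca"] = {
                "trait": trait,
                "parental_gca_proportion": gca.parental_gca_proportion,
                "components": {k: v["proportion"] for k, v in gca.components.items()},
                "n_hybrids": gca.n_hybrids,
                "n_excluded_checks": gca.n_excluded_checks,
            }

        stage = "interaction_scores"
        scores = score_all_pairs(data, trait, alpha=config.alpha,
                                 exclude_environments=excl)
        tables["interaction_scores"] = scores.pairs
        summary["interaction_scores"] = scores.summary()

        stage = "repeatability"
        try:
            rep = split_block_repeatability(data, trait, scope="all",
                                            exclude_environments=excl)
            summary["repeatability"] = {"rho": rep.rho, "n_hybrids": rep.n_hybrids,
                                        "design": rep.split_design}
        except (DataError, DesignError) as exc:
            # too few hybrids/blocks to split: report undefined, don't abort
            summary["repeatability"] = {"rho": None, "reason": str(exc)}

        stage = "nitrogen"
        qlys = qualifying_location_years(data, trait)
        summary["nitrogen"] = {"qualifying_location_years": qlys}
        if len(qlys) >= 2:
            ntab = nitrogen_plasticity_table(data, trait, qlys)
            tables["nitrogen_slopes"] = ntab.slopes.reset_index()
            tables["mnp"] = ntab.mnp.reset_index()
            rho_mat = cross_locationyear_correlation(ntab)
            summary["nitrogen"]["cross_locationyear_rho"] = {
                a: {b: (None if pd.isna(v) else float(v))
                    for b, v in row.items()}
                for a, row in rho_mat.iterrows()
            }
            nrep = nitrogen_split_block_repeatability(data, trait, qlys)
            summary["nitrogen"]["within_locationyear_rho"] = nrep.rho
            summary["nitrogen"]["per_location_year_rho"] = nrep.per_location_year

        stage = "trend"
        if len(data.pedigree) and data.pedigree["mean_parent_release_year"].notna().sum() >= 10:
            overall = data.obs.dropna(subset=[trait]).groupby("hybrid")[trait].mean()
            trend = trend_regression(fit, overall, data.pedigree)
            summary["trend"] = {
                "coefficients": trend["coefficients"].to_dict(orient="index"),
                "p_plasticity_first": float(
                    trend["anova_plasticity_first"].loc["plasticity", "PR(>F)"]
                ),
                "p_plasticity_controlling_release_year": float(
                    trend["anova_release_year_first"].loc["plasticity", "PR(>F)"]
                ),
                "p_release_year_first": float(
                    trend["anova_release_year_first"].loc["release_year", "PR(>F)"]
                ),
                "n_hybrids": trend["n_hybrids"],
            }
    except MetplastError as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tbl in tables.items():
            tbl.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float)
        )
    summary["_tables"] = tables
    return summary
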