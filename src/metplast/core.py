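"""Plot-level multi-environment trial (MET) data: containers, CSV I/O,
filtering, and agronomic unit utilities.

The atomic record is one field plot: a hybrid grown in one *environment*
(a location-year crossed with a nitrogen fertilization level) in one
replicate block, with any number of measured traits (grain yield in
MT/ha, ear and kernel traits, plant heights, thermal time to flowering).
A location-year is a unique combination of location, year, and
irrigation regime, since irrigation is usually confounded with site and
season in maize trials.

Data live in a :class:`TrialDataset`: a plot table (one row per plot,
one column per trait), a pedigree table mapping hybrids to their ear and
pollen parents and parental release years, and a trait registry carrying
units. All downstream analyses (Finlay-Wilkinson regression, variance
partitioning, interaction-importance scoring) consume this container.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("metplast")

#: Conversion factor from bushels/acre of maize grain (56-lb bushels at
#: 15.5% moisture) to metric tonnes per hectare.
BU_PER_ACRE_TO_MT_PER_HA = 0.0628

#: Base and optimum temperatures (deg C) for maize growing degree days
#: (the standard "86/50 F" method).
GDD_T_BASE_C = 10.0
GDD_T_OPT_C = 30.0

# Canonical plot-table column names. ``location_year`` and
# ``environment`` are derived identifiers, never read from disk.
ROLE_COLUMNS = (
    "hybrid",
    "location",
    "year",
    "irrigation",
    "nitrogen_level",
    "nitrogen_rate",
    "block",
    "row",
    "column",
)
REQUIRED_ROLES = ("hybrid", "location", "year", "block")


class MetplastError(Exception):
    """Base class for all package errors."""


class ConfigError(MetplastError):
    """A configuration value (column map, bounds, thresholds) is invalid."""


class DataError(MetplastError):
    """Input data are empty or structurally unusable."""


class DesignError(MetplastError):
    """The trial design cannot support the requested analysis."""


class EstimationError(MetplastError):
    """A model fit failed (non-convergence, singular design)."""


@dataclass(frozen=True)
class EnvironmentKey:
    """Identity of one trial environment.

    ``(location, year, irrigation)`` identifies a location-year; adding
    the nitrogen level identifies an environment. ``irrigation`` uses
    the field shorthand NI / LI / FI (none / limited / full) or ``""``
    when not specified; ``nitrogen_level`` is ``low`` / ``medium`` /
    ``high`` or ``""`` when the trial had a single unspecified rate.
    """

    location: str
    year: int
    irrigation: str = ""
    nitrogen_level: str = ""
    nitrogen_rate: float = float("nan")

    def __post_init__(self) -> None:
        if self.nitrogen_level and not math.isnan(self.nitrogen_rate):
            if self.nitrogen_rate <= 0:
                raise ConfigError(
                    f"nitrogen_rate must be positive when a nitrogen level is "
                    f"specified, got {self.nitrogen_rate!r} for {self.location} "
                    f"{self.year} {self.nitrogen_level}"
                )

    @property
    def location_year_id(self) -> str:
        parts = [str(self.year), self.location]
        if self.irrigation:
            parts.append(self.irrigation)
        return " ".join(parts)

    @property
    def env_id(self) -> str:
        if self.nitrogen_level:
            return f"{self.location_year_id} {self.nitrogen_level}"
        return self.location_year_id


def _derive_ids(obs: pd.DataFrame) -> pd.DataFrame:
    """Add ``location_year`` and ``environment`` identifier columns."""
    obs = obs.copy()
    ly = obs["year"].astype(int).astype(str) + " " + obs["location"].astype(str)
    irr = obs.get("irrigation")
    if irr is not None:
        irr = irr.fillna("").astype(str)
        ly = ly.where(irr == "", ly + " " + irr)
    obs["location_year"] = ly
    nl = obs.get("nitrogen_level")
    if nl is not None:
        nl = nl.fillna("").astype(str)
        obs["environment"] = ly.where(nl == "", ly + " " + nl)
    else:
        obs["environment"] = ly
    return obs


@dataclass
class TrialDataset:
    """Plot observations + pedigree + trait registry for one trial panel.

    Parameters
    ----------
    obs
        One row per plot. Canonical columns: ``hybrid``, ``location``,
        ``year``, ``block`` (required), ``irrigation``,
        ``nitrogen_level``, ``nitrogen_rate``, ``row``, ``column``
        (optional), plus one numeric column per trait. The derived
        ``location_year`` and ``environment`` id columns are added on
        construction.
    pedigree
        One row per hybrid: ``hybrid``, ``ear_parent``,
        ``pollen_parent``, ``ear_parent_release_year``,
        ``pollen_parent_release_year``, ``mean_parent_release_year``,
        ``is_check``. Commercial checks may have unknown (NaN) parents.
    trait_registry
        Mapping trait name -> unit string.
    info
        Free-form per-stage processing metadata (dropped-row counts,
        removed hybrids, outlier-removal fractions).
    """

    obs: pd.DataFrame
    pedigree: pd.DataFrame = field(default_factory=pd.DataFrame)
    trait_registry: dict = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_ROLES if c not in self.obs.columns]
        if missing:
            raise ConfigError(f"plot table is missing required columns: {missing}")
        if "environment" not in self.obs.columns:
            self.obs = _derive_ids(self.obs)
        if not self.trait_registry:
            known = set(ROLE_COLUMNS) | {"location_year", "environment"}
            self.trait_registry = {
                c: "" for c in self.obs.columns
                if c not in known and pd.api.types.is_numeric_dtype(self.obs[c])
            }

    # -- simple queries -------------------------------------------------

    @property
    def traits(self) -> list[str]:
        return list(self.trait_registry)

    @property
    def hybrids(self) -> list[str]:
        return sorted(self.obs["hybrid"].unique())

    def environments(self) -> list[str]:
        return sorted(self.obs["environment"].unique())

    def location_years(self) -> list[str]:
        return sorted(self.obs["location_year"].unique())

    def environment_keys(self) -> list[EnvironmentKey]:
        cols = ["location", "year", "irrigation", "nitrogen_level", "nitrogen_rate"]
        have = [c for c in cols if c in self.obs.columns]
        out = []
        for _, r in (
            self.obs[have + ["environment"]]
            .drop_duplicates("environment")
            .sort_values("environment")
            .iterrows()
        ):
            out.append(
                EnvironmentKey(
                    location=str(r["location"]),
                    year=int(r["year"]),
                    irrigation=str(r.get("irrigation", "") or ""),
                    nitrogen_level=str(r.get("nitrogen_level", "") or ""),
                    nitrogen_rate=float(r.get("nitrogen_rate", float("nan"))),
                )
            )
        return out

    def counts_per_environment(self) -> pd.Series:
        return self.obs.groupby("environment").size().sort_index()

    def environments_per_hybrid(self) -> pd.Series:
        return self.obs.groupby("hybrid")["environment"].nunique().sort_index()

    def summary(self) -> dict:
        return {
            "n_observations": int(len(self.obs)),
            "n_hybrids": int(self.obs["hybrid"].nunique()),
            "n_environments": int(self.obs["environment"].nunique()),
            "n_location_years": int(self.obs["location_year"].nunique()),
            "traits": list(self.trait_registry),
        }

    def validate(self) -> None:
        """Check the container's structural invariants.

        Raises :class:`DataError` if yields are non-positive or a
        non-check hybrid cannot be resolved in the pedigree (when a
        pedigree is present).
        """
        if "yield" in self.obs.columns:
            y = self.obs["yield"].dropna()
            if (y <= 0).any():
                raise DataError("yield values must be strictly positive")
        if len(self.pedigree):
            known = set(self.pedigree["hybrid"])
            unknown = set(self.obs["hybrid"]) - known
            if unknown:
                raise DataError(
                    f"{len(unknown)} hybrid(s) not resolvable in pedigree: "
                    f"{sorted(unknown)[:5]}..."
                )

    # -- subsetting -----------------------------------------------------

    def select_environments(self, env_ids: Iterable[str]) -> "TrialDataset":
        env_ids = set(env_ids)
        return replace(self, obs=self.obs[self.obs["environment"].isin(env_ids)].copy())

    def drop_environments(self, env_ids: Iterable[str]) -> "TrialDataset":
        env_ids = set(env_ids)
        return replace(self, obs=self.obs[~self.obs["environment"].isin(env_ids)].copy())


def match_environments(data: TrialDataset, patterns: Iterable[str]) -> set[str]:
    """Resolve exclusion patterns to environment ids.

    A pattern matches an environment if it equals the environment id,
    the location-year id, ``"<location>:<year>"``, or
    ``"<year> <location>"`` — so the low-yield 2022 Lincoln outlier
    location-year can be excluded as ``"Lincoln:2022"`` without naming
    its three nitrogen environments individually.
    """
    keys = data.obs[["environment", "location_year", "location", "year"]].drop_duplicates()
    out: set[str] = set()
    for pat in patterns:
        hit = (
            (keys["environment"] == pat)
            | (keys["location_year"] == pat)
            | keys["location_year"].str.startswith(pat + " ")
            | ((keys["location"].astype(str) + ":" + keys["year"].astype(str)) == pat)
            | ((keys["year"].astype(str) + " " + keys["location"].astype(str)) == pat)
        )
        matched = set(keys.loc[hit, "environment"])
        if not matched:
            logger.warning("exclusion pattern %r matched no environment", pat)
        out |= matched
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_plot_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    traits: Mapping[str, str] | Sequence[str] | None = None,
) -> TrialDataset:
    """Read a plot-level phenotype CSV into a :class:`TrialDataset`.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8, comma separated, ``.``
        decimal; blank cells are missing values).
    column_map
        Maps canonical roles (``hybrid``, ``location``, ``year``,
        ``block``, optionally ``irrigation``, ``nitrogen_level``,
        ``nitrogen_rate``, ``row``, ``column``) to the file's column
        names. Roles absent from the map default to their own name.
    traits
        Either a mapping ``{trait_name: file_column}`` or a sequence of
        file columns to keep as traits. ``None`` keeps every unmapped
        numeric column as a trait.

    Rows whose hybrid / location / year / block cells cannot be parsed
    are dropped with a logged count. Empty trait cells become missing
    values; observations with some missing traits are retained.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"no rows in {path}")
    column_map = dict(column_map or {})
    rename: dict[str, str] = {}
    for role in ROLE_COLUMNS:
        src = column_map.get(role, role)
        if src in df.columns:
            rename[src] = role
        elif role in REQUIRED_ROLES:
            raise ConfigError(
                f"required column {src!r} (role {role!r}) not found in {path}"
            )
    if isinstance(traits, Mapping):
        for name, src in traits.items():
            if src not in df.columns:
                raise ConfigError(f"trait column {src!r} not found in {path}")
            rename[src] = name
        trait_names = list(traits)
    elif traits is not None:
        for src in traits:
            if src not in df.columns:
                raise ConfigError(f"trait column {src!r} not found in {path}")
            rename[src] = src
        trait_names = list(traits)
    else:
        trait_names = None

    df = df.rename(columns=rename)
    if trait_names is None:
        known = set(ROLE_COLUMNS)
        trait_names = [
            c for c in df.columns
            if c not in known and pd.api.types.is_numeric_dtype(
                pd.to_numeric(df[c], errors="coerce")
            ) and pd.to_numeric(df[c], errors="coerce").notna().any()
        ]

    keep = [c for c in ROLE_COLUMNS if c in df.columns] + trait_names
    df = df[keep]

    n0 = len(df)
    df["year"] = pd.to_numeric(df["year"], errors="coerce")
    df["block"] = pd.to_numeric(df["block"], errors="coerce")
    bad = (
        df["hybrid"].isna()
        | df["location"].isna()
        | df["year"].isna()
        | df["block"].isna()
    )
    df = df[~bad]
    dropped = n0 - len(df)
    if dropped:
        logger.warning("dropped %d row(s) with unparseable keys", dropped)
    if df.empty:
        raise DataError(f"zero parseable rows in {path}")
    df["year"] = df["year"].astype(int)
    df["block"] = df["block"].astype(int)
    for c in trait_names + [c for c in ("nitrogen_rate", "row", "column") if c in df.columns]:
        df[c] = pd.to_numeric(df[c], errors="coerce")

    ds = TrialDataset(
        obs=df.reset_index(drop=True),
        trait_registry={t: "" for t in trait_names},
        info={"rows_read": n0, "rows_dropped": dropped},
    )
    logger.info(
        "read %d plots, %d hybrids, %d environments from %s",
        len(ds.obs), ds.obs["hybrid"].nunique(), ds.obs["environment"].nunique(), path,
    )
    return ds


def write_plot_table(data: TrialDataset, path: str | Path) -> None:
    """Write the plot table to CSV in the same schema ``read_plot_table`` reads."""
    cols = [c for c in ROLE_COLUMNS if c in data.obs.columns] + data.traits
    data.obs[cols].to_csv(path, index=False)


def read_pedigree_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a pedigree CSV (hybrid, ear/pollen parents, release years).

    ``mean_parent_release_year`` is computed as the arithmetic mean of
    the two parental release years where both are known; hybrids with an
    unknown parent (commercial checks) get NaN and ``is_check=True``.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise DataError(f"no rows in {path}")
    cm = dict(column_map or {})
    roles = (
        "hybrid", "ear_parent", "pollen_parent",
        "ear_parent_release_year", "pollen_parent_release_year",
    )
    rename = {}
    for role in roles:
        src = cm.get(role, role)
        if src in df.columns:
            rename[src] = role
        elif role == "hybrid":
            raise ConfigError(f"required column {src!r} not found in {path}")
    df = df.rename(columns=rename)
    for c in ("ear_parent_release_year", "pollen_parent_release_year"):
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce")
        else:
            df[c] = np.nan
    for c in ("ear_parent", "pollen_parent"):
        if c not in df.columns:
            df[c] = np.nan
    if "mean_parent_release_year" not in df.columns:
        df["mean_parent_release_year"] = (
            df["ear_parent_release_year"] + df["pollen_parent_release_year"]
        ) / 2.0
    df["is_check"] = df["ear_parent"].isna() | df["pollen_parent"].isna()
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_min_environments(data: TrialDataset, min_env: int) -> TrialDataset:
    """Drop hybrids observed in fewer than ``min_env`` distinct environments.

    Under-observed hybrids cannot support stable reaction-norm
    estimates; removing them fixes the hybrid cohort for every
    downstream analysis. The removed ids are recorded in
    ``info["removed_hybrids"]``.
    """
    if min_env < 1:
        raise ConfigError("min_env must be >= 1")
    counts = data.obs.groupby("hybrid")["environment"].nunique()
    removed = sorted(counts.index[counts < min_env])
    kept = data.obs[~data.obs["hybrid"].isin(removed)].copy()
    if kept.empty:
        raise DataError("all hybrids removed by the minimum-environment filter")
    if removed:
        logger.info(
            "min-environment filter removed %d hybrid(s): %s",
            len(removed), removed[:10],
        )
    out = replace(data, obs=kept, info=dict(data.info))
    out.info["removed_hybrids"] = removed
    return out


def remove_extreme_values(
    data: TrialDataset,
    bounds: Mapping[str, object] | None,
) -> TrialDataset:
    """Set trait values outside configured bounds to missing.

    ``bounds`` maps trait name to either a global ``(lower, upper)``
    pair or a mapping ``{location_year_id: (lower, upper)}`` for
    per-location-year thresholds. Traits without bounds are untouched.
    The fraction of non-missing values removed per trait is recorded in
    ``info["removal_fractions"]`` — for sane thresholds this should be
    small (a fraction of a percent to a few percent per trait).
    """
    if not bounds:
        out = replace(data, info=dict(data.info))
        out.info["removal_fractions"] = {}
        return out
    obs = data.obs.copy()
    fractions: dict[str, float] = {}
    for trait, spec in bounds.items():
        if trait not in obs.columns:
            raise ConfigError(f"bounds given for unknown trait {trait!r}")
        col = obs[trait]
        n_present = int(col.notna().sum())
        if isinstance(spec, Mapping):
            mask = pd.Series(False, index=obs.index)
            for ly, (lo, hi) in spec.items():
                if lo > hi:
                    raise ConfigError(f"lower bound {lo} > upper bound {hi} for {trait!r}")
                in_ly = obs["location_year"] == ly
                mask |= in_ly & col.notna() & ((col < lo) | (col > hi))
        else:
            lo, hi = spec
            if lo > hi:
                raise ConfigError(f"lower bound {lo} > upper bound {hi} for {trait!r}")
            mask = col.notna() & ((col < lo) | (col > hi))
        n_removed = int(mask.sum())
        obs.loc[mask, trait] = np.nan
        fractions[trait] = n_removed / n_present if n_present else 0.0
        if n_removed:
            logger.info(
                "removed %d extreme value(s) (%.2f%%) for trait %r",
                n_removed, 100 * fractions[trait], trait,
            )
    out = replace(data, obs=obs, info=dict(data.info))
    out.info["removal_fractions"] = fractions
    return out


# ---------------------------------------------------------------------------
# Unit utilities
# ---------------------------------------------------------------------------

def yield_to_mt_per_ha(yield_bu_per_acre):
    """Convert maize grain yield from bushels/acre to MT/ha (x 0.0628)."""
    arr = np.asarray(yield_bu_per_acre, dtype=float)
    if (arr < 0).any():
        raise ValueError("yield cannot be negative")
    out = arr * BU_PER_ACRE_TO_MT_PER_HA
    return float(out) if np.isscalar(yield_bu_per_acre) or arr.ndim == 0 else out


def growing_degree_days(tmin_series, tmax_series) -> float:
    """Accumulated maize growing degree days over daily min/max temperatures.

    Both daily extremes (deg C) are clamped into [10, 30] (base and
    optimum temperatures of the standard 86/50 F corn GDD method) before
    averaging; each day contributes ``max(0, (tmax_c + tmin_c)/2 - 10)``
    degree-days.
    """
    tmin = np.asarray(tmin_series, dtype=float)
    tmax = np.asarray(tmax_series, dtype=float)
    if tmin.shape != tmax.shape:
        raise ValueError(
            f"tmin and tmax series have different shapes: {tmin.shape} vs {tmax.shape}"
        )
    lo = np.clip(tmin, GDD_T_BASE_C, GDD_T_OPT_C)
    hi = np.clip(tmax, GDD_T_BASE_C, GDD_T_OPT_C)
    daily = np.maximum(0.0, (hi + lo) / 2.0 - GDD_T_BASE_C)
    return float(daily.sum())
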