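"""Core tables for trap-based community time series.

The observational unit is a count of individuals of one species in one
trap in one year of succession.  Three tables describe a study:

* a community table (trap, year, species, count) in long form,
* a trait table assigning each species a host-tree affinity
  (specialist / generalist / non_aspen) and a trophic guild,
* a site table assigning each trap an environment (sun-exposed or
  shaded), a landscape, and an optional fungal-diversity covariate.

Zeros may be stored explicitly or left implicit: a missing
(trap, year, species) row means the species was not caught in that
sample, while every (trap, year) pair of the design is assumed to have
been operated.  Calendar years are recoded to successional years 1..T.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOST_AFFINITIES = ("specialist", "generalist", "non_aspen")
ASPEN_AFFINITIES = ("specialist", "generalist")
GUILDS = ("wood_feeder", "fungivore", "predator", "omnivore_saprophage")
ENVIRONMENTS = ("exposed", "shaded")


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


class ConfigError(ValueError):
    """Raised when a column-name configuration does not match the file."""


@dataclass(frozen=True)
class CommunityMatrix:
    """Species counts indexed by (trap, year, species), long form.

    ``data`` holds one row per observed (trap, year, species) with a
    non-negative integer count; absent combinations are implicit zeros.
    ``traps``, ``years`` and ``species`` define the full design: every
    (trap, year) pair is a sample, whether or not any row mentions it.
    """

    data: pd.DataFrame  # columns: trap, year, species, count
    traps: tuple
    years: tuple  # successional years 1..T
    species: tuple
    year_map: dict = field(default_factory=dict)  # original -> recoded

    def __post_init__(self):
        _validate_community(self.data, self.traps, self.years, self.species)

    @property
    def n_traps(self) -> int:
        return len(self.traps)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def total_abundance(self) -> int:
        return int(self.data["count"].sum())

    def to_wide(self) -> pd.DataFrame:
        """Full (trap, year) x species count matrix with explicit zeros."""
        idx = pd.MultiIndex.from_product(
            [self.traps, self.years], names=["trap", "year"]
        )
        wide = (
            self.data.pivot_table(
                index=["trap", "year"],
                columns="species",
                values="count",
                aggfunc="sum",
                fill_value=0,
            )
            .reindex(idx, fill_value=0)
            .reindex(columns=list(self.species), fill_value=0)
        )
        return wide.astype(np.int64)

    def restrict_species(self, keep) -> "CommunityMatrix":
        keep = [s for s in self.species if s in set(keep)]
        sub = self.data[self.data["species"].isin(keep)].reset_index(drop=True)
        return CommunityMatrix(
            data=sub,
            traps=self.traps,
            years=self.years,
            species=tuple(keep),
            year_map=dict(self.year_map),
        )

    def to_csv(self, path) -> None:
        """Write the long table (explicit rows only) as UTF-8 CSV."""
        out = self.data.rename(columns={"trap": "trap", "year": "year"})
        out.to_csv(path, index=False)


def _validate_community(data, traps, years, species):
    required = {"trap", "year", "species", "count"}
    if not required.issubset(data.columns):
        raise ConfigError(
            f"community table must have columns {sorted(required)}, "
            f"got {list(data.columns)}"
        )
    counts = data["count"]
    bad = ~np.isfinite(counts) | (counts < 0) | (counts != np.floor(counts))
    if bad.any():
        rows = data.index[bad].tolist()[:5]
        raise ValidationError(
            f"counts must be non-negative integers; offending rows {rows}"
        )
    dup = data.duplicated(subset=["trap", "year", "species"])
    if dup.any():
        keys = data.loc[dup, ["trap", "year", "species"]].head().values.tolist()
        raise ValidationError(f"duplicate (trap, year, species) keys: {keys}")
    if not set(data["trap"]).issubset(traps):
        raise ValidationError("data mentions traps outside the design")
    if not set(data["year"]).issubset(years):
        raise ValidationError("data mentions years outside the design")
    if not set(data["species"]).issubset(species):
        raise ValidationError("data mentions species outside the species set")


@dataclass(frozen=True)
class TraitTable:
    """Per-species host affinity and trophic guild."""

    data: pd.DataFrame  # columns: species, host_affinity, guild

    def __post_init__(self):
        df = self.data
        for col in ("species", "host_affinity", "guild"):
            if col not in df.columns:
                raise ConfigError(f"trait table missing column {col!r}")
        if df["species"].duplicated().any():
            dups = df.loc[df["species"].duplicated(), "species"].tolist()
            raise ValidationError(f"duplicate species in trait table: {dups}")
        bad = ~df["host_affinity"].isin(HOST_AFFINITIES)
        if bad.any():
            raise ValidationError(
                "unknown host_affinity values: "
                f"{sorted(df.loc[bad, 'host_affinity'].unique())}"
            )
        ok_guilds = set(GUILDS) | {"unassigned"}
        bad = ~df["guild"].isin(ok_guilds)
        if bad.any():
            raise ValidationError(
                f"unknown guild values: {sorted(df.loc[bad, 'guild'].unique())}"
            )
        aspen = df["host_affinity"].isin(ASPEN_AFFINITIES)
        if (df.loc[aspen, "guild"] == "unassigned").any():
            missing = df.loc[
                aspen & (df["guild"] == "unassigned"), "species"
            ].tolist()
            raise ValidationError(
                f"aspen-associated species lack a guild: {missing}"
            )

    def affinity(self) -> pd.Series:
        return self.data.set_index("species")["host_affinity"]

    def guild(self) -> pd.Series:
        return self.data.set_index("species")["guild"]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class SiteTable:
    """Per-trap environment, landscape and fungal-diversity covariate."""

    data: pd.DataFrame  # columns: trap, environment, landscape, fungal_diversity

    def __post_init__(self):
        df = self.data
        for col in ("trap", "environment", "landscape"):
            if col not in df.columns:
                raise ConfigError(f"site table missing column {col!r}")
        if df["trap"].duplicated().any():
            raise ValidationError("duplicate traps in site table")
        if df["environment"].isna().any() or df["landscape"].isna().any():
            raise ValidationError("environment and landscape must be non-missing")
        bad = ~df["environment"].isin(ENVIRONMENTS)
        if bad.any():
            raise ValidationError(
                "environment must be 'exposed' or 'shaded', got "
                f"{sorted(df.loc[bad, 'environment'].unique())}"
            )
        if "fungal_diversity" in df.columns:
            fd = df["fungal_diversity"].dropna()
            if (fd < 0).any():
                raise ValidationError("fungal_diversity must be non-negative")

    def environment(self) -> pd.Series:
        return self.data.set_index("trap")["environment"]

    def landscape(self) -> pd.Series:
        return self.data.set_index("trap")["landscape"]

    def fungal_diversity(self) -> pd.Series:
        if "fungal_diversity" not in self.data.columns:
            return pd.Series(index=self.data["trap"], dtype=float, name="fungal_diversity")
        return self.data.set_index("trap")["fungal_diversity"]

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class GroupSeries:
    """Per (trap, year) richness and abundance for one functional group."""

    group: str
    data: pd.DataFrame  # columns: trap, year, richness, abundance

    def __post_init__(self):
        df = self.data
        if ((df["abundance"] == 0) != (df["richness"] == 0)).any():
            raise ValidationError("abundance is zero iff richness is zero")
        if (df["abundance"] < df["richness"]).any():
            raise ValidationError("abundance cannot be below richness")


# ---------------------------------------------------------------------------
# readers / constructors

_DEFAULT_DIALECT = {
    "trap": "trap",
    "year": "year",
    "species": "species",
    "count": "count",
}


def community_from_long(
    df: pd.DataFrame,
    traps=None,
    years=None,
    species=None,
    recode_years: bool = True,
) -> CommunityMatrix:
    """Build a CommunityMatrix from a long dataframe.

    Calendar years are recoded to successional years 1..T (sorted order)
    when ``recode_years`` is true.  The design defaults to the cross of
    observed traps and years.
    """
    df = df.loc[:, ["trap", "year", "species", "count"]].copy()
    try:
        df["year"] = df["year"].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"years must be coercible to integers: {exc}")
    df["trap"] = df["trap"].astype(str)
    df["species"] = df["species"].astype(str)
    if not np.issubdtype(df["count"].dtype, np.number):
        try:
            df["count"] = df["count"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"non-integer count: {exc}")

    year_map = {}
    if recode_years:
        observed = sorted(df["year"].unique()) if years is None else sorted(years)
        year_map = {int(y): i + 1 for i, y in enumerate(observed)}
        df["year"] = df["year"].map(year_map)
        years = tuple(year_map.values())
    traps = tuple(sorted(df["trap"].unique())) if traps is None else tuple(traps)
    if years is None:
        years = tuple(sorted(df["year"].unique()))
    species = (
        tuple(sorted(df["species"].unique())) if species is None else tuple(species)
    )
    c = df["count"].to_numpy()
    bad = ~np.isfinite(c) | (c < 0) | (c != np.floor(c))
    if bad.any():
        raise ValidationError(
            "counts must be non-negative integers; offending rows "
            f"{df.index[bad].tolist()[:5]}"
        )
    df["count"] = df["count"].astype(np.int64)
    return CommunityMatrix(
        data=df.reset_index(drop=True),
        traps=traps,
        years=tuple(int(y) for y in years),
        species=species,
        year_map=year_map,
    )


def read_community_table(
    path,
    dialect: dict | None = None,
    wide: bool = False,
    recode_years: bool = True,
) -> CommunityMatrix:
    """Read a community CSV (long by default, wide with ``wide=True``).

    ``dialect`` maps the canonical names trap/year/species/count to the
    column names used in the file.  In wide form the file has one row per
    (trap, year) and one column per species.
    """
    raw = pd.read_csv(path)
    names = dict(_DEFAULT_DIALECT)
    names.update(dialect or {})
    if wide:
        key_cols = [names["trap"], names["year"]]
        missing = [c for c in key_cols if c not in raw.columns]
        if missing:
            raise ConfigError(f"wide table missing columns {missing}")
        long = raw.melt(
            id_vars=key_cols, var_name="species", value_name="count"
        ).rename(columns={names["trap"]: "trap", names["year"]: "year"})
        long = long[long["count"] != 0].reset_index(drop=True)
        return community_from_long(long, recode_years=recode_years)
    missing = [c for c in names.values() if c not in raw.columns]
    if missing:
        raise ConfigError(
            f"community file {path} lacks expected columns {missing}; "
            f"found {list(raw.columns)}"
        )
    long = raw.rename(columns={v: k for k, v in names.items()})
    return community_from_long(long, recode_years=recode_years)


def read_trait_table(path) -> TraitTable:
    return TraitTable(pd.read_csv(path))


def read_site_table(path) -> SiteTable:
    df = pd.read_csv(path)
    df["trap"] = df["trap"].astype(str)
    return SiteTable(df)


# ---------------------------------------------------------------------------
# filtering and aggregation

def filter_aspen_associated(
    matrix: CommunityMatrix, traits: TraitTable
) -> CommunityMatrix:
    """Drop species not associated with the host tree.

    Retains specialists and generalists only; counts of retained species
    are untouched.  Every species in the matrix must appear in the trait
    table.
    """
    affinity = traits.affinity()
    missing = [s for s in matrix.species if s not in affinity.index]
    if missing:
        raise ValidationError(
            f"species missing from trait table: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    keep = [s for s in matrix.species if affinity[s] in ASPEN_AFFINITIES]
    return matrix.restrict_species(keep)


def group_species(traits: TraitTable, group: str) -> list:
    """Species ids selected by a grouping name.

    ``group`` is 'all', a host affinity ('specialist'/'generalist') or a
    trophic guild name.  'all' means all aspen-associated species.
    """
    df = traits.data
    aspen = df["host_affinity"].isin(ASPEN_AFFINITIES)
    if group == "all":
        sel = aspen
    elif group in ASPEN_AFFINITIES:
        sel = df["host_affinity"] == group
    elif group in GUILDS:
        sel = aspen & (df["guild"] == group)
    else:
        raise ConfigError(
            f"unknown group {group!r}; expected 'all', an affinity "
            f"{ASPEN_AFFINITIES} or a guild {GUILDS}"
        )
    return df.loc[sel, "species"].tolist()


def aggregate_group(
    matrix: CommunityMatrix, traits: TraitTable, group: str
) -> GroupSeries:
    """Per (trap, year) richness and abundance for one functional group."""
    members = group_species(traits, group)
    if not members:
        raise ConfigError(f"group {group!r} selects no species")
    wide = matrix.to_wide()
    cols = [s for s in wide.columns if s in set(members)]
    sub = wide[cols]
    out = pd.DataFrame(
        {
            "richness": (sub > 0).sum(axis=1).astype(np.int64),
            "abundance": sub.sum(axis=1).astype(np.int64),
        }
    ).reset_index()
    return GroupSeries(group=group, data=out)
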