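"""Parsing, validation, filtering and aggregation of kick-sample records.

The survey dataset is a long table of taxon counts, one row per taxon per
dated kick sample at a site.  The analysis keeps only the standardized
3-minute kick-sample method within the study years, then keeps only sites
with sufficient seasonal coverage: at least ``min_years_both_seasons``
calendar years that each contain both a spring (March-May) and an autumn
(September-November) sample.  Counts are then pooled per sample to wider
taxonomic groups, families, or trophic guilds for modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

#: Sample CSV dialect header.
SAMPLE_COLUMNS = (
    "site_id",
    "sample_id",
    "date",
    "method",
    "taxon_name",
    "taxon_rank",
    "count",
)

#: Taxonomy CSV dialect header.
TAXONOMY_COLUMNS = ("taxon_name", "rank", "family", "group")

VALID_RANKS = ("genus", "family", "higher-group")

#: The twelve wider taxonomic groups modelled at national scale.
WIDER_GROUPS = (
    "annelids",
    "molluscs",
    "Turbellaria",
    "crustaceans",
    "Ephemeroptera",
    "Trichoptera",
    "Plecoptera",
    "Coleoptera",
    "Diptera",
    "Megaloptera",
    "Hemiptera",
    "Odonata",
)

KICK_METHOD = "3-min kick"

SPRING = "spring"
AUTUMN = "autumn"
OTHER = "other"


@dataclass(frozen=True)
class FilterConfig:
    """Record-selection rules.

    ``both_seasons_jointly`` selects between the default coverage reading
    (a qualifying year must contain >= 1 spring AND >= 1 autumn sample) and
    the alternative (>= min_years spring-years and >= min_years autumn-years
    counted independently).  ``spring_autumn_only`` drops samples from
    non-window months at qualifying sites; by default the coverage rule
    selects sites, not samples.
    """

    year_min: int = 2002
    year_max: int = 2019
    min_years_both_seasons: int = 3
    spring_months: frozenset[int] = frozenset({3, 4, 5})
    autumn_months: frozenset[int] = frozenset({9, 10, 11})
    allowed_methods: frozenset[str] = frozenset({KICK_METHOD})
    both_seasons_jointly: bool = True
    spring_autumn_only: bool = False

    def __post_init__(self):
        if self.year_min > self.year_max:
            raise UsageError("year_min must be <= year_max")
        if self.min_years_both_seasons < 1:
            raise UsageError("min_years_both_seasons must be >= 1")
        if self.spring_months & self.autumn_months:
            raise UsageError("spring and autumn month sets must be disjoint")


@dataclass
class ParseReport:
    """Outcome of reading a sample CSV: totals and per-row rejections."""

    rows_total: int = 0
    rows_rejected: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    """Record/site counts at each filtering stage, serializable to JSON."""

    input_records: int = 0
    input_sites: int = 0
    after_method_year_records: int = 0
    after_method_year_sites: int = 0
    retained_records: int = 0
    retained_sites: int = 0

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def assign_season(date, config: FilterConfig | None = None) -> str:
    """Season of a calendar date: spring (Mar-May), autumn (Sep-Nov), else other."""
    cfg = config or FilterConfig()
    month = pd.Timestamp(date).month
    if month in cfg.spring_months:
        return SPRING
    if month in cfg.autumn_months:
        return AUTUMN
    return OTHER


def _derive_columns(df: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    df = df.copy()
    df["year"] = df["date"].dt.year
    month = df["date"].dt.month
    season = np.full(len(df), OTHER, dtype=object)
    season[month.isin(list(config.spring_months))] = SPRING
    season[month.isin(list(config.autumn_months))] = AUTUMN
    df["season"] = season
    return df


def parse_samples(
    path, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a sample CSV, validating each row.

    Malformed rows (unparseable date, non-integral or negative count, unknown
    rank) are rejected individually and reported with their line numbers; a
    missing mandatory column fails the whole file with :class:`FormatError`.
    Returns the valid records with derived ``year``/``season`` columns and a
    :class:`ParseReport`.
    """
    cfg = config or FilterConfig()
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"sample CSV missing mandatory columns: {missing}")

    report = ParseReport(rows_total=len(raw))
    lineno = raw.index + 2  # header occupies line 1

    date = pd.to_datetime(raw["date"], format="ISO8601", errors="coerce")
    count = pd.to_numeric(raw["count"], errors="coerce")
    bad_date = date.isna()
    bad_count = count.isna() | (count < 0) | (count != np.floor(count))
    bad_rank = ~raw["taxon_rank"].isin(VALID_RANKS)

    for mask, reason in (
        (bad_date, "unparseable date"),
        (bad_count, "count not a non-negative integer"),
        (bad_rank, f"taxon_rank not one of {VALID_RANKS}"),
    ):
        for ln in lineno[mask.to_numpy()]:
            report.messages.append(f"line {ln}: {reason}")

    bad = (bad_date | bad_count | bad_rank).to_numpy()
    report.rows_rejected = int(bad.sum())

    df = raw.loc[~bad, list(SAMPLE_COLUMNS)].copy()
    df["date"] = date[~bad]
    df["count"] = count[~bad].astype(int)
    df = _derive_columns(df, cfg).reset_index(drop=True)
    return df, report


def qualifying_sites(df: pd.DataFrame, config: FilterConfig) -> set:
    """Sites meeting the seasonal-coverage rule on the supplied records."""
    spring_years = (
        df[df["season"] == SPRING].groupby("site_id")["year"].agg(set)
    )
    autumn_years = (
        df[df["season"] == AUTUMN].groupby("site_id")["year"].agg(set)
    )
    sites = set(spring_years.index) & set(autumn_years.index)
    keep = set()
    for site in sites:
        sp, au = spring_years[site], autumn_years[site]
        if config.both_seasons_jointly:
            ok = len(sp & au) >= config.min_years_both_seasons
        else:
            ok = (
                len(sp) >= config.min_years_both_seasons
                and len(au) >= config.min_years_both_seasons
            )
        if ok:
            keep.add(site)
    return keep


def filter_records(
    df: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the method/year filter, then the site seasonal-coverage rule.

    Filtering is idempotent, and raising ``min_years_both_seasons`` can only
    shrink the retained site set.  An empty result is permitted.
    """
    cfg = config or FilterConfig()
    if "season" not in df.columns or "year" not in df.columns:
        df = _derive_columns(df, cfg)
    report = FilterReport(
        input_records=len(df), input_sites=df["site_id"].nunique()
    )

    stage1 = df[
        df["method"].isin(cfg.allowed_methods)
        & df["year"].between(cfg.year_min, cfg.year_max)
    ]
    report.after_method_year_records = len(stage1)
    report.after_method_year_sites = stage1["site_id"].nunique()

    keep = qualifying_sites(stage1, cfg)
    out = stage1[stage1["site_id"].isin(keep)]
    if cfg.spring_autumn_only:
        out = out[out["season"].isin([SPRING, AUTUMN])]
    out = out.reset_index(drop=True)
    report.retained_records = len(out)
    report.retained_sites = out["site_id"].nunique()
    return out, report


def read_taxonomy(path) -> pd.DataFrame:
    """Read the taxonomy CSV (taxon_name, rank, family, group)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"taxonomy CSV missing columns: {missing}")
    return df


AGGREGATION_LEVELS = ("group", "family", "trophic")


def aggregate_counts(
    df: pd.DataFrame,
    level: str,
    *,
    taxonomy: pd.DataFrame | None = None,
    trophic_map=None,
    materialize_zeros: bool | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pool counts per sample into aggregate units at the requested level.

    ``level`` is one of ``group`` (the twelve wider taxonomic groups),
    ``family``, or ``trophic`` (carnivore/herbivore/decomposer via a
    :class:`~rivertrends.traits.TrophicMap`).  A taxon belonging to several
    trophic guilds contributes its full count to each guild's sample total.
    Taxa unresolvable at the requested level are dropped and returned in the
    warnings list.  For resolvable taxa, total abundance per sample is
    conserved (counting multi-membership once per guild).

    ``materialize_zeros`` emits an explicit zero row for every
    (sample x unit) pair with no recorded members — trend models need the
    zeros.  Default ON for group/trophic, OFF for family.

    Returns ``(totals, unresolved)`` where totals has one row per
    (sample_id, unit) with columns sample_id, site_id, date, year, season,
    unit, count.
    """
    if level not in AGGREGATION_LEVELS:
        raise UsageError(f"unknown aggregation level {level!r}")
    if materialize_zeros is None:
        materialize_zeros = level in ("group", "trophic")

    df = df.copy()
    unresolved: list[str] = []

    if level in ("group", "family"):
        if taxonomy is None:
            raise UsageError(f"level {level!r} requires a taxonomy table")
        taxmap = taxonomy.set_index("taxon_name")
        target = {}
        for name in pd.unique(df["taxon_name"]):
            if name in taxmap.index:
                row = taxmap.loc[name]
                value = row["group"] if level == "group" else row["family"]
                if level == "family" and row["rank"] == "higher-group":
                    value = ""
                if value:
                    target[name] = value
                    continue
            unresolved.append(name)
        df["unit"] = df["taxon_name"].map(target)
        df = df[df["unit"].notna()]
        expanded = df
    else:
        if trophic_map is None:
            raise UsageError("level 'trophic' requires a trophic map")
        rows = []
        for name in pd.unique(df["taxon_name"]):
            groups = trophic_map.groups_of(name)
            if not groups:
                unresolved.append(name)
                continue
            for g in sorted(groups):
                rows.append((name, g))
        membership = pd.DataFrame(rows, columns=["taxon_name", "unit"])
        expanded = df.merge(membership, on="taxon_name", how="inner")

    keys = ["sample_id", "site_id", "date", "year", "season"]
    present = [k for k in keys if k in expanded.columns]
    totals = (
        expanded.groupby(present + ["unit"], as_index=False)["count"]
        .sum()
        .astype({"count": int})
    )

    if materialize_zeros and not totals.empty:
        units = sorted(totals["unit"].unique())
        samples = totals[present].drop_duplicates()
        full = samples.merge(pd.DataFrame({"unit": units}), how="cross")
        totals = full.merge(totals, on=present + ["unit"], how="left")
        totals["count"] = totals["count"].fillna(0).astype(int)

    totals = totals.sort_values(present + ["unit"]).reset_index(drop=True)
    return totals, unresolved
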