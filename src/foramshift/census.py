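"""Census-table domain model: readers, validation, taxonomic lumping,
season assignment, profile grouping and record filtering.

The canonical in-memory container for plankton census data is a wide
:class:`pandas.DataFrame`: one row per *subsample* (a single plankton
aliquot collected within one depth interval, time interval and
size-fraction window at one location), metadata in the reserved columns
below, and one column per species holding counts (individuals) or
concentrations (individuals per m^3) depending on ``count_kind``.

Sediment (pre-industrial surface-sediment) tables use the same layout
with ``site_id``/``latitude``/``longitude`` metadata and 0/1 presence
values per species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

DEVICES = frozenset({"net", "cpr", "pump", "trap"})
COUNT_KINDS = frozenset({"raw_count", "concentration"})
SEASONS = ("winter", "spring", "summer", "autumn")

#: Metadata columns of a census table, in canonical order.
META_COLUMNS = [
    "subsample_id",
    "sample_id",
    "latitude",
    "longitude",
    "date",
    "depth_upper",
    "depth_lower",
    "device",
    "size_lower",
    "size_upper",
    "volume_filtered",
    "count_kind",
]

#: Columns that analyses may add; never treated as species.
DERIVED_COLUMNS = [
    "season",
    "year",
    "profile_id",
    "profile_valid",
    "temperature",
    "omega_calcite",
    "env_ok",
    "harmonized",
    "quantifiable",
]

RESERVED_COLUMNS = frozenset(META_COLUMNS) | frozenset(DERIVED_COLUMNS)

SEDIMENT_META_COLUMNS = ["site_id", "latitude", "longitude"]


def species_columns(df: pd.DataFrame) -> list[str]:
    """Columns of ``df`` that hold per-species values."""
    return [c for c in df.columns if c not in RESERVED_COLUMNS and c not in SEDIMENT_META_COLUMNS]


# ---------------------------------------------------------------------------
# Reading and validation
# ---------------------------------------------------------------------------

@dataclass
class ReadResult:
    """Outcome of an ingest: validated records plus row-indexed rejections."""

    records: pd.DataFrame
    rejected: pd.DataFrame  # columns: row, field, message

    @property
    def n_rejected(self) -> int:
        return int(self.rejected["row"].nunique()) if len(self.rejected) else 0


def _row_checks(df: pd.DataFrame) -> list[tuple[int, str, str]]:
    """Collect invariant violations as (row, field, message) triples."""
    problems: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        if not (-90 <= row["latitude"] <= 90):
            problems.append((idx, "latitude", f"latitude {row['latitude']} outside [-90, 90]"))
        if not (-180 <= row["longitude"] < 360):
            problems.append((idx, "longitude", f"longitude {row['longitude']} outside [-180, 360)"))
        if pd.isna(row["date"]):
            problems.append((idx, "date", "unparseable or missing date"))
        if pd.isna(row["depth_upper"]) or pd.isna(row["depth_lower"]):
            problems.append((idx, "depth_upper", "missing depth bound"))
        elif not (0 <= row["depth_upper"] < row["depth_lower"]):
            problems.append(
                (idx, "depth_upper",
                 f"requires 0 <= depth_upper < depth_lower, got [{row['depth_upper']}, {row['depth_lower']})"))
        if row["device"] not in DEVICES:
            problems.append((idx, "device", f"device {row['device']!r} not one of {sorted(DEVICES)}"))
        if row["count_kind"] not in COUNT_KINDS:
            problems.append((idx, "count_kind", f"count_kind {row['count_kind']!r} invalid"))
        if pd.notna(row["size_upper"]) and not (row["size_lower"] < row["size_upper"]):
            problems.append((idx, "size_lower",
                             f"size_lower {row['size_lower']} must be < size_upper {row['size_upper']}"))
        if row["size_lower"] < 0 or pd.isna(row["size_lower"]):
            problems.append((idx, "size_lower", "size_lower must be >= 0"))
        if pd.notna(row["volume_filtered"]) and row["volume_filtered"] <= 0:
            problems.append((idx, "volume_filtered", "volume_filtered must be > 0 when given"))
    return problems


def read_census(path, schema: dict[str, str] | None = None) -> ReadResult:
    """Read a census CSV into the canonical wide table.

    Parameters
    ----------
    path
        CSV file (comma-separated, UTF-8, ``.`` decimal, ISO-8601 dates;
        an empty ``size_upper`` field encodes an unbounded top fraction).
    schema
        Optional mapping *file column -> canonical column*; unmapped
        columns are kept verbatim (non-metadata columns become species).

    Returns
    -------
    ReadResult
        Validated records and a row-indexed rejection report. Rows
        violating any invariant are rejected, never silently dropped.
    """
    raw = pd.read_csv(path)
    if schema:
        raw = raw.rename(columns=dict(schema))
    missing = [c for c in META_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")

    df = raw.copy()
    df["date"] = pd.to_datetime(df["date"], errors="coerce", format="mixed")
    for col in ("latitude", "longitude", "depth_upper", "depth_lower",
                "size_lower", "size_upper", "volume_filtered"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    sp = species_columns(df)
    for col in sp:
        df[col] = pd.to_numeric(df[col], errors="coerce")

    problems = _row_checks(df)
    # negative or unparseable species values are row errors too
    for col in sp:
        bad = df.index[(df[col] < 0) | (df[col].isna() & raw[col].notna())]
        problems.extend((idx, col, f"invalid count in {col!r}") for idx in bad)
    df[sp] = df[sp].fillna(0.0)

    rejected = pd.DataFrame(problems, columns=["row", "field", "message"])
    good = df.drop(index=rejected["row"].unique() if len(rejected) else [])
    good = good.reset_index(drop=True)
    if len(rejected):
        logger.warning("read_census: rejected %d of %d rows", rejected["row"].nunique(), len(df))
    return ReadResult(records=good[META_COLUMNS + species_columns(good)], rejected=rejected)


def write_census(records: pd.DataFrame, path) -> None:
    """Write a canonical census table; lossless round-trip with read_census."""
    out = records.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_sediment(path) -> pd.DataFrame:
    """Read a surface-sediment presence/absence table.

    Any positive species abundance is normalized to presence (1), zero
    to absence (0), so count- and proportion-based tables are accepted.
    """
    df = pd.read_csv(path)
    missing = [c for c in SEDIMENT_META_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    sp = [c for c in df.columns if c not in SEDIMENT_META_COLUMNS]
    for col in sp:
        df[col] = (pd.to_numeric(df[col], errors="coerce").fillna(0.0) > 0).astype(int)
    return df


def read_taxonomy(path) -> pd.DataFrame:
    """Read a taxonomy table (species_name, lumped_name, province, trophic, spinose)."""
    df = pd.read_csv(path)
    required = ["species_name", "lumped_name"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    lump = dict(zip(df["species_name"], df["lumped_name"]))
    for src, dst in lump.items():
        if lump.get(dst, dst) != dst:
            raise SchemaError(f"lumping map not idempotent at {src!r} -> {dst!r} -> {lump[dst]!r}")
    return df


# ---------------------------------------------------------------------------
# Taxonomic lumping
# ---------------------------------------------------------------------------

def lump_taxa(records: pd.DataFrame, taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Sum morphospecies columns that lump to the same target name.

    Species absent from the taxonomy pass through unchanged (logged),
    so partial taxonomies remain usable. The per-subsample total count
    is conserved exactly.
    """
    lump = dict(zip(taxonomy["species_name"], taxonomy["lumped_name"]))
    sp = species_columns(records)
    unmapped = [s for s in sp if s not in lump]
    if unmapped:
        logger.warning("lump_taxa: %d species not in taxonomy, passed through: %s",
                       len(unmapped), unmapped)
    target: dict[str, list[str]] = {}
    for s in sp:
        target.setdefault(lump.get(s, s), []).append(s)
    meta = [c for c in records.columns if c not in sp]
    out = records[meta].copy()
    for dst, sources in target.items():
        out[dst] = records[sources].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# Seasons
# ---------------------------------------------------------------------------

_NORTH_SEASON = {12: "winter", 1: "winter", 2: "winter",
                 3: "spring", 4: "spring", 5: "spring",
                 6: "summer", 7: "summer", 8: "summer",
                 9: "autumn", 10: "autumn", 11: "autumn"}
_SOUTH_SEASON = {12: "summer", 1: "summer", 2: "summer",
                 3: "autumn", 4: "autumn", 5: "autumn",
                 6: "winter", 7: "winter", 8: "winter",
                 9: "spring", 10: "spring", 11: "spring"}


def assign_season(latitude, date):
    """Hemisphere-aware meteorological season of a date.

    Northern convention (latitude >= 0, the equator counted north):
    DJF winter, MAM spring, JJA summer, SON autumn; the Southern
    Hemisphere is offset by six months.

    Accepts scalars or aligned array-likes; vectorized in either case.
    """
    lat = np.asarray(latitude, dtype=float)
    months = pd.DatetimeIndex(np.atleast_1d(np.asarray(date, dtype="datetime64[ns]"))).month
    north = np.array([_NORTH_SEASON[m] for m in months])
    south = np.array([_SOUTH_SEASON[m] for m in months])
    out = np.where(np.atleast_1d(lat) >= 0, north, south)
    if lat.ndim == 0:
        return str(out[0])
    return out


def add_seasons(records: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``season`` and ``year`` columns attached."""
    out = records.copy()
    out["season"] = assign_season(out["latitude"].to_numpy(), out["date"].to_numpy())
    out["year"] = pd.DatetimeIndex(out["date"]).year
    return out


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def group_profiles(records: pd.DataFrame, location_tolerance: float = 0.01) -> pd.DataFrame:
    """Group subsamples into vertical profiles.

    Subsamples sharing device, calendar date and location (latitude and
    longitude within ``location_tolerance`` degrees, via binning) form
    one profile. Adds ``profile_id`` and ``profile_valid`` columns;
    a profile whose member depth intervals overlap is flagged invalid.
    Members are ordered by ``depth_upper`` within each profile.
    """
    out = records.copy()
    lat_bin = np.floor(out["latitude"].to_numpy() / location_tolerance).astype(np.int64)
    lon_bin = np.floor(out["longitude"].to_numpy() / location_tolerance).astype(np.int64)
    key = pd.DataFrame({
        "device": out["device"].to_numpy(),
        "date": pd.DatetimeIndex(out["date"]).normalize(),
        "lat_bin": lat_bin,
        "lon_bin": lon_bin,
    }, index=out.index)
    out["profile_id"] = key.groupby(["device", "date", "lat_bin", "lon_bin"],
                                    sort=False).ngroup().astype(str)
    out = out.sort_values(["profile_id", "depth_upper"], kind="stable")

    # overlap check: within a profile, sorted intervals must not intersect
    prev_lower = out.groupby("profile_id")["depth_lower"].shift(1)
    overlap = (out["depth_upper"] < prev_lower) & prev_lower.notna()
    bad = set(out.loc[overlap.to_numpy(), "profile_id"])
    out["profile_valid"] = ~out["profile_id"].isin(bad)
    return out.reset_index(drop=True)


def profile_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-profile member count and depth coverage (requires profile_id)."""
    g = records.groupby("profile_id")
    return pd.DataFrame({
        "n_members": g.size(),
        "depth_min": g["depth_upper"].min(),
        "depth_max": g["depth_lower"].max(),
        "latitude": g["latitude"].first(),
        "longitude": g["longitude"].first(),
        "date": g["date"].first(),
        "device": g["device"].first(),
        "valid": g["profile_valid"].all(),
    }).reset_index()


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterResult:
    records: pd.DataFrame
    removed: dict[str, int] = field(default_factory=dict)


def filter_records(records: pd.DataFrame, *,
                   depth_range: tuple[float, float] | None = None,
                   seasons=None,
                   lat_band: tuple[float, float] | None = None,
                   lon_window: tuple[float, float] | None = None,
                   devices=None,
                   years: tuple[int, int] | None = None,
                   min_profile_size: int | None = None) -> FilterResult:
    """Apply a conjunction of predicates; report removals per predicate.

    Conventions: depth window and latitude band are half-open
    ``[low, high)`` except that a latitude band reaching 90 includes 90;
    a record must lie wholly inside the depth window; ``years`` is an
    inclusive calendar-year pair. An empty result is returned with a
    warning, not raised.
    """
    df = records
    removed: dict[str, int] = {}

    def apply(mask: np.ndarray, name: str):
        nonlocal df
        removed[name] = int((~mask).sum())
        df = df[mask]

    if depth_range is not None:
        lo, hi = depth_range
        apply((df["depth_upper"] >= lo) & (df["depth_upper"] < hi)
              & (df["depth_lower"] <= hi), "depth_range")
    if seasons is not None:
        if "season" not in df.columns:
            df = add_seasons(df)
        apply(df["season"].isin(set(seasons)), "seasons")
    if lat_band is not None:
        lo, hi = lat_band
        upper_ok = (df["latitude"] < hi) | ((hi >= 90) & (df["latitude"] == 90))
        apply((df["latitude"] >= lo) & upper_ok, "lat_band")
    if lon_window is not None:
        lo, hi = lon_window
        apply((df["longitude"] >= lo) & (df["longitude"] < hi), "lon_window")
    if devices is not None:
        apply(df["device"].isin(set(devices)), "devices")
    if years is not None:
        yr = pd.DatetimeIndex(df["date"]).year
        apply((yr >= years[0]) & (yr <= years[1]), "years")
    if min_profile_size is not None:
        if "profile_id" not in df.columns:
            df = group_profiles(df)
        sizes = df.groupby("profile_id")["profile_id"].transform("size")
        apply((sizes >= min_profile_size).to_numpy(), "min_profile_size")

    if df.empty:
        logger.warning("filter_records: empty result after filtering")
    return FilterResult(records=df.reset_index(drop=True), removed=removed)
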