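"""Lateral range-edge and vertical habitat-depth shift estimation.

The poleward range edge of a species is a high quantile (default the
95th percentile, the "northernmost 5%" boundary) of its occurrence
latitudes in near-surface spring/summer records. The shift between two
periods split at a cutoff year is expressed in km (1 deg latitude =
111.32 km) and as a speed over the difference of the periods' median
sampling years.

The vertical habitat metric is the depth of maximum abundance per
multinet profile (midpoint of the interval with the highest
concentration; ties break shallow); deepening between periods is tested
with a two-group one-way ANOVA (equivalent to a two-sided pooled
t-test, F = t^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .census import add_seasons, filter_records
from .errors import InsufficientDataError

KM_PER_DEGREE_LAT = 111.32


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class ShiftEstimate:
    """A species' range-edge or habitat-depth change between two periods."""

    species: str
    metric: str  # "northern_edge_deg" | "depth_of_max_m"
    value_before: float | None
    value_after: float | None
    delta: float | None  # after - before, metric units
    speed_km_per_yr: float | None = None  # lateral only
    n_before: int = 0
    n_after: int = 0
    p_value: float | None = None
    classification: str = "insufficient_data"
    sd_before: float | None = None
    sd_after: float | None = None


# ---------------------------------------------------------------------------
# Lateral
# ---------------------------------------------------------------------------

def _occurrence_filter(records: pd.DataFrame, species: str,
                       depth_window=(0.0, 100.0), seasons=("spring", "summer")):
    if "season" not in records.columns:
        records = add_seasons(records)
    sub = filter_records(records, depth_range=depth_window, seasons=seasons).records
    return sub[sub[species] > 0]


def northern_edge(records: pd.DataFrame, species: str, quantile: float = 0.95,
                  depth_window=(0.0, 100.0), seasons=("spring", "summer"),
                  n_min: int = 20, literal_max: bool = False) -> float:
    """Poleward range-edge latitude of a species.

    The ``quantile`` of the occurrence-latitude distribution
    (occurrence = record with concentration > 0), linear-interpolation
    convention, clipped to 90. ``literal_max`` returns the maximum
    occurrence latitude instead. Raises :class:`InsufficientDataError`
    below ``n_min`` occurrences.
    """
    occ = _occurrence_filter(records, species, depth_window, seasons)
    if len(occ) < n_min:
        raise InsufficientDataError(
            f"{species}: {len(occ)} occurrences < n_min={n_min}")
    lats = occ["latitude"].to_numpy(dtype=float)
    if literal_max or quantile >= 1.0:
        return float(lats.max())
    return float(min(np.quantile(lats, quantile, method="linear"), 90.0))


def poleward_shift(records: pd.DataFrame, species: str, cutoff_year: int = 1990,
                   quantile: float = 0.95, depth_window=(0.0, 100.0),
                   seasons=("spring", "summer"), n_min: int = 20) -> ShiftEstimate:
    """Range-edge shift across a cutoff year, as degrees, km and km/yr.

    Speed divides the km shift by the difference of the two periods'
    median occurrence years; positive = poleward (Northern Hemisphere).
    """
    if "year" not in records.columns:
        records = records.assign(year=pd.DatetimeIndex(records["date"]).year)
    before = records[records["year"] < cutoff_year]
    after = records[records["year"] >= cutoff_year]
    try:
        occ_b = _occurrence_filter(before, species, depth_window, seasons)
        occ_a = _occurrence_filter(after, species, depth_window, seasons)
        if len(occ_b) < n_min or len(occ_a) < n_min:
            raise InsufficientDataError(species)
        edge_b = northern_edge(before, species, quantile, depth_window, seasons, n_min)
        edge_a = northern_edge(after, species, quantile, depth_window, seasons, n_min)
    except InsufficientDataError:
        return ShiftEstimate(species=species, metric="northern_edge_deg",
                             value_before=None, value_after=None, delta=None)
    delta_deg = edge_a - edge_b
    yr_b = float(np.median(occ_b["year"]))
    yr_a = float(np.median(occ_a["year"]))
    dt = yr_a - yr_b
    speed = delta_deg * KM_PER_DEGREE_LAT / dt if dt > 0 else np.nan
    return ShiftEstimate(
        species=species, metric="northern_edge_deg",
        value_before=edge_b, value_after=edge_a, delta=delta_deg,
        speed_km_per_yr=speed, n_before=len(occ_b), n_after=len(occ_a),
        classification="estimated")


# ---------------------------------------------------------------------------
# Vertical
# ---------------------------------------------------------------------------

def depth_of_max_abundance(profile: pd.DataFrame, species: str) -> float:
    """Depth (interval midpoint) of a species' peak concentration in a profile.

    Ties break to the shallowest such interval; a species absent from
    every interval yields NaN. The caller is responsible for profile
    eligibility (member count, depth coverage).
    """
    prof = profile.sort_values("depth_upper", kind="stable")
    conc = prof[species].to_numpy(dtype=float)
    if not np.any(conc > 0):
        return float("nan")
    i = int(np.nanargmax(conc))  # argmax returns the first (shallowest) max
    return float(0.5 * (prof["depth_upper"].iloc[i] + prof["depth_lower"].iloc[i]))


def profile_depths_of_max(records: pd.DataFrame, species: str,
                          min_members: int = 4, depth_cover=(0.0, 200.0)) -> pd.DataFrame:
    """Depth of maximum abundance for every eligible profile.

    Eligible profiles have >= ``min_members`` subsamples lying inside
    ``depth_cover``; others are excluded (not an error). Returns
    (profile_id, year, latitude, depth_of_max) with NaN rows dropped.
    """
    if "profile_id" not in records.columns:
        raise InsufficientDataError("records carry no profile_id; run group_profiles first")
    sub = records[(records["depth_upper"] >= depth_cover[0])
                  & (records["depth_lower"] <= depth_cover[1])]
    if sub.empty:
        return pd.DataFrame(columns=["profile_id", "year", "latitude", "depth_of_max"])
    sub = sub.sort_values(["profile_id", "depth_upper"], kind="stable")
    g = sub.groupby("profile_id", sort=False)
    ok = (g[species].transform("size") >= min_members) & (g[species].transform("max") > 0)
    eligible = sub[ok]
    if eligible.empty:
        return pd.DataFrame(columns=["profile_id", "year", "latitude", "depth_of_max"])
    # idxmax on depth-sorted rows -> first (shallowest) maximal interval
    idx = eligible.groupby("profile_id", sort=False)[species].idxmax()
    peak = eligible.loc[idx]
    return pd.DataFrame({
        "profile_id": peak["profile_id"].to_numpy(),
        "year": pd.DatetimeIndex(peak["date"]).year.to_numpy(),
        "latitude": peak["latitude"].to_numpy(dtype=float),
        "depth_of_max": 0.5 * (peak["depth_upper"].to_numpy(dtype=float)
                               + peak["depth_lower"].to_numpy(dtype=float)),
    }).reset_index(drop=True)


def one_way_anova(group_a, group_b) -> AnovaResult:
    """Two-group one-way fixed-effects ANOVA (two-sided; F = t^2).

    Raises :class:`InsufficientDataError` for groups smaller than 2 or
    zero pooled within-group variance (undefined test).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss_within == 0:
        raise InsufficientDataError("zero within-group variance: test undefined")
    F, p = stats.f_oneway(a, b)
    return AnovaResult(F=float(F), df_between=1, df_within=len(a) + len(b) - 2,
                       p_value=float(p))


def vertical_shift_test(records: pd.DataFrame, species: str, cutoff_year: int = 1997,
                        alpha: float = 0.05, min_members: int = 4,
                        depth_cover=(0.0, 200.0), seasons=("spring", "summer"),
                        devices=("net",)) -> ShiftEstimate:
    """Habitat-depth change across a cutoff year, tested by ANOVA.

    Defaults mirror the standard near-surface multinet analysis: spring
    and summer, net profiles of >= 4 members within the upper 200 m.
    Positive delta = deepening; classification at level ``alpha`` is
    ``significant_deepening`` / ``significant_shallowing`` /
    ``not_significant``, or ``insufficient_data`` when fewer than two
    valid per-profile depths exist in either period (or the ANOVA is
    undefined).
    """
    if "season" not in records.columns:
        records = add_seasons(records)
    sub = filter_records(records, seasons=seasons, devices=devices).records
    depths = profile_depths_of_max(sub, species, min_members, depth_cover)
    before = depths[depths["year"] < cutoff_year]["depth_of_max"].to_numpy()
    after = depths[depths["year"] >= cutoff_year]["depth_of_max"].to_numpy()
    est = ShiftEstimate(species=species, metric="depth_of_max_m",
                        value_before=None, value_after=None, delta=None,
                        n_before=len(before), n_after=len(after))
    if len(before) < 2 or len(after) < 2:
        return est
    est.value_before = float(before.mean())
    est.value_after = float(after.mean())
    est.sd_before = float(before.std(ddof=1))
    est.sd_after = float(after.std(ddof=1))
    est.delta = est.value_after - est.value_before
    try:
        est.p_value = one_way_anova(before, after).p_value
    except InsufficientDataError:
        return est
    if est.p_value < alpha and est.delta > 0:
        est.classification = "significant_deepening"
    elif est.p_value < alpha and est.delta < 0:
        est.classification = "significant_shallowing"
    else:
        est.classification = "not_significant"
    return est
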