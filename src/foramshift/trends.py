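"""Decadal abundance trends, latitudinal sections, thermal-response
curves and assemblage clustering.

Decadal series average a species' concentration per half-open calendar
decade within a latitudinal band and scale the decade means by their
maximum, so the largest decade maps to 1 and a fitted percent change is
read relative to the initial level. A linear regression over decade
index, with the regression-ANOVA F test of the slope, classifies each
species/band as a significant increase, significant decrease, or
neither.

Thermal responses are min-max-normalized mean concentrations on 1 degC
in-situ temperature bins; species with similar responses are grouped by
principal-coordinate analysis (Euclidean distances; with this metric
PCoA coincides with PCA of the centred matrix), retaining the first two
component scores, followed by average-linkage hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa

from .census import add_seasons, filter_records
from .errors import InsufficientDataError, ParameterError


@dataclass
class DecadalSeries:
    """Per-decade mean abundance of one species in one latitude band."""

    species: str
    band: tuple[float, float]
    decades: np.ndarray  # decade start years, ordered
    mean_norm: np.ndarray  # decade means scaled by their maximum, in [0, 1]
    n: np.ndarray
    sd: np.ndarray  # +/- 1 sigma across records, raw concentration units
    degenerate: bool = False


@dataclass
class TrendResult:
    species: str
    band: tuple[float, float]
    slope_per_decade: float
    p_value: float
    percent_change: float  # % change over the fitted period; a decline is positive
    classification: str
    alpha: float = 0.05


@dataclass
class ThermalResponse:
    species: str
    bin_centres: np.ndarray  # degC, 1-degree bins
    normalized: np.ndarray  # min-max normalized mean concentration, in [0, 1]
    n: np.ndarray = field(default_factory=lambda: np.array([]))
    period: str = "all"  # "before" | "after" | "all"


DEFAULT_BANDS = ((0.0, 30.0), (30.0, 50.0), (50.0, 90.0))


def decadal_series(records: pd.DataFrame, species: str, band=(0.0, 30.0),
                   depth_window=(0.0, 200.0), start_decade: int = 1940,
                   devices=("net", "pump")) -> DecadalSeries:
    """Mean concentration per calendar decade, scaled by the maximum decade.

    Decades are half-open ([1940, 1950), ...), starting at
    ``start_decade``; decades with no data are absent, not zero. A
    constant series is flagged degenerate with missing normalized
    values (no trend can be read from it); fewer than two populated
    decades raises :class:`InsufficientDataError`.
    """
    sub = filter_records(records, depth_range=depth_window, lat_band=band,
                         devices=devices).records
    if "year" not in sub.columns:
        sub = sub.assign(year=pd.DatetimeIndex(sub["date"]).year)
    sub = sub[sub["year"] >= start_decade]
    decade = (sub["year"] // 10) * 10
    g = sub.groupby(decade)[species]
    stats_df = pd.DataFrame({"mean": g.mean(), "n": g.size(), "sd": g.std(ddof=1)}).dropna(subset=["mean"])
    if len(stats_df) < 2:
        raise InsufficientDataError(
            f"{species}: {len(stats_df)} populated decades < 2")
    means = stats_df["mean"].to_numpy(dtype=float)
    peak = means.max()
    if peak <= 0 or means.min() == peak:
        return DecadalSeries(species, band, stats_df.index.to_numpy(),
                             np.full(len(means), np.nan), stats_df["n"].to_numpy(),
                             stats_df["sd"].to_numpy(), degenerate=True)
    return DecadalSeries(species, band, stats_df.index.to_numpy(), means / peak,
                         stats_df["n"].to_numpy(), stats_df["sd"].to_numpy())


def trend_test(series: DecadalSeries, alpha: float = 0.05) -> TrendResult:
    """OLS regression of normalized decade means on decade index.

    The p-value is the regression-ANOVA F test of the slope. Percent
    change is read from the fitted endpoints,
    ``(fitted_first - fitted_last) / fitted_first * 100`` (decline
    positive), defined when the first fitted value is positive.
    """
    if series.degenerate or len(series.decades) < 3:
        raise InsufficientDataError(f"{series.species}: degenerate or < 3 decades")
    x = (series.decades - series.decades[0]) / 10.0  # decade index
    y = series.mean_norm
    model = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(model.params[1])
    p = float(model.f_pvalue)  # single regressor: F test of the slope
    fitted_first, fitted_last = model.fittedvalues[0], model.fittedvalues[-1]
    pct = float((fitted_first - fitted_last) / fitted_first * 100.0) \
        if fitted_first > 0 else np.nan
    if p < alpha and slope < 0:
        cls = "significant_decrease"
    elif p < alpha and slope > 0:
        cls = "significant_increase"
    else:
        cls = "not_significant"
    return TrendResult(series.species, series.band, slope, p, pct, cls, alpha)


def latitudinal_section(records: pd.DataFrame, species: str,
                        depth_split: float = 100.0, lat_bin: float = 10.0,
                        since: int = 1980,
                        seasons=("spring", "summer")) -> pd.DataFrame:
    """Mean concentration per latitude bin, split at ``depth_split`` m.

    Returns long-format (lat_bin_lo, depth_section, mean, n) with
    depth_section in {"shallow", "deep"}: records wholly above the split
    are shallow, records starting at or below it deep; straddlers are
    assigned by their midpoint.
    """
    sub = records if "season" in records.columns else add_seasons(records)
    sub = filter_records(sub, seasons=seasons).records
    if "year" not in sub.columns:
        sub = sub.assign(year=pd.DatetimeIndex(sub["date"]).year)
    sub = sub[sub["year"] >= since]
    mid = 0.5 * (sub["depth_upper"] + sub["depth_lower"])
    section = np.where(mid < depth_split, "shallow", "deep")
    bin_lo = np.floor(sub["latitude"] / lat_bin) * lat_bin
    g = sub.assign(lat_bin_lo=bin_lo, depth_section=section) \
           .groupby(["lat_bin_lo", "depth_section"])[species]
    return pd.DataFrame({"mean": g.mean(), "n": g.size()}).reset_index()


def minmax(values: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; constant input maps to NaN."""
    v = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(v), np.nanmax(v)
    if hi == lo:
        return np.full_like(v, np.nan)
    return (v - lo) / (hi - lo)


def thermal_response(records: pd.DataFrame, species: str, bin_width: float = 1.0,
                     split_year: int = 1990, period: str = "all",
                     max_depth: float = 100.0) -> ThermalResponse:
    """Min-max normalized mean concentration per in-situ temperature bin.

    Records must carry a ``temperature`` column (see
    :func:`foramshift.envfields.attach_environment`) and are restricted
    to mid-depths above ``max_depth``. ``period`` selects records
    before/after ``split_year`` or all of them.
    """
    if "temperature" not in records.columns:
        raise ParameterError("records carry no temperature; attach environment first")
    sub = records[np.isfinite(records["temperature"])]
    mid = 0.5 * (sub["depth_upper"] + sub["depth_lower"])
    sub = sub[mid <= max_depth]
    if period != "all":
        year = pd.DatetimeIndex(sub["date"]).year
        sub = sub[year < split_year] if period == "before" else sub[year >= split_year]
    if sub.empty:
        raise InsufficientDataError(f"{species}: no records in period {period!r}")
    centre = np.floor(sub["temperature"] / bin_width) * bin_width + bin_width / 2
    g = sub.groupby(centre)[species]
    mean = g.mean()
    if not np.any(mean.to_numpy() > 0):
        raise InsufficientDataError(f"{species}: all-zero thermal response")
    if len(mean) == 1:
        norm = np.array([1.0])  # a single populated bin is the peak by definition
    else:
        norm = minmax(mean.to_numpy())
    return ThermalResponse(species=species, bin_centres=mean.index.to_numpy(dtype=float),
                           normalized=norm, n=g.size().to_numpy(), period=period)


def response_matrix(responses: list[ThermalResponse]) -> pd.DataFrame:
    """Species x temperature-bin matrix; bins missing for a species are 0."""
    bins = sorted({b for r in responses for b in r.bin_centres})
    mat = pd.DataFrame(0.0, index=[r.species for r in responses], columns=bins)
    for r in responses:
        mat.loc[r.species, list(r.bin_centres)] = np.nan_to_num(r.normalized)
    return mat


def assemblage_clustering(matrix: pd.DataFrame, n_components: int = 2,
                          k: int = 2) -> tuple[pd.Series, np.ndarray]:
    """Cluster species by their thermal responses.

    Principal-coordinate analysis on the Euclidean inter-species
    distance matrix; the first ``n_components`` scores feed Euclidean
    distances into average-linkage agglomerative clustering cut at
    ``k`` clusters. Returns (labels indexed by species, proportion of
    variance explained per retained component).
    """
    if len(matrix) < 3:
        raise InsufficientDataError("need >= 3 species to cluster")
    if k > len(matrix):
        raise ParameterError(f"k={k} exceeds {len(matrix)} species")
    dm = DistanceMatrix(pdist(matrix.to_numpy(dtype=float)), ids=[str(i) for i in matrix.index])
    ord_res = pcoa(dm, number_of_dimensions=max(n_components, 2))
    scores = ord_res.samples.to_numpy()[:, :n_components]
    explained = ord_res.proportion_explained.to_numpy()[:n_components]
    Z = linkage(scores, method="average", metric="euclidean")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=matrix.index, name="cluster"), explained
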