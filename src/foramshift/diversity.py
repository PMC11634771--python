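"""Species richness, gridded richness maps, the latitudinal diversity
gradient, and modern-vs-pre-industrial richness differences.

Richness is the number of taxa from a fixed analysis set present
(value > 0) anywhere in a unit (a vertical profile, a sediment-trap
sample, or a sediment site). Grid cells are half-open, anchored at
(-90, -180). The latitudinal gradient takes a high percentile of unit
richness per 10-degree bin and fits a smooth curve through the
bin-centre points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .census import species_columns

logger = logging.getLogger(__name__)


def richness_per_unit(records: pd.DataFrame, taxa, unit_col: str = "profile_id") -> pd.DataFrame:
    """Per-unit species richness over a fixed analysis set.

    Returns a frame with unit_id, latitude, longitude, year, richness.
    Species outside ``taxa`` are ignored; an empty/all-zero unit scores 0.
    """
    taxa = [t for t in taxa if t in records.columns]
    if "year" not in records.columns:
        if "date" in records.columns:
            records = records.assign(year=pd.DatetimeIndex(records["date"]).year)
        else:  # sediment sites carry no collection date
            records = records.assign(year=np.nan)
    g = records.groupby(unit_col)
    present = (g[taxa].max() > 0) if taxa else pd.DataFrame(index=g.size().index)
    out = pd.DataFrame({
        "unit_id": present.index.astype(str),
        "latitude": g["latitude"].first().to_numpy(),
        "longitude": g["longitude"].first().to_numpy(),
        "year": g["year"].first().to_numpy(),
        "richness": present.sum(axis=1).to_numpy(dtype=int) if taxa else 0,
    })
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class GridSpec:
    """Half-open global grid anchored at (-90, -180)."""

    cell_lat: float
    cell_lon: float

    def cell_of(self, lat, lon):
        """Lower edges of the cell containing each point (boundary -> upper cell)."""
        i = np.floor((np.asarray(lat, dtype=float) + 90.0) / self.cell_lat)
        j = np.floor((np.asarray(lon, dtype=float) + 180.0) / self.cell_lon)
        return -90.0 + i * self.cell_lat, -180.0 + j * self.cell_lon


def gridded_richness(records: pd.DataFrame, grid: GridSpec,
                     reducer: str = "max") -> pd.DataFrame:
    """Reduce unit richness per occupied grid cell (empty cells absent)."""
    if reducer not in ("max", "mean"):
        raise ValueError(f"reducer must be 'max' or 'mean', got {reducer!r}")
    lat_lo, lon_lo = grid.cell_of(records["latitude"], records["longitude"])
    df = pd.DataFrame({"cell_lat_lo": lat_lo, "cell_lon_lo": lon_lo,
                       "richness": records["richness"].to_numpy()})
    out = df.groupby(["cell_lat_lo", "cell_lon_lo"], as_index=False)["richness"].agg(reducer)
    return out


def latitudinal_gradient(records: pd.DataFrame, bin_deg: float = 10.0,
                         percentile: float = 95.0,
                         smoother: str = "spline", lam: float | None = None) -> pd.DataFrame:
    """Latitudinal diversity gradient.

    Per ``bin_deg`` latitude bin (half-open, anchored at -90; the
    topmost bin includes 90), the given percentile of unit richness
    (linear-interpolation quantile). A penalized cubic smoothing spline
    (GCV-selected stiffness unless ``lam`` is given) is fitted through
    the (bin centre, percentile) points when at least 4 bins are
    populated; otherwise fitted values are NaN with a warning.

    Returns a frame (bin_centre, percentile, fitted) over populated bins.
    """
    lat = records["latitude"].to_numpy(dtype=float)
    edges = np.floor((lat + 90.0) / bin_deg)
    centres = -90.0 + (edges + 0.5) * bin_deg
    df = pd.DataFrame({"bin_centre": centres, "richness": records["richness"].to_numpy()})
    pct = (df.groupby("bin_centre")["richness"]
             .quantile(percentile / 100.0, interpolation="linear")
             .rename("percentile").reset_index()
             .sort_values("bin_centre"))
    x = pct["bin_centre"].to_numpy()
    y = pct["percentile"].to_numpy(dtype=float)
    if smoother == "none" or len(x) < 4:
        if smoother != "none":
            logger.warning("latitudinal_gradient: %d populated bins < 4, smoother skipped", len(x))
        pct["fitted"] = np.nan if len(x) < 4 or smoother == "none" else y
        return pct.reset_index(drop=True)
    spline = make_smoothing_spline(x, y, lam=lam)
    pct["fitted"] = spline(x)
    return pct.reset_index(drop=True)


def _pooled_cell_richness(presence: pd.DataFrame, taxa, grid: GridSpec) -> pd.DataFrame:
    taxa = [t for t in taxa if t in presence.columns]
    lat_lo, lon_lo = grid.cell_of(presence["latitude"], presence["longitude"])
    df = presence[taxa].gt(0).copy()
    df["cell_lat_lo"], df["cell_lon_lo"] = lat_lo, lon_lo
    pooled = df.groupby(["cell_lat_lo", "cell_lon_lo"])[taxa].any()
    return pooled.sum(axis=1).rename("richness").reset_index()


def richness_change(modern: pd.DataFrame, preindustrial: pd.DataFrame, taxa,
                    grid: GridSpec = GridSpec(4.5, 9.0)) -> dict[str, pd.DataFrame]:
    """Signed per-cell richness difference, modern minus pre-industrial.

    Both inputs are presence tables (latitude, longitude + species
    columns; any positive value counts as presence) reduced to the same
    analysis set. Cell richness pools presence across all units in the
    cell (union). Positive difference = modern gain. Cells occupied in
    only one dataset are reported separately, not as differences.

    Returns dict with keys ``difference``, ``modern_only``, ``preindustrial_only``.
    """
    m = _pooled_cell_richness(modern, taxa, grid)
    p = _pooled_cell_richness(preindustrial, taxa, grid)
    merged = m.merge(p, on=["cell_lat_lo", "cell_lon_lo"], how="outer",
                     suffixes=("_modern", "_pre"), indicator=True)
    both = merged[merged["_merge"] == "both"].copy()
    both["difference"] = (both["richness_modern"] - both["richness_pre"]).astype(int)
    return {
        "difference": both[["cell_lat_lo", "cell_lon_lo", "richness_modern",
                            "richness_pre", "difference"]].reset_index(drop=True),
        "modern_only": merged[merged["_merge"] == "left_only"][
            ["cell_lat_lo", "cell_lon_lo", "richness_modern"]].reset_index(drop=True),
        "preindustrial_only": merged[merged["_merge"] == "right_only"][
            ["cell_lat_lo", "cell_lon_lo", "richness_pre"]].reset_index(drop=True),
    }
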