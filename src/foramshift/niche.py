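"""Two-dimensional (temperature, Omega_calcite) niche envelopes and
emergence under scenario fields.

The occupied niche of a species set (or latitude band) is summarized as
the convex hull of its (T, Omega) sample-point cloud after trimming
each margin to quantiles (default 1%/99%) to shed outliers. Projecting
every historical sampling location into a scenario field at a future
horizon year (month-of-year preserved) gives a future point cloud; the
*emergence fraction* is the share of those points falling strictly
outside the current envelope (boundary points count as inside). High
emergence means conditions unlike anything in the currently occupied
niche.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

from .envfields import GriddedField, decimal_year, omega_field
from .errors import InsufficientDataError, ParameterError

DEFAULT_BANDS = {"tropical": (0.0, 30.0), "mid": (30.0, 50.0), "high": (50.0, 90.0)}


@dataclass
class NicheEnvelope:
    """A closed occupancy region in (temperature, Omega_calcite) space."""

    polygon: Polygon
    n_input: int
    n_retained: int
    trim: tuple[float, float]
    scope: str = ""

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def vertices(self) -> np.ndarray:
        return np.asarray(self.polygon.exterior.coords)


def build_niche(points: pd.DataFrame, trim: tuple[float, float] = (0.01, 0.99),
                scope: str = "") -> NicheEnvelope:
    """Trimmed convex hull of a (temperature, omega_calcite) point cloud.

    Temperature and Omega are trimmed independently to the ``trim``
    quantiles before the hull is taken; requires >= 10 finite points.
    """
    pts = points[["temperature", "omega_calcite"]].to_numpy(dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) < 10:
        raise InsufficientDataError(f"need >= 10 points to build a niche, got {len(pts)}")
    lo_t, hi_t = np.quantile(pts[:, 0], trim)
    lo_o, hi_o = np.quantile(pts[:, 1], trim)
    keep = ((pts[:, 0] >= lo_t) & (pts[:, 0] <= hi_t)
            & (pts[:, 1] >= lo_o) & (pts[:, 1] <= hi_o))
    retained = pts[keep]
    hull = MultiPoint(retained).convex_hull
    if hull.geom_type != "Polygon":  # degenerate (collinear) cloud
        hull = hull.buffer(1e-9)
    return NicheEnvelope(polygon=hull, n_input=len(pts), n_retained=len(retained),
                         trim=trim, scope=scope)


def project_conditions(records: pd.DataFrame,
                       temperature: GriddedField,
                       co3: GriddedField | None = None,
                       co3satcalc: GriddedField | None = None,
                       omega: GriddedField | None = None,
                       horizon_year: int = 2050,
                       clamp_tol: float = 1.0) -> pd.DataFrame:
    """Conditions at every historical sampling location at a horizon year.

    Each record's (lat, lon, depth-midpoint, month-of-year) is
    re-evaluated in the scenario fields with the calendar year replaced
    by ``horizon_year`` (seasonality retained). Raises
    :class:`ParameterError` when the horizon lies outside the scenario
    time span; points without coverage come back NaN (logged by count).
    """
    if omega is None:
        if co3 is None or co3satcalc is None:
            raise ParameterError("supply omega or the co3/co3satcalc pair")
        omega = omega_field(co3, co3satcalc)
    t_ax = temperature.axes["time"]
    if not (t_ax[0] - 0.5 <= horizon_year + 0.5 <= t_ax[-1] + 0.5):
        raise ParameterError(f"horizon {horizon_year} outside scenario span "
                             f"[{t_ax[0]:.1f}, {t_ax[-1]:.1f}]")
    lat = records["latitude"].to_numpy(dtype=float)
    lon = records["longitude"].to_numpy(dtype=float)
    depth = 0.5 * (records["depth_upper"].to_numpy(dtype=float)
                   + records["depth_lower"].to_numpy(dtype=float))
    month_frac = decimal_year(records["date"].to_numpy()) % 1.0
    when = horizon_year + month_frac
    out = pd.DataFrame({
        "latitude": lat,
        "longitude": lon,
        "temperature": temperature.sample(lat, lon, depth, when, clamp_tol=clamp_tol),
        "omega_calcite": omega.sample(lat, lon, depth, when, clamp_tol=clamp_tol),
        "horizon": horizon_year,
    })
    return out


def emergence_fraction(future: pd.DataFrame, envelope: NicheEnvelope) -> float:
    """Fraction of future points strictly outside the envelope.

    Boundary points count as inside; NaN points are excluded from the
    denominator.
    """
    pts = future[["temperature", "omega_calcite"]].to_numpy(dtype=float)
    pts = pts[np.all(np.isfinite(pts), axis=1)]
    if len(pts) == 0:
        raise InsufficientDataError("no finite future points")
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    inside = shapely.covers(envelope.polygon, geoms)  # covers includes the boundary
    return float(1.0 - inside.mean())


def band_summary(records: pd.DataFrame,
                 temperature_hist: GriddedField, omega_hist: GriddedField,
                 temperature_scen: GriddedField, omega_scen: GriddedField,
                 bands: dict[str, tuple[float, float]] = None,
                 horizons=(2050, 2100),
                 marker_species: dict[str, list[str]] | None = None,
                 trim=(0.01, 0.99)) -> pd.DataFrame:
    """Emergence per latitude band and horizon against the current envelope.

    The envelope is built from the current conditions of *all* records
    (all species pooled); emergence is then evaluated band by band on
    the scenario conditions at each horizon. ``marker_species`` may list
    per-band highlight species; their point clouds never alter the
    envelope. The result carries an ``ordering_ok`` diagnostic column:
    whether emergence is monotone from the tropical to the high band at
    each horizon (a qualitative expectation, reported, never asserted).

    ``records`` must already carry current ``temperature`` and
    ``omega_calcite`` columns (attach_environment with the historical
    fields); rows lacking them are ignored.
    """
    bands = bands or DEFAULT_BANDS
    current = records[np.isfinite(records["temperature"])
                      & np.isfinite(records["omega_calcite"])]
    envelope = build_niche(current, trim=trim, scope="all-bands")
    _ = (temperature_hist, omega_hist)  # envelope inputs already attached to records
    rows = []
    band_names = list(bands)
    for horizon in horizons:
        frac = {}
        for name in band_names:
            lo, hi = bands[name]
            in_band = current[(current["latitude"] >= lo) & (current["latitude"] < hi)]
            if in_band.empty:
                frac[name] = np.nan
                continue
            future = project_conditions(in_band, temperature_scen, omega=omega_scen,
                                        horizon_year=horizon)
            frac[name] = emergence_fraction(future, envelope)
        vals = [frac[n] for n in band_names]
        ordering_ok = bool(np.all(np.diff([v for v in vals if np.isfinite(v)]) <= 1e-12))
        for name in band_names:
            rows.append({"band": name, "horizon": horizon,
                         "emergence_fraction": frac[name],
                         "n_markers": len((marker_species or {}).get(name, [])),
                         "ordering_ok": ordering_ok})
    return pd.DataFrame(rows)
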