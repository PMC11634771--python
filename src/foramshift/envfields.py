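"""Gridded environmental fields and interpolation to sample points.

A :class:`GriddedField` holds one variable (temperature in degC,
carbonate-ion concentration ``co3``, its calcite-saturation value
``co3satcalc``, or the saturation state ``omega_calcite``) on a regular
(lat, lon, depth, time) grid. Time is a numeric axis in decimal years at
month centres (``year + (month - 0.5)/12``). Missing cells (land, below
sea floor) are NaN.

Interpolation is multilinear across the four axes; masked neighbours are
excluded by renormalizing the corner weights over the unmasked corners,
and an all-masked neighbourhood yields NaN. Points outside the grid are
clamped to the edge within a tolerance (surface samples above the top
model level, dates outside the month-centre span) and rejected beyond it.
Longitude interpolates across the dateline when the axis spans the globe.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import DomainError, OutOfDomainError

VARIABLES = ("temperature_degC", "co3", "co3satcalc", "omega_calcite")

DIMS = ("lat", "lon", "depth", "time")


def decimal_year(dates):
    """Convert datetimes to decimal years at month-centre convention."""
    scalar = np.ndim(dates) == 0
    idx = pd.DatetimeIndex(np.atleast_1d(np.asarray(dates, dtype="datetime64[ns]")))
    out = idx.year.to_numpy() + (idx.month.to_numpy() - 0.5) / 12.0
    return float(out[0]) if scalar else out


@dataclass
class GriddedField:
    """One 4-D environmental variable supporting point interpolation."""

    data: xr.DataArray  # dims (lat, lon, depth, time)
    variable: str = "temperature_degC"

    def __post_init__(self):
        if tuple(self.data.dims) != DIMS:
            self.data = self.data.transpose(*DIMS)
        for dim in DIMS:
            ax = self.data[dim].to_numpy()
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise DomainError(f"axis {dim!r} must be strictly increasing")

    @property
    def axes(self) -> dict[str, np.ndarray]:
        return {d: self.data[d].to_numpy().astype(float) for d in DIMS}

    # -- I/O ---------------------------------------------------------------

    def to_netcdf(self, path) -> None:
        self.data.to_dataset(name=self.variable).to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, variable: str) -> "GriddedField":
        ds = xr.open_dataset(path, engine="scipy")
        return cls(data=ds[variable].load(), variable=variable)

    @classmethod
    def from_long_csv(cls, path, variable: str, value_col: str = "value") -> "GriddedField":
        """Build a field from long-format CSV (lat, lon, depth, time, value)."""
        df = pd.read_csv(path)
        idx = pd.MultiIndex.from_frame(df[list(DIMS)])
        da = xr.DataArray.from_series(pd.Series(df[value_col].to_numpy(), index=idx))
        return cls(data=da, variable=variable)

    # -- sampling ----------------------------------------------------------

    def sample(self, latitude, longitude, depth, when, clamp_tol: float = 1.0):
        """Interpolate the field to points; see module docstring.

        ``when`` may be datetimes or decimal years. ``clamp_tol`` is the
        allowed overshoot beyond the axis ends, in axis units (degrees,
        metres; time clamps unconditionally to the month-centre span).
        """
        t = np.asarray(when)
        if np.issubdtype(t.dtype, np.datetime64) or t.dtype == object:
            t = decimal_year(when)
        pts = [np.atleast_1d(np.asarray(a, dtype=float))
               for a in (latitude, longitude, depth, t)]
        n = max(len(p) for p in pts)
        pts = [np.broadcast_to(p, (n,)) for p in pts]

        axes = self.axes
        lon_ax = axes["lon"]
        periodic_lon = len(lon_ax) > 2 and (lon_ax[-1] - lon_ax[0]) + np.diff(lon_ax).mean() >= 359.0

        idx0, idx1, w1 = [], [], []
        for d, x in zip(DIMS, pts):
            ax = axes[d]
            if d == "lon" and periodic_lon:
                i0, i1, w = _bracket_periodic(ax, x)
            else:
                tol = np.inf if d == "time" else clamp_tol
                i0, i1, w = _bracket(ax, x, tol, d)
            idx0.append(i0)
            idx1.append(i1)
            w1.append(w)

        vals = self.data.to_numpy()
        acc = np.zeros(n)
        wacc = np.zeros(n)
        for corner in range(16):
            bits = [(corner >> k) & 1 for k in range(4)]
            ii = [np.where(b, i1, i0) for b, i0, i1 in zip(bits, idx0, idx1)]
            ww = np.ones(n)
            for b, w in zip(bits, w1):
                ww = ww * (w if b else 1.0 - w)
            v = vals[ii[0], ii[1], ii[2], ii[3]]
            ok = np.isfinite(v) & (ww > 0)
            acc[ok] += ww[ok] * v[ok]
            wacc[ok] += ww[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(wacc > 0, acc / wacc, np.nan)
        return float(out[0]) if np.ndim(latitude) == 0 and n == 1 else out


def _bracket(ax: np.ndarray, x: np.ndarray, tol: float, name: str):
    lo, hi = ax[0], ax[-1]
    if np.any(x < lo - tol) or np.any(x > hi + tol):
        raise OutOfDomainError(f"points beyond clamp tolerance on axis {name!r}")
    xc = np.clip(x, lo, hi)
    i1 = np.searchsorted(ax, xc, side="right")
    i1 = np.clip(i1, 1, len(ax) - 1) if len(ax) > 1 else np.zeros_like(i1)
    i0 = np.maximum(i1 - 1, 0)
    span = ax[i1] - ax[i0]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(span > 0, (xc - ax[i0]) / np.where(span > 0, span, 1.0), 0.0)
    return i0, i1, w


def _bracket_periodic(ax: np.ndarray, x: np.ndarray):
    """Bracket a longitude on a globe-spanning axis, wrapping the seam."""
    period = 360.0
    xm = (x - ax[0]) % period + ax[0]
    i1 = np.searchsorted(ax, xm, side="right")
    wrap = (i1 == len(ax)) | (i1 == 0)
    i1c = np.clip(i1, 1, len(ax) - 1)
    i0 = i1c - 1
    span = ax[i1c] - ax[i0]
    w = (xm - ax[i0]) / span
    # seam: between the last and (first + 360) node
    seam_span = (ax[0] + period) - ax[-1]
    w_seam = (xm - ax[-1]) / seam_span
    i0 = np.where(wrap, len(ax) - 1, i0)
    i1c = np.where(wrap, 0, i1c)
    w = np.where(wrap, np.clip(w_seam, 0.0, 1.0), w)
    return i0, i1c, w


def omega_from_carbonate(co3, co3satcalc):
    """Calcite saturation state Omega = co3 / co3satcalc.

    Omega < 1 means calcite dissolution is thermodynamically favoured.
    Scale-invariant in the concentration unit. Raises on non-positive
    saturation concentration.
    """
    sat = np.asarray(co3satcalc, dtype=float)
    if np.any(sat <= 0):
        raise DomainError("co3satcalc must be > 0")
    out = np.asarray(co3, dtype=float) / sat
    return float(out) if np.ndim(co3) == 0 and np.ndim(co3satcalc) == 0 else out


def omega_field(co3: GriddedField, co3satcalc: GriddedField) -> GriddedField:
    """Pointwise Omega_calcite field from the two carbonate fields."""
    sat = co3satcalc.data
    if np.any(sat.to_numpy()[np.isfinite(sat.to_numpy())] <= 0):
        raise DomainError("co3satcalc must be > 0 where unmasked")
    return GriddedField(data=co3.data / sat, variable="omega_calcite")


def attach_environment(records: pd.DataFrame,
                       temperature: GriddedField,
                       omega: GriddedField | None = None,
                       co3: GriddedField | None = None,
                       co3satcalc: GriddedField | None = None,
                       clamp_tol: float = 1.0) -> pd.DataFrame:
    """Annotate records with temperature and Omega_calcite at the sample point.

    The depth used is the midpoint of the sampled interval (the averaged
    sampled depth); time is the collection date. Omega may be supplied
    directly or as the co3/co3satcalc pair. Records without coverage are
    flagged via ``env_ok`` rather than dropped.
    """
    if omega is None:
        if co3 is None or co3satcalc is None:
            raise DomainError("supply either an omega field or the co3/co3satcalc pair")
        omega = omega_field(co3, co3satcalc)
    out = records.copy()
    lat = out["latitude"].to_numpy(dtype=float)
    lon = out["longitude"].to_numpy(dtype=float)
    depth = 0.5 * (out["depth_upper"].to_numpy(dtype=float)
                   + out["depth_lower"].to_numpy(dtype=float))
    when = out["date"].to_numpy()
    out["temperature"] = temperature.sample(lat, lon, depth, when, clamp_tol=clamp_tol)
    out["omega_calcite"] = omega.sample(lat, lon, depth, when, clamp_tol=clamp_tol)
    out["env_ok"] = np.isfinite(out["temperature"]) & np.isfinite(out["omega_calcite"])
    return out
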