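"""Synthetic survey generator with injected, known ground truth.

Emulates an idealized, zonally uniform North-Atlantic-like sector:
surface temperature decreases linearly poleward and with depth, carries
a mild seasonal cycle, and warms linearly in time; the calcite
saturation state declines multiplicatively. Species have Gaussian
thermal and depth preferences, multiplicative decadal abundance trends,
injected poleward range speeds and habitat-deepening rates. A survey
plan of multinet profiles (8 depth intervals over 0-200 m) draws
Poisson counts and splits them across mesh-size fractions with the
species' size-normalized catch curve, so every stage of the analysis
pipeline (harmonization, range-edge, habitat-depth, trend, thermal-
niche, projection) can be checked by parameter recovery against the
truth table.

Poleward movement is realized through environmental tracking: the
effective thermal optimum drifts as ``T_opt + (w - g*v)t`` (w = surface
warming per year, g = meridional gradient, v = injected speed in
deg/yr), so the realized range edge moves at exactly the injected
speed, mimicking species following isotherms. A species with
``v = w/g`` is a pure isotherm tracker whose realized thermal optimum
is constant in time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .envfields import GriddedField
from .harmonize import SYNTHETIC_MODEL, SizeNormModel, size_factor
from .migration import KM_PER_DEGREE_LAT


@dataclass(frozen=True)
class SpeciesScenario:
    """Injected ecological parameters of one synthetic species."""

    name: str
    t_opt: float  # degC, thermal optimum
    t_sd: float  # degC, thermal niche width
    depth_mode: float  # m, depth of maximum abundance at the reference year
    depth_sd: float  # m
    base_concentration: float  # ind/m^3 (>= 100 um) at the niche centre
    trend_pct_per_decade: float = 0.0  # signed % change per decade
    poleward_speed_km_per_yr: float = 0.0
    deepening_rate_m_per_decade: float = 0.0
    province: str = "subtropical"
    trophic: str = "symbiont_barren"
    f_max: float = SYNTHETIC_MODEL.f_max  # size-distribution curve
    s_half_um: float = SYNTHETIC_MODEL.s_half_um


@dataclass(frozen=True)
class WorldScenario:
    """The idealized ocean and the survey sampling plan."""

    years: tuple[int, int] = (1940, 2018)
    scenario_years: tuple[int, int] = (2019, 2100)
    # climate
    equator_surface_temp: float = 28.0  # degC
    meridional_gradient: float = 0.28  # degC per degree latitude
    depth_lapse: float = 0.02  # degC per metre
    seasonal_amplitude: float = 1.0  # degC, peak in August
    warming_rate: float = 0.2  # degC per decade (historical), depth-uniform
    scenario_warming_rate: float = 0.3  # degC per decade after the historical span
    omega_equator_surface: float = 5.8
    omega_lat_gradient: float = 0.035  # per degree latitude
    omega_depth_gradient: float = 0.004  # per metre
    omega_rel_trend_per_decade: float = -0.015  # multiplicative
    co3satcalc_surface: float = 42.0  # umol/kg
    co3satcalc_depth_slope: float = 0.02  # umol/kg per metre
    # grid
    lat_step: float = 1.0
    lon_range: tuple[float, float] = (-45.0, -5.0)
    lon_step: float = 5.0
    depth_levels: tuple[float, ...] = (0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0)
    # sampling plan
    stations_per_date: int = 120
    months: tuple[int, ...] = (3, 4, 5, 6, 7, 8)  # spring + summer
    profile_depth_edges: tuple[float, ...] = (0, 25, 50, 75, 100, 125, 150, 175, 200)
    volume_m3: float = 25.0
    device: str = "net"
    seed: int = 0

    @property
    def warming_per_year(self) -> float:
        return self.warming_rate / 10.0


# ---------------------------------------------------------------------------
# Analytic climate (single source of truth for fields and survey)
# ---------------------------------------------------------------------------

def temperature_at(world: WorldScenario, lat, depth, month, year):
    """In-situ temperature of the idealized ocean (degC), vectorized."""
    lat, depth, month, year = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat, depth, month, year)))
    tau = year + (month - 0.5) / 12.0 - world.years[0]
    hist_end = world.years[1] + 1 - world.years[0]
    warm = np.where(
        tau <= hist_end,
        world.warming_per_year * tau,
        world.warming_per_year * hist_end
        + world.scenario_warming_rate / 10.0 * (tau - hist_end))
    seasonal = world.seasonal_amplitude * np.cos(2 * np.pi * (month - 8.0) / 12.0)
    return (world.equator_surface_temp - world.meridional_gradient * lat
            - world.depth_lapse * depth + seasonal + warm)


def omega_at(world: WorldScenario, lat, depth, month, year):
    """Calcite saturation state of the idealized ocean, vectorized."""
    lat, depth, month, year = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (lat, depth, month, year)))
    tau = year + (month - 0.5) / 12.0 - world.years[0]
    base = (world.omega_equator_surface - world.omega_lat_gradient * lat
            - world.omega_depth_gradient * depth)
    return base * (1.0 + world.omega_rel_trend_per_decade * tau / 10.0)


def co3satcalc_at(world: WorldScenario, depth):
    return world.co3satcalc_surface + world.co3satcalc_depth_slope * np.asarray(depth, dtype=float)


def generate_environment(world: WorldScenario, scenario: bool = False) -> dict[str, GriddedField]:
    """Gridded monthly (temperature, co3, co3satcalc) fields.

    ``scenario=False`` covers the historical span, ``True`` the future
    span. The co3 field is constructed as Omega * co3satcalc, so
    dividing back reproduces Omega exactly.
    """
    y0, y1 = world.scenario_years if scenario else world.years
    lat = np.arange(0.0, 90.0 + world.lat_step / 2, world.lat_step)
    lon = np.arange(world.lon_range[0], world.lon_range[1] + world.lon_step / 2, world.lon_step)
    depth = np.asarray(world.depth_levels, dtype=float)
    years = np.arange(y0, y1 + 1)
    months = np.arange(1, 13)
    time = (years[:, None] + (months[None, :] - 0.5) / 12.0).ravel()
    yr_grid = np.repeat(years, 12)
    mo_grid = np.tile(months, len(years))

    shape = (len(lat), 1, len(depth), len(time))
    L = lat[:, None, None, None]
    D = depth[None, None, :, None]
    M = mo_grid[None, None, None, :]
    Y = yr_grid[None, None, None, :]
    temp = np.broadcast_to(temperature_at(world, L, D, M, Y), shape)
    omg = np.broadcast_to(omega_at(world, L, D, M, Y), shape)
    sat = np.broadcast_to(co3satcalc_at(world, D), shape)

    def mk(arr, name):
        full = np.broadcast_to(arr, (len(lat), len(lon), len(depth), len(time))).copy()
        da = xr.DataArray(full, dims=("lat", "lon", "depth", "time"),
                          coords={"lat": lat, "lon": lon, "depth": depth, "time": time})
        return GriddedField(data=da, variable=name)

    return {
        "temperature": mk(temp, "temperature_degC"),
        "co3": mk(omg * sat, "co3"),
        "co3satcalc": mk(sat, "co3satcalc"),
    }


# ---------------------------------------------------------------------------
# Species defaults
# ---------------------------------------------------------------------------

def default_species(world: WorldScenario | None = None) -> list[SpeciesScenario]:
    """The standard scenario set: each species isolates one injected effect.

    Two isotherm trackers (``v = w/g``) carry the thermal-optimum truth;
    three movers carry poleward speeds 10/5/0 km/yr; three species carry
    habitat deepenings of 50/20/0 m between the pre-/post-1997 period
    means; two carry total decadal declines of 25% and 40% over the
    1940s-2010s fitted span.
    """
    world = world or WorldScenario()
    w = world.warming_per_year  # degC/yr
    g = world.meridional_gradient
    v_track = w / g * KM_PER_DEGREE_LAT  # isotherm-tracking speed, km/yr
    # deepening rate producing a target delta between period mean years
    dd = _period_mean_gap_decades(world, cutoff_year=1997)
    span_decades = 7.0  # 1940s..2010s fitted endpoints
    r25 = (0.75 ** (1 / span_decades) - 1) * 100
    r40 = (0.60 ** (1 / span_decades) - 1) * 100
    return [
        SpeciesScenario("tracker_warm", 26.0, 3.0, 30.0, 25.0, 20.0,
                        poleward_speed_km_per_yr=v_track,
                        province="tropical", trophic="symbiont_bearing"),
        SpeciesScenario("tracker_cold", 6.0, 3.0, 30.0, 25.0, 12.0,
                        poleward_speed_km_per_yr=v_track,
                        province="subpolar", trophic="symbiont_barren"),
        SpeciesScenario("mover_10", 20.0, 1.2, 40.0, 30.0, 15.0,
                        poleward_speed_km_per_yr=10.0),
        SpeciesScenario("mover_5", 17.0, 1.2, 40.0, 30.0, 15.0,
                        poleward_speed_km_per_yr=5.0, province="temperate"),
        SpeciesScenario("mover_0", 14.0, 1.2, 40.0, 30.0, 15.0,
                        poleward_speed_km_per_yr=0.0, province="temperate"),
        SpeciesScenario("deepener_50", 24.0, 6.0, 25.0, 25.0, 15.0,
                        deepening_rate_m_per_decade=50.0 / dd,
                        province="tropical", trophic="symbiont_bearing"),
        SpeciesScenario("deepener_20", 24.0, 6.0, 40.0, 25.0, 15.0,
                        deepening_rate_m_per_decade=20.0 / dd,
                        province="tropical"),
        SpeciesScenario("deepener_0", 24.0, 8.0, 50.0, 25.0, 15.0,
                        province="tropical"),
        SpeciesScenario("decliner_25", 17.0, 8.0, 35.0, 30.0, 18.0,
                        trend_pct_per_decade=r25, province="subtropical"),
        SpeciesScenario("decliner_40", 16.0, 8.0, 35.0, 30.0, 18.0,
                        trend_pct_per_decade=r40, province="subtropical"),
    ]


def _survey_years(world: WorldScenario) -> np.ndarray:
    return np.arange(world.years[0], world.years[1] + 1)


def _period_mean_gap_decades(world: WorldScenario, cutoff_year: int) -> float:
    years = _survey_years(world)
    before, after = years[years < cutoff_year], years[years >= cutoff_year]
    if len(before) == 0 or len(after) == 0:
        return float("nan")
    return (after.mean() - before.mean()) / 10.0


def truth_table(world: WorldScenario, species: list[SpeciesScenario]) -> pd.DataFrame:
    """Injected parameters plus the implied recoverable quantities."""
    dd97 = _period_mean_gap_decades(world, 1997)
    span = 7.0
    rows = []
    for sp in species:
        rows.append({
            "species": sp.name,
            "t_opt": sp.t_opt,
            "t_sd": sp.t_sd,
            "depth_mode": sp.depth_mode,
            "depth_sd": sp.depth_sd,
            "base_concentration": sp.base_concentration,
            "trend_pct_per_decade": sp.trend_pct_per_decade,
            "poleward_speed_km_per_yr": sp.poleward_speed_km_per_yr,
            "deepening_rate_m_per_decade": sp.deepening_rate_m_per_decade,
            "deepening_delta_m_1997": sp.deepening_rate_m_per_decade * dd97,
            "percent_decline_total":
                (1.0 - (1.0 + sp.trend_pct_per_decade / 100.0) ** span) * 100.0,
            "province": sp.province,
            "trophic": sp.trophic,
        })
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# Survey generation
# ---------------------------------------------------------------------------

def _expected_concentration(world: WorldScenario, sp: SpeciesScenario,
                            lat, depth, month, year):
    """Expected >=100 um concentration (ind/m^3) of one species."""
    t_local = temperature_at(world, lat, depth, month, year)
    tau = np.asarray(year, dtype=float) + (np.asarray(month, dtype=float) - 0.5) / 12.0 \
        - world.years[0]
    v_deg = sp.poleward_speed_km_per_yr / KM_PER_DEGREE_LAT
    t_opt_eff = sp.t_opt + (world.warming_per_year
                            - world.meridional_gradient * v_deg) * tau
    mode_t = sp.depth_mode + sp.deepening_rate_m_per_decade * tau / 10.0
    trend = (1.0 + sp.trend_pct_per_decade / 100.0) ** (tau / 10.0)
    return (sp.base_concentration
            * np.exp(-((t_local - t_opt_eff) ** 2) / (2 * sp.t_sd ** 2))
            * np.exp(-((np.asarray(depth, dtype=float) - mode_t) ** 2) / (2 * sp.depth_sd ** 2))
            * trend)


def _mesh_fractions(sp: SpeciesScenario):
    """Proportions of the >=100 um stock in each mesh fraction."""
    m = SizeNormModel(f_max=sp.f_max, s_half_um=sp.s_half_um,
                      s_sup1_um=100.0, sz_norm_um=100.0)
    f150 = size_factor(150.0, m)
    p_fine = (f150 - 1.0) / (m.f_max - 1.0)  # [100, 150)
    return p_fine, 1.0 - p_fine  # and [150, OPEN)


def generate_survey(world: WorldScenario, species: list[SpeciesScenario],
                    seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the full synthetic census table plus its truth table.

    Stations are drawn uniformly over latitude 0-90 and the longitude
    sector, ``stations_per_date`` per (year, month) date, each an
    8-interval multinet profile with Poisson counts per species and
    depth interval. The mesh plan cycles by year: year % 4 == 0 samples
    the coarse [150, OPEN) fraction only, year % 4 == 1 splits the catch
    into [100, 150) and [150, OPEN) subsamples (conserving the total
    count exactly), other years retain the full [100, OPEN) fraction.
    A fixed seed makes the output bit-identical.
    """
    rng = np.random.default_rng(world.seed if seed is None else seed)
    years = _survey_years(world)
    months = np.asarray(world.months)
    n_dates = len(years) * len(months)
    n_st = n_dates * world.stations_per_date

    yr = np.repeat(np.repeat(years, len(months)), world.stations_per_date)
    mo = np.repeat(np.tile(months, len(years)), world.stations_per_date)
    lat = rng.uniform(0.0, 90.0, n_st)
    lon = rng.uniform(world.lon_range[0], world.lon_range[1], n_st)

    edges = np.asarray(world.profile_depth_edges, dtype=float)
    uppers, lowers = edges[:-1], edges[1:]
    mids = 0.5 * (uppers + lowers)
    n_d = len(mids)

    lam = np.empty((n_st, n_d, len(species)))
    for j, sp in enumerate(species):
        lam[:, :, j] = _expected_concentration(
            world, sp, lat[:, None], mids[None, :], mo[:, None], yr[:, None]) \
            * world.volume_m3

    mesh = yr % 4  # 0 coarse, 1 split, else open
    p_fine = np.array([_mesh_fractions(sp)[0] for sp in species])

    counts_open = rng.poisson(lam)  # drawn for every station; masked below
    total_split = counts_open  # same Poisson total, then binomially split
    counts_fine = rng.binomial(total_split, p_fine[None, None, :])
    counts_coarse_of_split = total_split - counts_fine
    counts_coarse_only = rng.binomial(counts_open, (1.0 - p_fine)[None, None, :])

    frames = []
    sp_names = [sp.name for sp in species]

    def block(mask, counts, size_lower, size_upper, tag):
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            return
        n_rows = len(idx) * n_d
        frames.append(pd.DataFrame({
            "subsample_id": [f"s{tag}{i}" for i in range(n_rows)],
            "sample_id": np.repeat([f"st{i}" for i in idx], n_d),
            "latitude": np.repeat(lat[idx], n_d),
            "longitude": np.repeat(lon[idx], n_d),
            "date": np.repeat(pd.to_datetime(pd.DataFrame(
                {"year": yr[idx], "month": mo[idx],
                 "day": np.full(len(idx), 15)})).to_numpy(), n_d),
            "depth_upper": np.tile(uppers, len(idx)),
            "depth_lower": np.tile(lowers, len(idx)),
            "device": world.device,
            "size_lower": float(size_lower),
            "size_upper": np.nan if size_upper is None else float(size_upper),
            "volume_filtered": world.volume_m3,
            "count_kind": "raw_count",
            **{s: counts[idx, :, j].ravel() for j, s in enumerate(sp_names)},
        }))

    block(mesh == 0, counts_coarse_only, 150, None, "c")
    block(mesh == 1, counts_fine, 100, 150, "f")
    block(mesh == 1, counts_coarse_of_split, 150, None, "g")
    block((mesh != 0) & (mesh != 1), counts_open, 100, None, "o")

    census = pd.concat(frames, ignore_index=True)
    census = census.sort_values(["sample_id", "depth_upper", "size_lower"],
                                kind="stable", ignore_index=True)
    return census, truth_table(world, species)


def generate_sediment(world: WorldScenario, species: list[SpeciesScenario],
                      reference_year: int = 1900,
                      detection_threshold: float = 0.05,
                      lat_step: float = 1.0) -> pd.DataFrame:
    """Pre-industrial surface-sediment presence/absence table.

    Presence = the expected >=100 um concentration averaged over the
    upper 200 m (annual mean at the reference year) exceeds the
    detection threshold. Deterministic given the world.
    """
    lats = np.arange(lat_step / 2, 90.0, lat_step)
    lon = float(np.mean(world.lon_range))
    depths = np.linspace(10.0, 190.0, 10)
    months = np.arange(1, 13)
    out = pd.DataFrame({
        "site_id": [f"sed{i}" for i in range(len(lats))],
        "latitude": lats,
        "longitude": lon,
    })
    for sp in species:
        conc = _expected_concentration(
            world, sp, lats[:, None, None], depths[None, :, None],
            months[None, None, :], float(reference_year))
        out[sp.name] = (conc.mean(axis=(1, 2)) > detection_threshold).astype(int)
    return out
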