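"""End-to-end parameter-recovery and calibration experiments.

These drivers run the full pipeline on the synthetic survey (generate ->
harmonize -> group -> estimate) and compare estimates against the truth
table; they back both the test-suite's recovery checks and the
acceptance script. Null (zero-effect) experiments measure the realized
type-I error of each test family at alpha = 0.05.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .census import add_seasons, group_profiles
from .envfields import attach_environment
from .errors import InsufficientDataError
from .harmonize import SYNTHETIC_MODEL, harmonize_table
from .migration import one_way_anova, poleward_shift, vertical_shift_test
from .simulate import (SpeciesScenario, WorldScenario, default_species,
                       generate_environment, generate_survey)
from .trends import DecadalSeries, decadal_series, thermal_response, trend_test


def prepared_survey(seed: int, world: WorldScenario | None = None,
                    species: list[SpeciesScenario] | None = None):
    """Generate, harmonize, season-annotate and profile-group a survey."""
    world = world or WorldScenario(seed=seed)
    species = species or default_species(world)
    census, truth = generate_survey(world, species, seed=seed)
    records = harmonize_table(census, SYNTHETIC_MODEL)
    records = add_seasons(records)
    records = group_profiles(records)
    return records, truth, world


def recover_poleward_speeds(records: pd.DataFrame, species_names,
                            cutoff_year: int = 1990) -> pd.DataFrame:
    rows = []
    for name in species_names:
        est = poleward_shift(records, name, cutoff_year=cutoff_year)
        rows.append({"species": name, "speed_km_per_yr": est.speed_km_per_yr,
                     "delta_deg": est.delta,
                     "n": est.n_before + est.n_after})
    return pd.DataFrame(rows).set_index("species")


def recover_deepenings(records: pd.DataFrame, species_names,
                       cutoff_year: int = 1997, alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for name in species_names:
        est = vertical_shift_test(records, name, cutoff_year=cutoff_year, alpha=alpha)
        rows.append({"species": name, "delta_m": est.delta,
                     "classification": est.classification,
                     "p_value": est.p_value,
                     "n": est.n_before + est.n_after})
    return pd.DataFrame(rows).set_index("species")


def recover_declines(records: pd.DataFrame, species_to_band: dict[str, tuple],
                     alpha: float = 0.05) -> pd.DataFrame:
    rows = []
    for name, band in species_to_band.items():
        series = decadal_series(records, name, band=band)
        res = trend_test(series, alpha=alpha)
        rows.append({"species": name, "percent_change": res.percent_change,
                     "slope_per_decade": res.slope_per_decade,
                     "p_value": res.p_value, "classification": res.classification,
                     "n": int(series.n.sum())})
    return pd.DataFrame(rows).set_index("species")


def recover_thermal_optima(records: pd.DataFrame, species_names,
                           world: WorldScenario) -> pd.DataFrame:
    """Peak 1-degC bin of the thermal response vs the injected optimum.

    Temperatures are attached by interpolating the generated historical
    fields to each record, i.e. through the same code path real
    analyses use.
    """
    fields = generate_environment(world)
    attached = attach_environment(records, temperature=fields["temperature"],
                                  co3=fields["co3"], co3satcalc=fields["co3satcalc"])
    rows = []
    for name in species_names:
        resp = thermal_response(attached, name, period="all")
        peak = float(resp.bin_centres[int(np.nanargmax(resp.normalized))])
        rows.append({"species": name, "peak_bin_degC": peak,
                     "n": int(resp.n.sum())})
    return pd.DataFrame(rows).set_index("species"), attached, fields


# ---------------------------------------------------------------------------
# Null experiments (type-I error)
# ---------------------------------------------------------------------------

def anova_null_pvalues(n_sims: int = 2000, n: int = 20, seed: int = 0) -> np.ndarray:
    """p-values of the two-group ANOVA under a Gaussian null."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_sims)
    for i in range(n_sims):
        out[i] = one_way_anova(rng.normal(size=n), rng.normal(size=n)).p_value
    return out


def trend_null_rate(n_reps: int = 1000, n_decades: int = 8, noise_sd: float = 0.15,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of flat noisy decadal series classified as significant."""
    rng = np.random.default_rng(seed)
    decades = 1940 + 10 * np.arange(n_decades)
    hits = 0
    for _ in range(n_reps):
        means = np.clip(1.0 + rng.normal(0.0, noise_sd, n_decades), 1e-6, None)
        series = DecadalSeries("null", (0.0, 30.0), decades, means / means.max(),
                               np.full(n_decades, 10), np.full(n_decades, noise_sd))
        res = trend_test(series, alpha=alpha)
        hits += res.classification != "not_significant"
    return hits / n_reps


def vertical_null_rate(n_reps: int = 1000, n_profiles: int = 30,
                       depth_mode: float = 60.0, depth_sd: float = 30.0,
                       peak_count: float = 25.0, alpha: float = 0.05,
                       seed: int = 0,
                       depth_edges=(0, 25, 50, 75, 100, 125, 150, 175, 200)) -> float:
    """False-positive rate of the habitat-depth ANOVA with zero deepening.

    Profiles in both periods are drawn from one Poisson model (Gaussian
    depth preference); the depth of maximum abundance uses the same
    shallowest-tie-break argmax rule as the profile estimator.
    """
    rng = np.random.default_rng(seed)
    edges = np.asarray(depth_edges, dtype=float)
    mids = 0.5 * (edges[:-1] + edges[1:])
    lam = peak_count * np.exp(-((mids - depth_mode) ** 2) / (2 * depth_sd ** 2))
    counts = rng.poisson(lam, size=(n_reps, 2, n_profiles, len(mids)))
    nonzero = counts.max(axis=3) > 0
    peak_depth = mids[np.argmax(counts, axis=3)]  # argmax: first (shallowest) max
    hits = 0
    valid = 0
    for i in range(n_reps):
        a = peak_depth[i, 0][nonzero[i, 0]]
        b = peak_depth[i, 1][nonzero[i, 1]]
        try:
            res = one_way_anova(a, b)
        except InsufficientDataError:
            continue
        valid += 1
        hits += res.p_value < alpha
    return hits / valid if valid else float("nan")
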