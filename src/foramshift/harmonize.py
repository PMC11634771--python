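"""Size-normalized catch model.

Plankton-net catches taken with different mesh sizes retain different
test-diameter (size-fraction) windows and are not directly comparable.
The size-normalized catch model maps a concentration measured in an
arbitrary size fraction ``[sz_inf, sz_sup)`` onto the concentration that
a net retaining everything above a common normalization size
(``sz_norm``, default 100 um) would have caught.

The model is a saturating multiplication factor over test size ``S``::

    f(S) = 1 + (f_max - 1) * (S - S_sup1) / ((S - S_sup1) + (S_half - S_sup1))

where ``S_sup1`` is the upper bound of the first size class (f = 1
there), ``S_half`` the size at which f reaches the midpoint between 1
and ``f_max``, and ``f(OPEN) = f_max``. The cumulative concentration of
individuals larger than ``S`` is proportional to ``f_max - f(S)``, so a
measured fraction rescales as::

    C_norm = C_measured * (f_max - f(sz_norm)) / (f(sz_sup) - f(sz_inf))

``f_max`` and ``S_half`` are application-level calibration constants and
must be supplied by the caller; :data:`SYNTHETIC_MODEL` provides
documented synthetic defaults used by the test-suite and simulator only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .census import species_columns
from .errors import DegenerateFractionError, DomainError, UnitConversionError

#: Sentinel for an unbounded top size fraction.
OPEN = math.inf


@dataclass(frozen=True)
class SizeNormModel:
    """Parameters of the size-normalized catch model.

    Attributes
    ----------
    f_max : float
        Asymptotic multiplication factor (> 1).
    s_half_um : float
        Size at which f reaches the midpoint between 1 and f_max (um).
    s_sup1_um : float
        Upper bound of the first size class (um); f(s_sup1_um) = 1.
    sz_norm_um : float
        Normalization size (um); concentrations are reported for
        individuals >= this size.
    """

    f_max: float
    s_half_um: float
    s_sup1_um: float = 100.0
    sz_norm_um: float = 100.0

    def __post_init__(self):
        if not self.f_max > 1:
            raise DomainError(f"f_max must be > 1, got {self.f_max}")
        if not (self.s_half_um > self.s_sup1_um > 0):
            raise DomainError("requires S_half > S_sup1 > 0")
        if not self.sz_norm_um > 0:
            raise DomainError("sz_norm must be > 0")


#: Synthetic defaults for tests and the simulator; real analyses must
#: supply calibrated values.
SYNTHETIC_MODEL = SizeNormModel(f_max=3.0, s_half_um=200.0, s_sup1_um=100.0, sz_norm_um=100.0)


def size_factor(S, model: SizeNormModel):
    """Multiplication factor f(S); accepts scalars or arrays, and OPEN.

    Raises :class:`DomainError` below the first size class.
    """
    s = np.asarray(S, dtype=float)
    if np.any(s < model.s_sup1_um):
        raise DomainError(f"size below first size class bound {model.s_sup1_um} um")
    d = s - model.s_sup1_um
    with np.errstate(invalid="ignore"):
        f = 1.0 + (model.f_max - 1.0) * d / (d + (model.s_half_um - model.s_sup1_um))
    f = np.where(np.isinf(s), model.f_max, f)
    return float(f) if np.ndim(S) == 0 else f


def normalize_concentration(concentration, sz_inf, sz_sup, model: SizeNormModel):
    """Concentration of individuals >= sz_norm implied by one measured fraction.

    ``C_norm = C * (f_max - f(sz_norm)) / (f(sz_sup) - f(sz_inf))``.
    ``sz_sup`` may be OPEN (``math.inf`` or NaN).
    """
    sz_sup = np.where(np.isnan(np.asarray(sz_sup, dtype=float)), OPEN, sz_sup)
    f_lo = size_factor(sz_inf, model)
    f_hi = size_factor(sz_sup, model)
    denom = f_hi - f_lo
    if np.any(np.asarray(denom) <= 0):
        raise DegenerateFractionError("zero-width size fraction: f(sz_sup) == f(sz_inf)")
    numer = model.f_max - size_factor(model.sz_norm_um, model)
    return np.asarray(concentration, dtype=float) * numer / denom if np.ndim(concentration) \
        else float(concentration) * numer / float(denom)


def normalized_total(fractions, model: SizeNormModel) -> float:
    """Normalize a set of adjacent measured fractions as one combined window.

    ``fractions`` is an iterable of ``(concentration, sz_inf, sz_sup)``
    covering contiguous windows. Their measured concentrations are summed
    over the combined window and normalized once, which makes the result
    additive over any partition of the window: the factor denominator
    telescopes, ``(f_b - f_a) + (f_max - f_b) = f_max - f_a``.
    """
    fr = sorted(fractions, key=lambda t: t[1])
    for (_, _, hi), (_, lo, _) in zip(fr[:-1], fr[1:]):
        if not math.isclose(hi, lo, rel_tol=1e-9):
            raise DomainError(f"fractions are not contiguous at {hi} != {lo}")
    total = sum(c for c, _, _ in fr)
    return normalize_concentration(total, fr[0][1], fr[-1][2], model)


def to_concentration(count, volume_filtered):
    """Convert a raw count to individuals per m^3."""
    if volume_filtered is None or (isinstance(volume_filtered, float) and math.isnan(volume_filtered)) \
            or volume_filtered <= 0:
        raise UnitConversionError(f"volume_filtered must be > 0, got {volume_filtered}")
    return count / volume_filtered


def harmonize_table(records: pd.DataFrame, model: SizeNormModel,
                    per_species: dict[str, SizeNormModel] | None = None,
                    only_above_norm: bool = True) -> pd.DataFrame:
    """Convert a census table to size-normalized concentrations.

    Raw counts are divided by the filtered volume, then each size
    fraction is rescaled to the >= sz_norm equivalent with the catch
    model (optionally per species via ``per_species`` overrides).

    Adds provenance columns: ``harmonized`` (bool) and ``quantifiable``
    (False for fractions lying wholly below sz_norm, which are never
    extrapolated; their values are left in place but flagged). Records
    with raw counts and no usable volume are flagged unquantifiable.

    With ``only_above_norm`` (default), fractions whose lower bound is
    below sz_norm but that extend above it are treated as already
    quantifying the >= sz_norm stock when ``sz_inf <= sz_norm`` and the
    top is open; bounded straddling fractions are rescaled from sz_norm.
    """
    out = records.copy()
    sp = species_columns(out)
    n = len(out)

    sz_inf = out["size_lower"].to_numpy(dtype=float)
    sz_sup = out["size_upper"].to_numpy(dtype=float)
    sz_sup = np.where(np.isnan(sz_sup), OPEN, sz_sup)
    vol = out["volume_filtered"].to_numpy(dtype=float)
    is_raw = (out["count_kind"] == "raw_count").to_numpy()

    norms = np.array([(per_species or {}).get(s, model).sz_norm_um for s in sp])
    if len(set(norms)) > 1:
        raise DomainError("per-species models must share sz_norm")

    quantifiable = ~(sz_sup <= model.sz_norm_um)  # wholly below the norm size
    has_vol = np.isfinite(vol) & (vol > 0)
    usable = quantifiable & (~is_raw | has_vol)

    values = out[sp].to_numpy(dtype=float)
    conc = np.where(is_raw[:, None] & has_vol[:, None], values / vol[:, None], values)
    conc = np.where(is_raw[:, None] & ~has_vol[:, None], np.nan, conc)

    # clip fraction bounds into the model domain: a fraction straddling
    # sz_norm only quantifies its >= sz_norm part
    lo = np.clip(sz_inf, model.sz_norm_um, None)
    factors = np.empty((n, len(sp)))
    for j, s in enumerate(sp):
        m = (per_species or {}).get(s, model)
        mask = usable
        f_lo = np.ones(n)
        f_hi = np.full(n, m.f_max)
        f_lo[mask] = size_factor(np.clip(lo[mask], m.s_sup1_um, None), m)
        f_hi[mask] = size_factor(np.clip(sz_sup[mask], m.s_sup1_um, None), m)
        denom = f_hi - f_lo
        numer = m.f_max - size_factor(m.sz_norm_um, m)
        with np.errstate(divide="ignore", invalid="ignore"):
            factors[:, j] = np.where(denom > 0, numer / denom, np.nan)
    normed = conc * factors

    out[sp] = np.where(usable[:, None], normed, np.where(quantifiable[:, None], np.nan, values))
    out["count_kind"] = "concentration"
    out["harmonized"] = usable
    out["quantifiable"] = quantifiable & (~is_raw | has_vol)
    _ = only_above_norm  # retained switch: fractions below sz_norm are never rescaled either way
    return out
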