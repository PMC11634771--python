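# foramshift

Quantifying three-dimensional distribution change in planktonic
foraminifera (PF) from water-column census data.

Planktonic foraminifera are calcifying marine zooplankton whose shells
both record modern biodiversity and accumulate in sediments, linking the
historical and fossil records. A century of census counts — plankton
nets, continuous plankton recorders (CPR), pumps and sediment traps —
can reveal how these species respond to ocean warming and acidification:
by migrating poleward, by moving deeper in the water column, by
declining in abundance, or not at all. But raw catches are incomparable
across devices and mesh sizes, so every inference rests on careful
harmonization first.

`foramshift` implements that analysis chain as a tested, reusable
library for plankton ecologists and palaeoceanographers:

1. **Census model** — validated ingest of subsample tables (one row per
   plankton aliquot: location, date, depth interval, device, size
   fraction, volume, per-species counts), taxonomic lumping,
   hemisphere-aware seasons, vertical-profile grouping, predicate
   filtering.
2. **Size-fraction harmonization** — the size-normalized catch model.
   With a saturating multiplication factor over test size *S*

   $$f(S) = 1 + (f_{\max}-1)\,\frac{S - S_{\sup,1}}{(S - S_{\sup,1}) + (S_{\text{half}} - S_{\sup,1})},$$

   a concentration measured in the size window $[sz_{\inf}, sz_{\sup})$
   rescales to the common $\ge sz_{\text{norm}}$ (100 µm) standard as

   $$C^{\infty}_{sz_{\text{norm}}} = C^{sz_{\sup}}_{sz_{\inf}}\;
     \frac{f_{\max} - f_{sz_{\text{norm}}}}{f_{sz_{\sup}} - f_{sz_{\inf}}}.$$

3. **Environmental fields** — 4-D (lat, lon, depth, month) gridded
   temperature and carbonate fields with mask-aware multilinear
   interpolation to sample points, and the calcite saturation state
   $\Omega_{\text{calcite}} = \mathrm{co3}/\mathrm{co3satcalc}$.
4. **Diversity** — species richness per profile/site, gridded richness
   maps, the latitudinal diversity gradient (95th percentile of richness
   per 10° bin plus a penalized-spline smoother), and modern minus
   pre-industrial richness differences on a shared taxon set.
5. **3-D migration** — the poleward range edge as the 95th percentile of
   occurrence latitudes ("northernmost 5%"), edge shifts across a cutoff
   year in km yr⁻¹; the depth of maximum abundance on ≥4-sample multinet
   profiles and its deepening/shallowing tested by two-group ANOVA.
6. **Trends & thermal niches** — decadal abundance series per
   latitudinal band with OLS + ANOVA trend classification; 1 °C-binned
   thermal responses; PCoA + average-linkage clustering of species with
   similar responses.
7. **Niche projection** — trimmed-convex-hull envelopes in
   (temperature, Ω_calcite) space and the *emergence fraction*: the share
   of sampling locations whose projected future conditions fall outside
   the currently occupied niche.
8. **Synthetic surveys** — an idealized warming, acidifying ocean and a
   multinet survey plan with species whose thermal optima, habitat
   depths, poleward speeds, deepening rates and abundance trends are
   injected and recorded in a truth table, so every estimator is
   validated by parameter recovery.

## Worked example

Simulate a survey with two injected behaviours and recover them:

```python
from foramshift import (WorldScenario, SpeciesScenario, generate_survey,
                        harmonize_table, SYNTHETIC_MODEL, add_seasons,
                        group_profiles, poleward_shift, vertical_shift_test)

world = WorldScenario(years=(1960, 2018), stations_per_date=100, seed=42)
species = [
    SpeciesScenario("G_ruber_like", t_opt=24.0, t_sd=2.0, depth_mode=30.0,
                    depth_sd=25.0, base_concentration=15.0,
                    poleward_speed_km_per_yr=8.0),
    SpeciesScenario("G_calida_like", t_opt=25.0, t_sd=6.0, depth_mode=20.0,
                    depth_sd=25.0, base_concentration=12.0,
                    deepening_rate_m_per_decade=14.0),
]
census, truth = generate_survey(world, species, seed=42)
records = group_profiles(add_seasons(harmonize_table(census, SYNTHETIC_MODEL)))

edge = poleward_shift(records, "G_ruber_like", cutoff_year=1990)
vert = vertical_shift_test(records, "G_calida_like", cutoff_year=1997)
```

This prints (formatting the two estimates):

```
G_ruber_like  edge 36.30 -> 38.20 deg N, speed 7.06 km/yr (injected 8.0)
G_calida_like depth of max abundance 41.5 -> 81.6 m (significant_deepening, p=0.0e+00)
```

The warm-water species' range edge (95th percentile of occurrence
latitudes, 0–100 m, spring/summer) moved ~1.9° poleward between the
pre- and post-1990 periods — a speed of 7.06 km yr⁻¹ against the
injected 8 km yr⁻¹ — while the second species' habitat depth deepened by
~40 m (truth-table value 41.3 m between the period means), correctly
classified as a significant deepening at α = 0.05.

## Command line

A thin CLI wraps the library: `foramshift ingest | harmonize |
attach-env | gradient | migrate | trends | simulate | niche`. See
`foramshift --help`.

See `docs/methods.md` for the model descriptions, parameter defaults,
numerical conventions and known limitations.
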