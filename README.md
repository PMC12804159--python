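# delivloc

Estimation of **where births happen** — the share of live births delivered
in public/non-profit hospitals, private for-profit hospitals,
public/non-profit lower-level facilities, private for-profit lower-level
facilities, or outside any facility — for a hierarchy of countries over an
estimation period (by default 1995–2023), from heterogeneous survey
microdata.

It is written for health-systems and epidemiological modellers who need
complete, uncertainty-quantified country-year time series of the delivery
location mix from fragmentary inputs: surveys with incompatible response
options, 5-year recall windows, partial information on facility level
(hospital vs lower-level, defined by comprehensive emergency obstetric and
neonatal care capability) and ownership sector, and an externally estimated
total in-facility delivery share.

## Method

1. **Categorisation.** Each survey response option is mapped to
   (facility status, level, sector) by an ordered keyword rulebook with
   per-country overrides; remaining level-ambiguous options are sorted by
   their caesarean-section rate against the hospital/lower comparator rates
   in the same source (hospitals perform caesareans; lower-level facilities
   largely do not). Private non-profit is merged with public for modelling.
   A location-year enters the level-and-sector models only if ≥85% of its
   facility births carry both level and sector, and the level-only models
   only if ≥95% carry at least level.

2. **Preparation.** Six indicators are tabulated per (source, country,
   birth year), all as shares *p* of live births: the four level×sector
   categories and the two level totals. Unknown level/sector mass is
   redistributed proportionally to the known categories (level first, then
   sector within level), conserving facility mass exactly. Each datum gets
   a Kish effective sample size `n_eff = (Σw)²/Σw²` and sampling variance
   `p(1−p)/n_eff`; modelling happens on the clamped logit scale.

3. **ST-GPR.** Per indicator, a three-stage spatiotemporal Gaussian process
   regression:
   - *stage 1*: linear mixed-effects models (nested random intercepts for
     super-region/region/country) over every covariate subset, combined
     with weights `w_i ∝ 1/RMSE_i` from source-level cross-validation;
   - *stage 2*: space–time weighted smoothing of the data residuals,
     with time weights `(1 − (Δt/(1+Δt_max))^λ)³` and hierarchy-tier space
     weights ζ, ζ(1−ζ), ζ(1−ζ)²;
   - *stage 3*: per country, GP conditioning over years with the smoothed
     series as prior mean, Matérn-5/2 kernel `η²·m₅⁄₂(|Δt|/ℓ)` (amplitude η
     from the stage-1/stage-2 disagreement), and the data's sampling
     variance as noise. Posterior draws are back-transformed to shares.

4. **Raking & aggregation.** Per draw, (hospital, lower) totals are scaled
   multiplicatively into the supplied in-facility envelope; the sector
   pairs are then scaled into the resulting hospital/lower envelopes;
   non-facility is one minus the envelope — so the five shares sum to one
   exactly, draw by draw. Countries aggregate to regions and the global
   total by live births. Uncertainty intervals are the 2.5th/97.5th
   percentiles over draws; the 1995→2023 facility increase is decomposed
   into per-category contributions per draw.

A fully synthetic world generator (hierarchy, births, covariates, true
compositions, envelope draws, multi-survey microdata with a ~45-label
response dialect) provides ground truth for every stage; no external data
are required.

## Worked example

```python
import pandas as pd
import delivloc as dl
from delivloc.synthetic_data import SimulationConfig

config = dl.RunConfig(
    seed=3,
    n_draws=100,
    output_dir="out",
    simulation=SimulationConfig(
        n_super_regions=1, n_regions_per=2, n_countries_per=2,
        year_start=2000, year_end=2012,
        n_surveys_per_country=2, births_per_survey=400,
    ),
)
manifest = dl.run_all(config)

table = pd.read_csv("out/table_2012.csv")
print(table[["location_id", "pub_hosp", "priv_hosp", "non_facility"]])
```

prints the 2012 report table (mean and 95% uncertainty interval, percent):

```
location_id         pub_hosp        priv_hosp     non_facility
     global 68.0 (66.3–69.8)    6.1 (5.1–7.2) 12.0 (11.1–13.1)
        R00 81.6 (79.7–83.5)    1.1 (0.6–1.9)    7.9 (7.0–9.0)
        R01 51.8 (48.9–54.7)  12.1 (9.9–14.7) 16.8 (14.9–18.7)
       C000 83.7 (81.2–85.8)    0.4 (0.2–0.7)    5.0 (4.3–6.1)
       C001 79.2 (75.9–82.1)    1.9 (0.9–3.5)  11.3 (9.1–13.1)
       C010 59.6 (55.8–62.5)    4.7 (2.9–7.2) 14.3 (12.0–17.1)
       C011 43.7 (39.7–47.6) 19.7 (16.2–24.0) 19.3 (16.5–22.6)
```

So in this simulated world, 68.0% of 2012 births were in public or
non-profit hospitals globally, with the two regions differing sharply
(81.6% vs 51.8%). `out/change_decomposition.csv` attributes the rise in
facility delivery over 2000–2012 to categories; here public hospitals
carried 77.3% of the 15.5-percentage-point increase. Every mean and
interval is computed on the 100 posterior draws, never on summaries.

The same run is available from the shell:

```bash
delivloc run-all --config config.yaml --seed 3 --out out
```

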