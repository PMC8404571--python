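# erebia

Flight-curve abundance and phenology indices from butterfly transect
counts, with single-predictor ΔAIC screening of seasonal climate effects.

## What it is for

Long-term butterfly monitoring schemes walk fixed transects several times a
week during the flight season and count the adults seen. Ecologists then
want to know, per transect and year: *how many* butterflies flew (a relative
abundance index), *when* the flight period started and *how long* it lasted
— and which climate conditions experienced by the developing larvae (autumn
feeding, overwintering, spring feeding) or by the adults themselves drive
those quantities. This package implements that entire chain for
univoltine mountain species such as *Erebia* ringlets:

1. **Flight curves.** Counts standardized per km of transect are smoothed
   over day-of-year with a penalized cubic-spline GAM (basis dimension
   k = 4, log link, quasi-Poisson variance; penalty chosen by Pearson-based
   GCV). Zero pseudo-counts one week before the first and two weeks after
   the last walk pull the curve to zero outside the season.
2. **Indices.** The **PAI** (population abundance index) is the area under
   the fitted curve by the rectangle rule on a 0.01-day grid; **Onset** is
   the day when 20% of the season's fitted abundance has accrued, and
   **Duration** the 20%–80% day span.
3. **Climate predictors.** Monthly station records are aggregated into
   seasonal predictors aligned to the flight year: autumn (Sep–Oct of the
   previous year), winter (Nov–Apr), spring (May–Jun) and summer (Jul–Aug);
   temperatures are averaged, precipitation and snow days summed.
4. **Screening.** With only ~35 transect-years per dataset, predictors are
   screened one at a time: `log(index) ~ Transect` is the null and each
   standardized predictor is added alone; `ΔAIC < −6` counts as strong and
   `< −2` as moderate support. Year trends, an odd/even-year (biennial)
   contrast, a maximum-likelihood AR(1) residual check, abundance-vs-
   phenology models and Onset–Duration correlations (Fisher-z CI) complete
   the analysis.
5. **Synthetic data.** A generator produces walks and climate with known
   ground truth (negative-binomial counts under a Gaussian flight density,
   planted per-SD climate effects, biennial parity ratios), so every stage
   is testable by parameter recovery without any field data.

## Worked example

```python
import numpy as np
import erebia

cfg = erebia.SimulationConfig(
    climate_effects={"T_avg_Spr": 0.45, "P_tot_Win": 0.33},
    biennial_log_ratio=np.log(1.8),
)
sim = erebia.simulate_dataset(cfg, seed=1)
rows, curves = erebia.fit_flight_curves(sim.walks)

from erebia.climate import seasonal_table
seasonal = seasonal_table(sim.climate, list(cfg.years), cfg.station_id)
frame = erebia.build_analysis_dataset(
    rows, seasonal, {t: cfg.station_id for t in cfg.transect_ids}, label="demo"
)
screen = erebia.DeltaAICScreen(frame).fit()
for r in screen.ledgers["log_pai"]:
    if r.predictor_name in ("T_avg_Spr", "P_tot_Win"):
        print(r.predictor_name, round(r.delta_aic, 2), round(r.slope, 2), r.effect_class)
print("biennial ratio:", round(np.exp(screen.biennial.slope), 2),
      "dAIC:", round(screen.biennial.delta_aic, 2))
```

prints (seed 1):

```
P_tot_Win 1.84 0.05 none
T_avg_Spr -9.91 0.37 strong
biennial ratio: 1.5 dAIC: -1.24
```

The planted spring-temperature effect (0.45 per SD on log abundance) is
recovered as 0.37 and classed *strong* (ΔAIC −9.9). The planted 1.8×
odd-year excess is estimated at 1.5× in this replicate, and the smaller
winter-precipitation effect (0.33 per SD) is missed — at n = 36 the
screening has partial power for effects of that size, which is exactly
what the Monte-Carlo calibration in the acceptance script quantifies
(detection rates, null call rates, and 2-SE coverage over 200 replicates).

The same pipeline runs from the shell:

```bash
erebia simulate --seed 1 --out data/
erebia fit data/walks.csv --out data/indices.csv
erebia climate data/climate_monthly.csv --years 2009-2020 --out data/seasonal.csv
erebia screen data/indices.csv data/seasonal.csv --mapping map.yaml --out ledger.csv
erebia run --config pipeline.yaml --out results/
```

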