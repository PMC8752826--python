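# lagoonhab

Spatio-temporal habitat-use analysis for satellite-tracked marine
megaherbivores (dugongs) in coral-reef lagoon ecosystems — from raw
GPS fixes and lagoon geometry to ecoregions, residence-time surfaces, a
per-ecoregion habitat model, tidal/diel effect tests, and cross-validation
against an independent aerial-survey density map.

It is written for movement ecologists who have (or can simulate) animal
telemetry in a structured coastal seascape and want the full chain as
tested, importable Python rather than a pile of scripts. Because real
tracking data of this kind are typically access-restricted, the package
ships a first-class synthetic-data module that generates a three-ecoregion
lagoon, semidiurnal tides, state-switching tracks and a daytime-biased
density surface with the statistical structure the analysis assumes — every
stage is testable end to end without any download.

## The analysis

1. **Tracks.** GPS fixes are cleaned (invalid quality flags dropped, steps
   implying > 10 km/h removed, on-land fixes relocated to the nearest
   water), split at gaps > 10 h, and interpolated hourly with a
   continuous-time correlated random walk: velocity is an integrated
   Ornstein–Uhlenbeck process with autocorrelation parameter
   β ∈ [−3, 4] (Normal(0.5, 2) prior) and scale σ, fitted by maximum
   penalized likelihood through a Kalman filter with 10 m observation
   noise; positions come from the fixed-interval smoother.
2. **Residence time.** At each hourly location, the time spent inside a
   circle of radius ρ (backward + forward, excursions outside longer than
   τ = 2 h truncate the scan). ρ ∈ {1, 2, 3, 4} km is chosen by a
   per-individual variance-of-log-RT vote (1 km on the synthetic defaults);
   the series is smoothed with an order-4 centred moving average and the
   first/last 3 h of each segment are dropped.
3. **Ecoregions.** The corridor is cut into 20-km slices at 45° to the
   coast, each summarized by nine topographic variables (mean/sd of depth,
   slope and distance to patch reefs, northing, water area, summed pass
   widths); slices are Ward-clustered on z-scores and the mean silhouette
   width over k ∈ {3, 4, 5} picks the partition.
4. **Habitat model.** Intensity of use per 500-m cell (mean RT per
   individual ÷ water area, max across individuals, h/km²) is modelled as a
   negative-binomial GAM with penalized spline smooths (basis ≤ 5) of
   depth, distances and seagrass cover — fitted per ecoregion after a
   pairwise |r| > 0.7 collinearity screen.
5. **Tidal & diel cycles.** Locations are labelled high/low tide (±1 h of a
   gauge peak), dawn/day/dusk/night (03–09/09–15/15–21/21–03), and
   shallow/medium/deep ([0,2]/(2,10]/>10 m). Linear mixed models with
   individual random intercepts test tidal × diel effects on log RT and
   used depth range (Type III Wald χ², marginal/conditional R², Tukey
   post-hoc); excursions past the barrier reef are detected and their diel
   timing tested with a χ² GOF using 2000 Monte-Carlo replicates.
6. **Cross-validation.** √-transformed predictions are classed
   suitable/poor at the 90th/10th percentiles and compared with a 1.6-km
   density map: suitable cells with zero density are "newly predicted",
   poor cells with high density are "omitted", with Pearson r overall and
   in four depth strata.

## Worked example

```bash
python examples/04_habitat_model_and_crossval.py
```

prints (seed 1):

```
3315 hourly locations from 16 individuals; residence radius 1 km
retained predictors after the |r|>0.7 screen: ['depth_log', 'dist_barrier_signed', 'dist_reef', 'seagrass_cov']
deviance explained: 23.7%
...
cross-validation: overall Pearson r = 0.42; 2.1% newly predicted, 0.03% omitted
  stratum    n    r  pct_newly_predicted
  shallow 1167 0.35                 8.83
   medium 4023 0.39                 3.41
     deep 5801 0.38                 0.09
```

16 simulated animals yield ~3300 hourly positions; the GAM explains ~24% of
the deviance in intensity of use; and the model "newly predicts" suitable
habitat almost exclusively in the shallow stratum — exactly the signature
expected when a daytime survey under-samples nocturnal shallow-water use.
The other examples cover the generator (`01`), track processing and
residence time (`02`), ecoregion clustering (`03`) and the tidal/diel mixed
models and excursion timing (`05`).

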