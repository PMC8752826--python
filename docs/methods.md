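# Methods

This note documents the models and procedures implemented in `lagoonhab`,
the parameters that matter, what the synthetic study system does and does
not emulate, and the numerical choices made where the design was open.

## The synthetic study system

Everything lives in a local metric plane (x along-coast, y cross-shore);
longitude/latitude appear only at I/O boundaries through a fixed affine
anchor. Timestamps are naive local time at a fixed UTC+11 offset.

**Lagoon.** A 280-km corridor between a gently sinusoidal coastline and a
barrier reef, split into three planted regions whose contrasts mirror a
deep/wide, shallow/narrow, and shallow/medium lagoon:

| region | length (km) | width (km) | depth mean ± sd (m) | patch reefs /10 km | passes |
|---|---|---|---|---|---|
| 1 | 120 | 9.0 | 17 ± 2 | 1.6 | 6 × 1.68 km |
| 2 | 60  | 4.5 | 6.5 ± 1 | 0 | 3 × 2.33 km |
| 3 | 100 | 6.75 | 7 ± 3 | 2.0 | 5 × 1.4 km |

Depth combines a cross-shore profile (nearshore ramp, deeper mid-lagoon,
shallower back-reef), a smooth noise field (the depth sd) and a
short-wavelength roughness term that carries the per-region slope contrast.
Patch reefs are shallow (0.6 m) circles; islets are small (< 1 km²) land
patches, mostly in region 3; seagrass meadows hug the coast and cap the
depth beneath them at 4.5 m, honouring the "shallow (< 5 m) seagrass"
convention of such map products. Beyond the barrier a fore-reef shelf
(≈ 6 m) drops quadratically to > 60 m within 2.5 km.

Two geometric conventions make the planted partition a clean ground truth
for the clustering stage: region boundaries run along 45° lines (x − y =
const), parallel to the analysis slices, and passes are centred one per
20-km band. Without this, every region boundary produces a mixed-profile
slice and the silhouette criterion tends to split it off as a spurious
fourth cluster — an artefact of the corridor's artificial sharpness, not a
property of the clustering. The coastline shape itself is fixed; seeds vary
reefs, islets, meadows, noise fields, pass jitter and everything downstream.

**Tides.** A semidiurnal harmonic (period 12.42 h) around a 1.505-m mean
with amplitude 0.345 m, a ±0.015-m spring–neap envelope and 5 mm gauge
noise, sampled every 20 min. Realized high-tide peaks fall in 1.80–1.91 m
and lows in 1.10–1.28 m, the envelope of the study-period regime this
system emulates.

**Tracks.** Discrete-time movement at the 30-min fix interval with two
behavioural states — transit (2.2 km/h, low turning) and area-restricted
search (0.45 km/h, high turning) — switching with exponential dwell times
(0.25/h into ARS, 0.10/h out). Sixteen individuals with durations of 4–20
days (mean ≈ 9.6) start spread across the three regions. At dusk/night, and
more strongly at dusk/night high tide, headings are biased down the local
depth gradient toward shallow water, with slowed movement once in < 2 m;
during the day the bias reverses. The default effect strengths (3.0 each)
produce a day-high vs night-high shallow-occupancy contrast of roughly 1%
vs 35–50% — the order of magnitude of the strongest regional pattern the
analysis is designed to detect, set once and not fitted. At each dawn an
individual within 8 km of a pass starts an excursion with probability
0.08: it transits out through the pass, spends N(8, 1.5²) h on the
fore-reef shelf and returns. Observation degradations are layered on top:
10 m GPS noise, extra 60-m jitter on 30% of very-shallow fixes (the source
of on-land positions), invalid-quality fixes displaced 5–20 km (1%), and
gaps of 11–16 h (0.4%/fix).

What the generator does **not** emulate: Argos-class error ellipses, tag
loss and duty cycling, currents and tidal advection, shark-avoidance
behaviour, seasonal movements, and any feedback of seagrass depletion on
movement. Passing tests therefore demonstrate that the pipeline recovers
structure it is designed for under clean assumptions — not that it is
robust to every pathology of field data.

**Density surface.** True per-cell intensity of use is decomposed by the
night fraction of its visits; the daytime component (1 − bias ×
night_fraction, default bias 0.8) is averaged to a 1.6-km lattice, scaled
to a 0.2 dugongs/km² mean, and Poisson-thinned at a survey-effort exposure
(default 200 animal-detection units per km²-density). This reproduces the
key property of daytime aerial surveys: cells used mainly at night read as
zero density.

## Track processing

The speed filter is a forward pass with recheck: the fix terminating a
step > 10 km/h is dropped and the step recomputed from the last retained
fix. Gaps strictly longer than 10 h split segments. On-land points are
projected to the nearest point of the water polygon (domain minus all land,
so an islet point moves to that islet's shore) and displaced 1 m into
water; a point > 5 km from water raises an error, since it indicates broken
geometry rather than GPS error. Relocation is applied both before CRW
fitting and to the interpolated positions.

The CRW is the integrated Ornstein–Uhlenbeck velocity model. With
θ = exp(β) the mean-reversion rate and σ the velocity-noise scale, the
state (position, velocity) has an exact Gaussian transition over any step,
so irregular fixes cost nothing. Each coordinate is filtered independently
(shared parameters), observation noise is fixed at 10 m, and the objective
is the penalized log-likelihood with the Normal(0.5, 2) prior on β as a
quadratic penalty, maximized by L-BFGS-B within β ∈ [−3, 4]; σ is
unconstrained on the log scale. Standard errors come from the central-
difference Hessian at the optimum; self-simulation recovers both parameters
within 3 SE in ≥ 90% of replicates at n = 500. Interpolation evaluates the
RTS smoother on the union of fix times and hour marks; smoothed (not
filtered-only) states are used because prediction is retrospective.

## Residence time

The hourly path is treated as piecewise linear, so circle entry/exit times
are roots of per-step quadratics — sub-hour geometry beyond that is
unknowable. Scanning from the focal point, inside-circle time accumulates;
cumulative time outside (reset on re-entry) exceeding τ stops the scan in
that direction. The implementation is verified against an independent
oracle that enumerates every inside interval of the whole path per focal
circle and merges them by the same τ-gap rule; agreement is at 1e-6 h on
random tracks. Properties tested: RT is monotone in both ρ and τ, symmetric
under time reversal, and equals the track span for a stationary animal.

Scale selection computes the per-individual variance of log(RT + 0.1 h)
(the 0.1-h offset guards zero RT at sharp transits) at ρ ∈ {1, 2, 3, 4} km
and takes the majority argmax, ties toward the smaller radius. The order-4
centred moving average uses the standard half-weight endpoints
(1/8, 1/4, 1/4, 1/4, 1/8); the half-window at each series end is left
unsmoothed rather than partially averaged.

## Ecoregions

Slice bands are anchored on the coast curve: the number of slices is the
along-axis extent of the coast divided by the 20-km nominal width, and the
45°-band coordinate range of the coast is divided evenly, with the first
and last bands extended to cover the full domain. The nine slice variables
are unweighted means/sds over lagoon water cells (cells strictly inside the
barrier); "mean latitude" is realized as mean projected northing. Variables
are z-scored before Ward clustering because their units are incommensurate
(km, degrees, m, km²); constant variables are dropped with a warning. The
mean silhouette width over k ∈ {3, 4, 5} selects the partition, ties toward
smaller k; clusters are not constrained to be contiguous.

## Habitat model

The response in a cell is the maximum over individuals of that individual's
mean residence time there, divided by the cell's water area (500-m cells,
area × water_fraction). The negative-binomial family needs counts: hours
are rounded to integers and log water-area enters as an offset, which makes
exp(smooth terms) exactly the h/km² intensity scale. Collinearity screening
drops a predictor when |Pearson r| with another exceeds 0.7 in more than
one ecoregion; within an offending pair the member with the larger mean
absolute correlation goes, with near-ties resolved against the
lower-priority (later-listed) predictor.

One independent GAM is fitted per ecoregion — equivalent to a single model
with ecoregion-by-factor smooths up to the shared intercept and dispersion,
and matching the per-ecoregion reporting. Smooths are penalized cubic
B-splines with basis size 5 (the overfitting cap). Penalty weights are
selected by GCV over a shared log-spaced grid (0.1–1000); the NB dispersion
α is estimated by method-of-moments outer iteration (Var = μ + αμ²,
3 iterations). Per-term Wald χ² uses the spline coefficient block and its
covariance, with the block edf (from the penalized hat matrix) as test df.
Partial dependence evaluates the smooth over the central 95% of the
predictor's observed range, centred to mean zero, with a ±2 SE band.
Predictions outside any training range are clipped to it and flagged
`extrapolated`.

## Tidal and diel cycles

Tide peaks are local extrema of the lightly smoothed 20-min gauge series;
labels are high/low within a closed ±60-min window, else neither, and
"neither" locations are excluded from the cyclic models (the models
contrast high vs low). Ebb/flood is the sign of the smoothed height
derivative. Diel phases are a fixed local-clock partition with half-open
boundaries (the boundary minute belongs to the later phase). Depth bins are
closed as printed: [0, 2], (2, 10], (10, ∞) m.

The cyclic models are linear mixed models (ML) of log RT and of the
depth-bin ordinal (1, 2, 3 treated as numeric — a pragmatic reading that
yields one χ² per term) on tidal × diel with individual random intercepts,
fitted per ecoregion after removing individuals with < 10 locations.
Sum-to-zero factor coding makes the Wald block tests Type III. Marginal and
conditional R² follow the fixed/random variance partition
(var(Xβ) and +var(intercept) over the total). Post-hoc contrasts of the
eight cell means use the studentized-range (Tukey) correction. Calibration
on data simulated from the model family itself puts each term's type-I rate
inside the 95% binomial band around 5% with 16 individuals × 80 locations.

Excursions are maximal runs of hourly locations seaward of the barrier
(pass channels count as inside); crossing times are found by bisection
along the crossing step. Open-ended runs (track ends outside) are flagged
and excluded from duration statistics. The timing test compares diel
category counts with uniformity via χ², with the Monte-Carlo p-value
(1 + #{χ²_rep ≥ χ²_obs}) / (N + 1) at N = 2000 multinomial replicates; it
agrees with exact multinomial-tail enumeration to within Monte-Carlo error.

## Cross-validation

Predictions are √-transformed (rank-preserving, so classification is
unchanged by it when values are distinct — pinned in tests); cells strictly
above the 90th / below the 10th percentile (inclusive linear-interpolation
quantiles) are suitable / poor, ties fall intermediate. Each 500-m cell
inherits the density of the 1.6-km cell containing its centroid. Density
classes: low (exactly 0), medium (0, 0.10), high [0.10, 0.50], very high
(> 0.50) dugongs/km²; the unnamed (0, 0.10) range is treated as neither low
nor high for discrepancy purposes. Newly predicted = suitable ∧ low;
omitted = poor ∧ (high ∨ very high). Pearson r, t and p are reported
overall and within the four depth strata ([0,2], (2,10], (10,60], >60 m).

## Problem sizes and runtime

The shipped configuration — 16 individuals, ~9.6-day mean duration, 30-min
fixes (≈ 6 600 fixes → ≈ 3 300 hourly locations), a 280-km corridor at
100-m bathymetry and ≈ 11 600 modelled 500-m cells — was chosen so that a
full pipeline run takes on the order of a minute on one CPU and the whole
test suite a couple of minutes, while keeping every stage's sample sizes in
the regime where its statistics are meaningful (tens of locations per
tide × diel cell, hundreds of cells per ecoregion). Calibration and
recovery tests use 20–50 seeds at these sizes.

## Known limitations

- The NB-GAM's GCV-on-a-grid penalty selection is coarser than a full REML
  outer iteration; smooth terms can be slightly under- or over-penalized,
  which matters mainly for edf-based p-values near the 0.05 boundary.
- Wald χ² tests in the mixed models ignore uncertainty in the variance
  components; with few individuals they run mildly anticonservative.
- The depth-bin response is ordinal treated as numeric; a cumulative-link
  mixed model would be more principled but reports per-threshold effects.
- Relocation moves points to the nearest water, which for a fix deep inside
  a convoluted shoreline can cross headlands; with 10–60 m errors this is
  immaterial.
- The excursion detector keys on the lagoon/barrier polygons; a track that
  skims the barrier crest itself is counted as inside.
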