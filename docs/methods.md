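# Methods

## The along-shelf coordinate

All distributional inference happens on a single axis: the along-shelf
distance from an origin at the equatorward end of the continental shelf.
Latitude is a poor shift coordinate on a curved shelf (a species can move
"north along the shelf" while barely changing latitude), so distance is
measured as the shortest path over sea-and-on-shelf raster cells with the
coastline and the shelf break as barriers.

The raster algorithm is exact single-source shortest paths (Dijkstra via
`scipy.sparse.csgraph`) on an 8-connected grid. Orthogonal steps cost the
local cell dimension (north–south: Δlat·111.195 km; east–west:
Δlon·111.195·cos φ km, per row); diagonal steps cost the hypotenuse with the
east–west dimension averaged over the two rows. The test suite holds this to
an independently written Bellman–Ford relaxation oracle, exactly, on
randomized barrier worlds. Stranding coordinates are snapped to the nearest
*reachable* traversable cell by great-circle distance (3-D KD-tree on
unit-sphere coordinates); records farther than `snap_km` (default 25 km,
about two county widths at this grid scale) are flagged rather than
assigned. Default grid resolution is 0.05°; the default origin (25.2° N,
80.6° W, snapped to sea) sits at the southern end of mainland Florida.

## Record cleaning

Multi-decade stranding databases mix coordinate notations. The normalizer
declares its own inference heuristic: tokens with hemisphere letters or
space/colon-separated parts are DMS (two parts → degrees + decimal minutes);
plain numbers whose magnitude exceeds the axis bound and match the packed
`ddmm.m` pattern are DDM; anything else is DD. Minutes or seconds ≥ 60 are
rejected, west longitudes with a dropped sign are negated when the mirrored
value falls in the study bounding box, and every rejection is a reason-coded
row in a rejects report — parsing never silently drops a record.
Cross-checking against a county-centroid gazetteer flags records more than
50 km (configurable) from their described county. The NEUS/SEUS regional
split is at 35.25° N (Cape Hatteras), closed to the north.

## Shift inference

Annual center = mean poleward distance; annual trailing edge = 5th
percentile with linear interpolation between order statistics (the (n−1)p
"type 7" rule — the common software default; with one event the statistic is
that event). Years with zero events are omitted, not imputed. Trends are
unweighted OLS of the annual statistic on year; two-sided slope p-values.

Bootstrap CIs resample *event rows* with replacement at the original sample
size, conserving each event's distance–year pairing (not stratified within
year), recompute the annual statistic and slope per resample, and take the
0.025/0.975 quantiles of B = 1000 slopes. Resamples covering fewer than 3
distinct years are redrawn and counted. Multiplicity is controlled with
Dunn–Šidák, α′ = 1 − (1 − α)^(1/m), where the family m is the set of shift
tests reported together (configurable; the pipeline uses the number of
species × edge tests in the run).

Because the center is computed from in-domain records only, it understates a
shift once distributional mass exits the poleward end of the domain. Two
diagnostics flag that regime: the center-vs-trailing-edge gap
(`convergence_check`) and the fraction of events in the terminal 10% of the
domain (`censoring_fraction`, a diagnostic of this package's own design).

## Climate velocity

Scalar (gradient-ratio) velocity only: v = g_t/|∇T|, no trajectory or
bearing decomposition. g_t is the per-cell OLS slope of annual SST on year
(cells with < 3 valid years masked). |∇T| is computed on the time-mean
field: for each cell, the south–north component is the mean central
difference down the three columns of its 3×3 neighborhood, the west–east
component the mean along the three rows (with per-row cos-latitude km
scaling), magnitude by hypotenuse; border cells and cells with < 3 valid
neighbors are masked. A gradient floor ε = 1e−5 °C/km masks velocity where
the spatial gradient is effectively zero, instead of letting v diverge.
Regional summaries are unweighted cell quantiles; the anomaly series is the
regional annual mean minus the full-record climatology (baseline window
configurable).

## Power analysis

The simulator draws n events per year for T = 25 years from
N(a + b·t, σ²), computes the annual statistic (mean or 5th percentile), fits
OLS on year, and scores a detection when the two-sided p < .05 **and** the
slope sign matches b. Power is the detection fraction over 1000 replicate
datasets; `min_n` scans ascending integers n = 2..400 (or the replication
grid n ∈ {2, 5, 6, 7, 8, 10, 24, 25, 50, 66, 86, 100, 250, 331}) for the
smallest n with power ≥ 0.95. The intercept a is irrelevant (affine
invariance of the slope test; asserted by test).

Two deliberate numerical choices:

* **Analytic oracle.** For the mean statistic, the annual mean has SD σ/√n
  and the signed detection event is exactly t̂ > t₀.₉₇₅,T−₂ with
  t̂ ~ noncentral-t(df = T−2, δ = b·√(n·Sxx)/σ), Sxx = (T³−T)/12. The
  simulator is validated against this closed form point-wise within 3
  binomial MC standard errors across a 125-point (b, σ, n) grid, and its
  signed false-detection rate at b = 0 against the nominal α/2 = 0.025.
* **Common random numbers.** Simulation draws are keyed by
  (seed, n, T, statistic) only — never by b or σ. With identical draws,
  increasing b (or decreasing σ) can only convert non-detections into
  detections, so estimated power and the derived min-n surfaces are exactly
  monotone in slope and in σ rather than monotone up to Monte-Carlo noise.
  This is a variance-reduction choice; it does not bias any individual power
  estimate.

Negative slopes use the same rule with sign(b) = −1; b = 0 is rejected
("correct sign" is undefined) in favor of `power_null`.

## Synthetic data: what it does and does not emulate

The generator produces the study conditions the analysis assumes: Gaussian
event-level noise around a linear poleward drift, fixed (or per-year
specified) annual sample sizes, events placed deterministically on a
straight (optionally wavy) synthetic coastline at their along-shelf
distance, SST cubes with prescribed warming rates and a north–south spatial
gradient plus i.i.d. noise, and census tables with a prescribed
population-change-vs-distance slope. Default drift rates, σ values and
annual counts in the pipeline mirror the observed species profiles
(e.g. σ = 217–733 km, 6–331 events/yr).

It does **not** emulate: non-Gaussian or autocorrelated stranding noise,
stochastic year-to-year sample sizes, reporting-effort gradients, coastline
realism, oceanographic structure (fronts, rings) or spatially correlated SST
noise. Passing tests therefore demonstrate correctness of the estimators
under the stated model, and calibration of the simulator against its own
assumptions — not robustness of the method to real-data violations of
those assumptions.

## Problem sizes and tolerances in the test suite

The suite runs the bootstrap-coverage check at 200 outer replicates × 1000
bootstrap resamples for the headline condition (σ = 307, n = 20, b = 10; a
95% ± 3% band) and a scaled-down 100-replicate sweep across
(σ, n) ∈ {200, 400, 600} × {5, 25, 100} with a correspondingly wider MC
band; the simulator-vs-oracle grid uses 2000 reps per point; the
minimum-sample-size table is computed on the replication n-grid at 1000
reps. Exact checks (closed-form velocity, shortest-path oracle, noiseless
OLS) are asserted at 1e−9 or tighter.

## Known limitations

* Strandings confound distribution with abundance, mortality and reporting;
  the bias module checks only the census-population confound.
* The center statistic is domain-censored near the poleward boundary (see
  diagnostics above); trailing-edge quantiles are noisy at small n.
* The percentile bootstrap can slightly undercover for small numbers of
  years; B = 1000 quantile CIs carry their own simulation noise.
* Velocity is the scalar gradient ratio; it is undefined (masked) over flat
  temperature fields and unstable where gradients are weak.
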