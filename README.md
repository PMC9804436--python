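# strandshift

Detecting poleward range shifts of coastal odontocetes (toothed whales and
dolphins) from stranding records.

Strandings — animals found beached along the coast — are one of the few
multi-decade, large-spatial-scale observation records for cetaceans, whose
at-sea survey coverage is too sparse to resolve distributional trends. This
package turns a Level-A-style stranding database into range-shift inference
along a 1-D along-shelf axis, and asks the statistical question that has to
come first: *given how variable and how rare a species' strandings are, how
many events per year would it take to detect a shift at all?*

## What it computes

Every stranding event is assigned a **poleward distance** `d`: the
along-shelf shortest-path distance (km) from an origin at the equatorward
end of the shelf, computed over a raster with the coastline and the shelf
break as barriers (8-connected Dijkstra, √2-weighted diagonals,
cos-latitude cell scaling). Per species and year, the distribution of
strandings is summarized by its **center** (annual mean of `d`) and — for
species whose equatorward range limit falls inside the study region — the
**trailing edge** (annual 5th percentile of `d`, linear-interpolation order
statistic).

A shift is the OLS slope of the annual statistic on year,

    d̄_t = α + β t + ε_t ,

with a 95% CI from an event-level nonparametric bootstrap (B = 1000 resamples
of event rows, distance–year pairing conserved) and family-wise Type-I error
control via Dunn–Šidák, α′ = 1 − (1 − α)^(1/m).

**Power analysis.** Events are simulated as `d = a + b·t + ε`,
`ε ~ N(0, σ²)`, with n events per year over T = 25 years; a run *detects*
the shift when the slope of the annual statistic is significant two-sided at
p < .05 **and** has the sign of `b`. `power_sim.min_n` inverts the power
surface to the smallest n detecting a shift 95% of the time; for the mean
statistic a noncentral-t closed form (`analytic_power`, noncentrality
δ = b·√(n·Sxx)/σ, Sxx = (T³−T)/12) serves as an independent oracle for the
simulator.

**Climate velocity.** From annual-mean SST cubes: per-cell warming rate g_t
(OLS slope of SST on year) divided by the spatial gradient magnitude |∇T|
(3×3-neighborhood central differences), v = g_t/|∇T| in km/yr, with regional
median/quartile summaries and SST-anomaly trend series.

Also included: climatic-category (warm/cool/arctic/cosmopolitan) composition
trends vs year and vs SST anomaly, an observer-effort bias check regressing
county-level census population change on poleward distance, and a
synthetic-data module that generates stranding sets, SST cubes, shelf worlds
and census tables with known ground truth so the whole pipeline is testable
offline.

## Worked example

```python
import strandshift as ss

# synthetic shelf world: 300 x 24 cells at 10 km, straight coastline
world = ss.build_world(ss.WorldSpec(grid_shape=(300, 24), cell_km=10.0))

# a warm-water dolphin drifting poleward at 8.7 km/yr, sigma = 307 km, 66 events/yr
spec = ss.SpeciesSimSpec("common_dolphin", slope_b=8.7, intercept_a=900.0,
                         sd_sigma=307.0, annual_n=66)
events = ss.gen_strandings(spec, world, seed=42)
events = ss.poleward_distance(events, world.field())

from strandshift.shift_inference import shift_trend
fit = shift_trend(events, kind="mean", n_boot=1000, seed=42, m_comparisons=9)
print(f"center shift: {fit.slope:.1f} km/yr "
      f"(95% bootstrap CI {fit.boot_ci_low:.1f}-{fit.boot_ci_high:.1f})")

res = ss.min_n(8.7, 307.0, statistic="mean", reps=1000, seed=42)
print(f"minimum annual sample size: {res.min_n}")
```

prints

```
center shift: 8.3 km/yr (95% bootstrap CI 6.3-10.2)
minimum annual sample size: 13
```

The recovered slope of 8.3 km/yr brackets the generating 8.7 km/yr inside
its bootstrap CI; the power inversion says 13 strandings per year suffice to
detect a shift of that speed 95% of the time at this spatial variance, so
the simulated 66/yr record is comfortably adequate.

A `strandshift` console script exposes the stages (`simulate`, `clean`,
`distance`, `velocity`, `shifts`, `power`, `bias`, `run-all`, each driven by
the same YAML config); `run-all` writes the
cleaned records, trend table with bootstrap CIs, velocity summaries,
composition series, power table and bias regression as CSV/JSON with
config-hash + seed provenance.

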