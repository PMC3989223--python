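# isoassign

Dual-isotope (δ²H, δ³⁴S) feather isoscapes and likelihood-based geographic
assignment of bird natal origin.

## The problem

Natal dispersal — how far a songbird settles from where it hatched — drives
gene flow and sets the spatial scale of population dynamics, but first-year
breeders are almost never recaptured where they were ringed. Stable isotope
ratios in feathers offer a way around mark–recapture: a feather grown near
the natal site records the local isotopic signal, so an unmarked bird can be
assigned to a likely region of origin by comparing its feather values
against spatially continuous surfaces of expected values (*isoscapes*).
Hydrogen (δ²H) varies with growing-season precipitation along broad
continental gradients; sulfur (δ³⁴S) adds coastal–inland contrast from
marine sulfate deposition, which sharpens assignments in coastal regions.

`isoassign` implements the full analysis for a two-isotope design:

1. **Isoscapes** — per-location means of after-second-year (ASY) males are
   interpolated by ordinary kriging; the semivariogram family (spherical,
   circular, exponential, gaussian, or linear) is selected by leave-one-out
   cross-validated RMSE.
2. **Calibration** — δ²H is corrected for year effects using benchmark
   returning-ASY birds (offset = benchmark-year mean − year-*y* mean), and
   second-year (SY) birds are shifted by an age correction factor
   (±6, ±3, 0 ‰) because fledgling-grown feathers differ from adult ones.
   δ³⁴S is never calibrated; a pooled-variance *t*-test checks for a year
   effect.
3. **Assignment** — for each individual with feather values
   (*x*, *y*) = (δ²H, δ³⁴S), every 2×2 km raster cell *j* gets the
   bivariate normal likelihood

   f(x, y | μ_j, Σ) = (2π σ_H σ_S √(1−ω²))⁻¹ exp{ −[z_H² − 2ω z_H z_S + z_S²] / (2(1−ω²)) },
   z = (value − μ_j)/σ,

   where μ_j comes from the isoscapes and Σ (within-location SDs σ_H, σ_S
   and correlation ω) is estimated from pooled residuals of a validation
   cohort and assumed stationary. Normalized cell masses are cut into a
   binary likely/unlikely origin mask by an odds ratio: the highest-mass
   cells are included until their cumulative mass reaches odds/(odds+1)
   (2:1 → 67 %, 4:1 → 80 %).
4. **Dispersal** — a bird is a *resident* if its likely-origin mask overlaps
   the capture area, an *immigrant* otherwise (with a minimum dispersal
   distance to the nearest likely cell); fictional individuals carrying the
   local expected values give the *minimum detectable distance* — the
   method's short-range blind spot.

Because no individual-level field data are released with the study this
package models, a first-class synthetic generator reproduces the sampling
design (26 locations over ~340×530 km, 3–10 ASY per location, within-location
SDs 10.5 ‰ and 3.8 ‰ with correlation 0.29, year offsets of 10–20 ‰, an SY
age offset) so every stage is testable end to end.

## Worked example

```sh
isoassign simulate --seed 42 --out demo
isoassign assign --records demo/records.csv --out demo_out --cell 4 --no-individual-rasters
```

which prints (abridged):

```
Year offsets (d2H, vs 2010): {2010: 0.0, 2011: 23.0, 2012: 11.5}
d2H isoscape: linear variogram, nugget 11, sill 90.7, range 221.4 km, LOOCV RMSE 8
d34S isoscape: gaussian variogram, nugget 6.66, sill 22, range 199.2 km, LOOCV RMSE 3.5
Covariance structure: sigma_H 9.20, sigma_S 3.70, omega 0.367
Known-origin ASY classification accuracy (2:1): 87.0%
Minimum detectable distance at district locations: 42 +/- 5 km (n=5)

Residency by age correction factor and odds ratio:
  factor +6 permil, 2:1 -> 26/35 residents (74.3%), 35 edge contacts
  factor +0 permil, 2:1 -> 24/35 residents (68.6%), 35 edge contacts
  factor +0 permil, 4:1 -> 30/35 residents (85.7%), 35 edge contacts
  ...
```

Reading this: the simulated 2011/2012 samples were shifted onto the 2010
benchmark scale by +23.0 and +11.5 ‰ (the generator's true offsets are 21.1
and 11.9 ‰; the difference is sampling noise in the benchmark means). The
within-location dispersion estimated from 66 validation birds (9.2 ‰,
3.7 ‰, ω = 0.37) scatters around the generating values (10.5, 3.8, 0.29).
Of 35 simulated SY recruits, 24–30 are classified as residents depending on
the age correction and odds ratio — the 4:1 regions are supersets of the
2:1 regions, so residency can only rise with the odds ratio. Every
individual mask touches the grid edge, which is why the method bounds
minimum, not maximum, dispersal. The 42 km detectability floor means
dispersal shorter than ~40 km at the district cannot be distinguished from
residency at all.

Programmatic use mirrors the CLI:

```python
from isoassign import (SimConfig, generate_true_field, simulate_individuals,
                       PipelineConfig, run_pipeline)

cfg = SimConfig(seed=42)
fields = {iso: generate_true_field(cfg, iso) for iso in ("d2H", "d34S")}
records = simulate_individuals(cfg, fields)
result = run_pipeline(PipelineConfig(records=records, out_dir="demo_out",
                                     grid_cell=4.0))
print(result.summary)
```

## Layout

- `isoassign.simulate` — synthetic study designs (true isotope fields,
  sampling locations, capture tables)
- `isoassign.variogram` / `isoassign.isoscape` — semivariograms, WLS
  fitting, LOOCV model selection, ordinary kriging
- `isoassign.calibration` — year offsets, age correction, sulfur year test
- `isoassign.assignment` — bivariate likelihood surfaces, odds-ratio masks
- `isoassign.dispersal` — residency, dispersal distances, detectability
- `isoassign.pipeline` / `isoassign.cli` — end-to-end driver and the
  `isoassign` command

See `docs/methods.md` for the statistical details and design decisions.
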