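# Methods

This note documents the statistical model behind `isoassign`, the choices
made where the design was genuinely open, and what the synthetic fixtures
do and do not establish about real data.

## Coordinate frame and grids

All coordinates are planar kilometres in an arbitrary projected CRS; the
package performs no reprojection. Grids are cell-centre registered,
row-major from the lower-left (south-west) corner, with a 2 km default
cell. Rasters serialize as ESRI ASCII grids, a plain-text format readable
by any GIS; the kriging provenance (variogram family, parameters, LOOCV
RMSE) is written to a YAML sidecar next to each isoscape.

## Semivariograms and kriging

The empirical semivariogram is the classical Matheron estimator on
equal-width lag bins (default 12) up to half the maximum pairwise distance;
bins with fewer than 3 pairs are dropped, and each retained bin is plotted
at its empirical mean lag rather than the bin centre. Five parametric
families are supported — spherical, circular, exponential, gaussian
(bounded) and linear (unbounded) — in the standard closed forms, with two
conventions worth noting:

- For the exponential and gaussian families the stored `range_` is the
  *practical* range (lag at 95 % of the partial sill), matching what
  geostatistical GUIs report as the "major range".
- γ(0) is defined as the nugget, and every family is nondecreasing in lag.
  Inside the kriging system the diagonal (self-pair) entries are set to 0,
  the standard convention that keeps ordinary kriging an exact interpolator
  when the nugget is zero.

Fitting is weighted least squares with weights `pair_count / lag²`, which
privileges short lags where kriging weights are decided. The optimizer is
bounded Levenberg–Marquardt (`scipy.optimize.least_squares`) with
multi-start over the range parameter, because the bounded families have
non-convex objective surfaces; the linear family reduces to a
non-negative linear least-squares problem. On noiseless model-generated
curves the generating parameters are recovered to 1e-6, which the test
suite asserts for every bounded family.

Model selection minimizes leave-one-out cross-validated RMSE of the
per-location means: each location is predicted by ordinary kriging from all
others under the fitted model. LOOCV was chosen because the selection
criterion in the comparable GUI workflows is a cross-validated RMSE of
exactly this form; ties between families are broken by the canonical family
order (spherical, circular, exponential, gaussian, linear). The reported
"sill" is always nugget + partial sill.

Ordinary kriging solves the bordered Gamma system once per set of
observations (LU factorization) and back-substitutes all grid cells at
once; weights sum to 1 at every cell by construction and the test suite
spot-checks this on random cells. Duplicate observation coordinates make
the system singular and raise an error naming the offending pair.

## Calibration

Year offsets for δ²H are computed from returning-ASY birds at the
benchmark district only: offset(y) = mean(benchmark year) − mean(year y),
added to every year-y value. A single spatially constant offset is used —
the working assumption is that inter-annual variation in growing-season
precipitation δ²H is uniform across the ~180 000 km² sampling area; no
spatially varying correction is attempted. Offsets are reported at 0.1 ‰
precision but carried at full precision into assignment.

The SY age correction is a pure translation of δ²H, run as a sensitivity
design over {+6, +3, 0, −3, −6} ‰ because the true fledgling–adult
discrimination is uncertain (literature values span roughly 0–6 ‰, with
the sign itself debated). δ³⁴S receives no year or age correction — sulfur
shows little diet–tissue discrimination — but a year effect is tested with
a pooled-variance two-sample *t*-test (pooled, not Welch, to match the
degrees of freedom convention of the original analysis; df = n₁ + n₂ − 2).
Group differences smaller than the ±2 ‰ analytical measurement error are
reported as statistically detectable but practically negligible.

## Covariance structure and assignment

The within-location dispersion Σ is estimated from a validation cohort:
residuals (individual − location mean) are pooled across locations, with
N − L degrees of freedom (each of the L locations absorbs one mean), giving
σ_H, σ_S and the residual correlation ω. Locations contributing a single
bird carry no residual information and are dropped. Σ is assumed
stationary over the study area; at the emulated validation size (66 birds
over 22 locations) the sampling SE of ω is ≈ 0.15, so single-cohort
estimates scatter widely — the tests therefore check the estimator on
averages over cohorts, and the acceptance script uses a 22 × 500 cohort
where the SE is below 0.01.

Each individual's origin likelihood is the bivariate normal density
evaluated per cell at the isoscape means, normalized to a discrete
probability mass summing to 1 over cells (no continuous integration — the
analysis lives on raster cells). Normalization happens in log space so
individuals far off the isoscape scale do not underflow to an all-zero
surface.

The odds-ratio mask is a highest-density region over cell masses: cells
sorted by mass descending (stable in cell index for determinism) are
included until the cumulative mass reaches odds/(odds+1), boundary
inclusive. The region is minimal — dropping its lowest-mass cell falls
below the threshold — which makes the 2:1 region a subset of the 4:1
region on every surface. Individuals missing one isotope are excluded
from assignment rather than falling back to a univariate rule.

## Residency, distances, detectability

A bird is resident when at least one included cell centre lies inside the
capture area (a configurable polygon; a point capture site becomes a disc
of default radius 5 km). Immigrants get the minimum Euclidean distance
from the breeding point to the nearest included cell centre; at the 2 km
cell size, centre-to-centre distances dominate any sub-cell refinement, so
no polygon-boundary distance is computed. "Perpendicular distance" to the
unlikely region is implemented as nearest-neighbour Euclidean distance,
the only well-defined reading on a raster.

The minimum detectable distance assigns a fictional individual carrying
exactly the local predicted values and measures the distance to the
nearest cell classified as unlikely. One subtlety: cells whose mass ties
the lowest included mass (as on a perfectly flat surface) are excluded by
arbitrary ordering, not by evidence, so they are not counted as "unlikely";
a surface with no genuinely unlikely cells raises a "not detectable within
extent" signal instead of returning a meaningless distance.

Maximum dispersal distances are deliberately not estimated — on smooth
isoscapes every origin mask reaches the grid edge — and only an
edge-contact flag is reported.

## The synthetic generator

The generator emulates the study conditions rather than any particular
dataset: a 340 × 530 km extent; 26 sampling locations (a 4-location
benchmark district plus 22 outside locations placed uniformly under a
25 km minimum-separation constraint, mimicking the ~65 km mean
nearest-neighbour spacing of the real design); 3–10 ASY males per outside
location with δ³⁴S measured for 3 per location; returning ASY of 23/14/11
across three years at the district; and 35 SY recruits whose true natal
origin is drawn from an isotropic Gaussian (SD 40 km) around the capture
point and carried in the output for scoring, invisible to assignment.

True isotope landscapes are a linear gradient — δ²H enriched to the
southeast (gradient (0.06, −0.057) ‰/km about a −75 ‰ intercept), δ³⁴S
enriched toward the eastern coast (0.02 ‰/km about 5 ‰) — plus a frozen
Gaussian random field with a gaussian covariance (range 120.7 km; sills
31.8 and 11.8 ‰², nuggets 0.81 and 0 ‰², per isotope). The smooth
component is realized once per seed on a coarse lattice (~range/8) and
interpolated bilinearly; a full-grid realization would be numerically
pointless for a field this smooth. The per-isotope sills follow the
two isotopes' different variability; the config accepts a scalar and
broadcasts it when a common value is wanted.

Individual values are bivariate normal draws around the field value at the
bird's *origin* with SDs (10.5, 3.8) ‰ and correlation 0.29; year offsets
(0, −21.1, −11.9 ‰ for the three years) and the SY age offset (−6 ‰
default) are pure translations of δ²H, so calibration can restore them
exactly. Everything is reproducible byte-for-byte from the config seed.

What the generator does *not* model: elevation and coastline effects
beyond the linear gradients, habitat-age structure within locations,
spatially varying year effects, and measurement error as a separate term
(it is absorbed into the within-location SDs). Passing tests therefore
demonstrate internal consistency of the method under its own assumptions —
correct coverage of highest-density regions, unbiased covariance recovery,
kriging exactness — not that real feather data satisfy those assumptions.

## Numerical choices and scale

- Assignment normalization is checked to 1e-9; density oracles to 1e-12.
- The odds threshold comparison uses a 1e-12 slack so exact-boundary cases
  (e.g. a uniform 3-cell surface at 2:1) are included, not dropped to
  floating-point noise.
- Residual correlations within 1e-9 of ±1 are rejected as degenerate.
- Test problems run on 10–20 km grids and down-scaled extents (e.g.
  220 × 260 km, 12 locations); Monte-Carlo checks use 10⁴ draws for
  moment recovery, 200 birds for coverage, and 10 replicates for model
  comparison — sizes at which the asserted tolerances are several
  standard errors wide.
- Known limitation: with only ~26 location means, LOOCV RMSE differences
  between variogram families are often within sampling noise, so the
  *selected* family is not stable across seeds (the paper-scale analogue:
  both of its isoscapes reported the same fitted range, hinting at weak
  identifiability). The pipeline reports the per-family RMSEs in its log
  so users can judge how decisive the selection was.
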