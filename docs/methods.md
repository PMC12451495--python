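# Methods

## Event definitions and counting

Heat waves and cold spells are percentile-based run events. Per grid cell,
the climatological threshold is the q-th percentile (heat q = 90, cold
q = 10) of **all** unmasked daily temperatures in the baseline decade pooled
together; no calendar-day windowing is applied, since the event definition
references only "the percentile for that grid cell". A 5-day calendar-window
climatology is the obvious alternative and would sharpen seasonal contrast,
but it changes thresholds by fractions of a degree at desk scale and is left
as future work. The percentile estimator is linear interpolation between
order statistics (`numpy` default), recorded in the threshold metadata.

An event is a **maximal** run of at least `run_length_days` (default 6)
consecutive days strictly beyond the threshold; one maximal run is one
event regardless of length, assigned to the calendar month containing its
first day (and hence to the decade containing that month). Missing days
never exceed the threshold, so they terminate runs. The source gridded
extreme-indices product does not document its internal counting convention;
ours is the simplest deterministic reading, and a non-overlapping-windows
variant (⌊run length / 6⌋ events per run) is available via
`AnalysisConfig(event_counting="nonoverlapping_windows")` for sensitivity
checks. Cells with fewer than 30 unmasked baseline days are masked with a
warning: below that, a 90th/10th percentile is dominated by sampling noise.

Droughts are months with SPEI-3 strictly below −1.5 (severe drought). All
exceedance comparisons are strict; for layer thresholds the comparison is
inclusive (Δ ≥ t), matching how the published threshold ("≥ 32 events") is
stated.

## Hazard layers

Decadal sums cover exactly 120 months; partial coverage raises instead of
silently truncating. The difference field Δ = recent − baseline is exact
integer arithmetic. Heat and drought layers keep in-region cells with
Δ ≥ t where t is the `layer_percentile` (default 80) linear-interpolation
percentile of Δ **over in-region cells after clipping**: the percentile
could equally be taken before clipping, but clipping first is the
self-consistent choice, since the aim is the upper tail of the distribution
of changes across the cells the species actually occupy. The cold layer
keeps cells with Δ > 0 (strict — "an increase in cold spells"); a
`cold_include_zero` flag provides the inclusive variant. The region mask is
the union footprint of all species ranges on the event grid (any
positive-area overlap ⇒ inside).

## Overlap geometry

The overlap proportion is a ratio of spherical-Earth areas. Hazard cells are
polygonized into lon/lat rectangles and intersected **exactly** with the
(unioned, validity-repaired) range geometry using Shapely; each intersection
piece's area is evaluated by densifying its edges to ≤ 0.01° segments,
mapping through the cylindrical equal-area projection (x = λ rad,
y = sin φ), and scaling the planar area by R² (R = 6371 km). The chord error
of densification is O(Δφ²) ≈ 10⁻⁹ relative, far below the 10⁻³ oracle
tolerance used in tests. The total area is computed the same cell-by-cell
way against the full grid footprint, so numerator and denominator share
every discretization choice and the proportion is internally consistent.
Overlapping parts of multipart ranges are unioned before any area is taken,
so areas are never double counted (for truly disjunct parts the union is a
no-op and the proportion is unaffected). Absolute km² values use the
sphere, not the planar-degree areas of a desktop GIS; the two differ by a
latitude-dependent factor that largely cancels in the ratio.

Exposure is strict: proportion > cutoff (default 0.5); a species sitting
exactly at 50% overlap is not exposed. The inclusive variant is one
configuration change away for anyone who prefers it. Excess-event zonal statistics include every
cell with positive-area overlap (configurable to center-in-cell), reporting
the plain mean, the sum, and an overlap-area-weighted mean of Δ.

Aggregation uses the same positive-area membership rule on a 2° grid
(anchored at the extent's SW corner), so small-ranged species are never
dropped; percentages are stored at full precision and rounded only for
display.

## Status-change model

The multinomial logit (reference outcome: no change) is fitted by
Newton–Raphson on the analytic gradient and Hessian, with step-halving to
keep the log-likelihood non-decreasing; convergence requires gradient
max-norm < 10⁻⁸ within 200 iterations, otherwise an error is raised. Wald
standard errors come from the inverse observed information at the optimum;
confidence intervals and p-values are Wald on the log-odds scale,
exponentiated for presentation as odds ratios with 95% CIs.
Profile-likelihood intervals would be more accurate
for the rare downlisted outcome but are not what the presentation mirrors.
Coefficients beyond |β| > 15 trigger a separation warning (Wald intervals
are then unreliable); at the default desk scale of 300 species this happens
routinely for the nearly-constant cold-exposure predictor and is flagged,
not hidden. The two reassessment periods are fitted as separate models with
identical specification; all three exposure classes enter jointly. A period
whose records contain a single outcome level is skipped with a warning
rather than fitted (the model is not identifiable there).

## Synthetic data

The generator defines the desk-scale study conditions: a 20 × 20 grid of
0.5° cells over a tropical window (10° × 10°), the two analysis decades, and
300 species. Daily temperature is per-cell climatology (N(24, 1.5²) °C
across cells) + a 4 °C seasonal sinusoid + a linear warming trend
(0.5 °C/decade referenced to the baseline midpoint) + AR(1) noise (φ = 0.7,
σ = 2 °C). The trend magnitude is at the high end of observed land warming
so that the recent decade shows a clear, testable excess of heat events over
a 10-year window; the AR(1) persistence makes multi-day runs realistically
common. SPEI is emulated directly as standardized values — N(0, 1) in the
baseline decade, mean-shifted by −0.5 in the recent decade (the drying trend
accumulated over the 30-year gap) — because the index is consumed, not
computed, by the pipeline; the closed forms Φ(−1.5) ≈ 0.067 and
Φ(−1.0) ≈ 0.159 for monthly drought frequency anchor the tests. Ranges are
axis-aligned rectangles with log-uniform areas between 0.25 and 25 deg²,
random aspect ratio in [0.5, 2]; 25% of species get 2–3 mutually disjoint
parts. Status outcomes are drawn from the multinomial logit with the
2004–2022 fitted values as default truth (uplisted intercept odds 0.03, ORs
1.84/1.66/1.24; downlisted 0.02, ORs 0.67/0.18/0.77).

What the generator does **not** emulate: spatial autocorrelation beyond
per-cell AR(1) (no teleconnections, no shared weather across cells),
temperature–SPEI coupling (real heat and drought co-occur, which is why the
published heat and drought layers overlap strongly), realistic range shapes
and range–climate covariance, and observation error in Red List categories.
Passing tests therefore demonstrate correctness of the algorithms under
known ground truth, not climatological realism of any particular map.

All generator streams derive from a single scenario seed via CRC32-hashed
stream labels, so identical seeds give byte-identical outputs across
processes.

## Problem sizes and null conditions

The odds-ratio recovery experiment uses the real species count (n = 7202)
with independent Uniform(0, 1) exposures, 50 replicates; reported values are
means of exponentiated refitted coefficients (slightly above the generating
values by the Jensen gap exp(SE²/2), well inside the recovery bands). The
null-model sanity check uses intercept odds of 0.25 for both non-reference
outcomes at n = 5000 over 20 seeds, so each outcome has ≈ 800 events and the
per-replicate odds-ratio noise is small enough for the mean to sit near 1;
the empirical outcome mix of the real reassessment data would leave the
downlisted class too rare for a meaningful null band at this n. The overlap
oracle comparison uses 100 generated ranges against 0.02° subcell
quadrature; run detection is checked against an exhaustive scan on 1000
random Bernoulli exceedance series.

## Known limitations

- Longitude wrap-around at the antimeridian is not handled; grids must live
  in [−180, 180) without crossing it.
- GeoJSON is the only vector format (no shapefile driver); NetCDF (classic
  format) the only grid format.
- The event-counting convention of the upstream extremes product is not
  publicly specified; ours is documented above, not asserted identical.
- Country tallies use exact polygon intersection and scale as
  O(species × countries); adequate at desk scale, not optimized for
  hundreds of countries with complex coastlines.
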