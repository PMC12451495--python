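# amphex

Species-level exposure to climate extremes — heat waves, cold spells, and
droughts — and its association with Red List status change.

## The problem

Extreme climate events are implicated in global amphibian declines, but
species-level exposure is rarely quantified. `amphex` implements a complete,
testable pipeline for doing so:

1. **Event detection.** A heat wave (cold spell) is a run of ≥ 6 consecutive
   days with daily temperature strictly above (below) the cell's 90th (10th)
   climatological percentile, computed from a baseline decade; one maximal
   run is one event, assigned to its start month. A drought event is a month
   with SPEI-3 (3-month standardized precipitation–evapotranspiration index)
   strictly below −1.5 (severe drought).
2. **Hazard layers.** Monthly counts are summed over a recent decade
   (2010–2019) and a baseline decade (1980–1989); the cell-wise difference
   Δ = recent − baseline is binarized: heat and drought layers keep in-region
   cells with Δ ≥ the 80th percentile of Δ, the cold layer keeps cells with
   Δ > 0. The region is the union footprint of all species ranges.
3. **Exposure.** For each species with range polygon *S* (WGS84, possibly
   disjunct), the exposure proportion is

   p = A(S ∩ hazard cells) / A(S ∩ grid),

   with spherical-Earth areas (R = 6371 km). A species is *exposed* when
   p > 0.5. Excess-event zonal statistics (mean, sum, area-weighted mean of
   Δ over intersected cells) quantify magnitude.
4. **Aggregation.** Exposed species are tallied per 2° grid cell (counts and
   proportion of richness), per taxon (order/family/genus), per country, and
   by multi-hazard combination.
5. **Status model.** A multinomial logistic regression links status-change
   outcome y ∈ {no_change (reference), uplisted, downlisted} to the three
   exposure proportions x:

   P(y = k | x) = exp(xᵀβₖ) / (1 + Σⱼ exp(xᵀβⱼ)),

   fitted by Newton–Raphson with step-halving; exp(βₖ) are odds ratios with
   Wald 95% CIs.

A synthetic-data module generates all inputs (daily temperature cubes with a
warming trend, standardized SPEI cubes with drying, multipolygon ranges with
taxonomy, status outcomes from known odds ratios) so the whole pipeline runs
and is validated without any external downloads.

## Worked example

Run the full synthetic pipeline (20 × 20 grid of 0.5° cells, two decades,
300 species; ~5 s):

```sh
amphex run-all --seed 1 --out-dir demo
```

`demo/exposure/exposure.csv` holds one record per species × event class:

```
species_id event_class  overlap_km2  total_km2  proportion  exposed  excess_mean
    sp0001   heat_wave    24470.454  168823.14       0.145    False       20.264
    sp0001  cold_spell     3069.642  168823.14       0.018    False       -9.444
    sp0001     drought    53332.890  168823.14       0.316    False       11.208
```

sp0001's range overlaps the heat-wave layer over 14.5% of its area (below
the 50% cutoff, so not exposed), and saw on average ≈ 20 more heat-wave
events per decade within its range than in the 1980s. At this seed 5.0% of
species end up heat-wave exposed, 4.7% drought exposed, and none cold-spell
exposed (cold spells decline under the warming trend);
`demo/aggregate/multi_exposure.csv` shows 1 of 300 species exposed to two or
more classes.

Fitting the status model on simulated outcomes for 7202 species with the
known generating parameters:

```python
import numpy as np
from amphex.synthetic import gen_uniform_exposures, gen_status_changes
from amphex.status import fit_multinomial

rng = np.random.default_rng([1, 1])
exposures = gen_uniform_exposures(7202, rng)
records = gen_status_changes(exposures, rng=rng)
print(fit_multinomial(records).summary())
```

```
Multinomial logit of status change (reference: no_change, n = 7202)
log-likelihood = -1702.237; converged = True
   outcome        predictor  odds_ratio  ci_low  ci_high        p
  uplisted      (Intercept)      0.0273  0.0192   0.0389 4.72e-89
  uplisted    heat_exposure        1.53    1.07     2.21   0.0212
  uplisted drought_exposure        1.74    1.21      2.5   0.0029
  ...
```

An odds ratio of 1.74 means that moving a species' drought-exposure
proportion from 0 to 1 multiplies its odds of being uplisted (vs. no status
change) by 1.74.

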