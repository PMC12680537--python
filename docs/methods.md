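# Methods

## The accounting model

Biomass movement of a species or subgroup is the product of its global
biomass (tonnes) and the mean distance its individuals actively travel
per year (km). Group estimates are sums over children, so aggregation is
exactly additive and permutation-invariant; everything is kept in
canonical units of tonnes, km and years and displayed in Gt km yr^-1
(1 Gt = 1e9 t). A year is 365 days for daily-to-annual conversion and
3.1536e7 s for power; these constants live in one shared
`UnitConventions` instance so no module can disagree about them.

Three kinds of distance information are accepted per record, in priority
order: an annual distance, a daily distance (scaled by 365), or an
activity-time x characteristic-speed pair. The last yields only an
*upper bound* `B x h x v x 365`, which is robust to under-sampled
movement data; such records contribute to group bounds but never to
central estimates. Records with no usable information are skipped with a
warning and surface in a coverage report — aggregation never aborts and
never silently drops a leaf.

### Uncertainty

Estimates carry a low/mean/high interval tagged by its basis (95% CI or
extrema) and optionally a hard upper bound. Sums combine intervals by the
arithmetic sum of the children's lower and upper offsets; this dominates
the quadrature (root-sum-square) alternative whenever more than one child
has width, which is the point — systematic biases across groups need not
cancel. Quadrature is available but off by default. Products
(biomass x distance) use endpoint intervals (`low*low`, `high*high`),
again conservative for nonnegative quantities. Headline values display at
one significant figure, rounded half-away-from-zero, with raw values
always retained.

Known display quirk: the wild-land-mammal energy row computes to
30 x 3 / 3.6 = 25 TWh/yr (2.85 GW), which displays as 30 TWh/yr and 3 GW
under this package's rounding; published compilations of the same inputs
sometimes show 20 TWh/yr and 2 GW, which no nearest-digit rounding of 25
reproduces. Similarly 57 GW (from 500 TWh/yr) displays as 60 GW here. The
`round_then_derive` power mode (power from the already-rounded energy) is
provided for compatibility with tables built that way. All such cells
agree within the roughly threefold uncertainty attached to these
estimates.

## Trajectories

Path length is the sum of great-circle hops between consecutive fixes on
a sphere of radius 6371 km (the ellipsoidal correction is far below every
other error source). Inter-fix gaps longer than `max_gap` (default 7 d,
a typical avian GPS duty-cycle scale) are excluded from both path and
covered time rather than bridged — gaps reduce coverage, they never
fabricate movement. Annual distance scales the path linearly from covered
days to 365; there is no seasonal re-weighting. Tracks with coverage
below 0.5 of their span are flagged unusable. Resampling
(`regularize`, default 1 h) interpolates lat/lon linearly per segment
with longitudes unwrapped across the antimeridian; altitudinal movement
is ignored throughout.

The sampling-bias direction is one-sided: chords cut corners, so
subsampling can only shorten a measured path. On generator tracks the
hourly-sampled path is within ~0.3% of the exact integrated length, while
daily sampling loses the foraging tortuosity and underestimates.
Species-level distances are means over individuals with a nonparametric
bootstrap 95% CI (1,000 replicates, seeded, resampling individuals as the
unit of independence).

## Energetics

COT follows `a m^b` per locomotion mode with `b <= 0`. The shipped
constants are generic literature-style defaults — walking/running
`a = 11.5, b = -0.316` is calibrated so a 70-kg adult costs ~3 J kg^-1
m^-1 (0.72 kcal kg^-1 km^-1 at 4184 J per dietary kcal) — but group
averages used in headline tables are configuration inputs, because a
group's effective COT is a movement-weighted mean that the biomass
composition, not the allometry alone, determines. Energy is
movement x COT / 3.6 (1 Gt km = 1e15 kg m, 1 TWh = 3.6e15 J); power
spreads the annual energy over 3.1536e7 s.

## Human mobility

The two-step estimate: (1) harmonize heterogeneous reported data
(per-capita km/yr, total pkm/yr, km per day) to per-capita km/yr per
country and mode, averaging duplicates and rejecting unknown units with a
logged reason; (2) fill missing country-mode pairs with the average of
two models — the population-weighted per-capita mean of the country's
World Bank income group, and a per-mode OLS regression of log per-capita
demand on log GDP per capita fitted to reported countries. Reported
values pass through bit-identical. The log-log form was chosen for
positivity and elasticity interpretability; it is pluggable. Gap-filled
walking/cycling values are floored at 1 km/d per capita (walking data are
globally scarce; the floor is an explicit, configurable assumption).
Person-km convert to biomass movement at 54 kg average body mass
(per-country override supported). Upper/mean/lower variants apply
per-status multipliers (reported 0.9-1.15, gap-filled 0.5-1.6) standing
in for scenario rules that depend on source-level data quality.

## Synthetic data

Generators emulate the study conditions, not real geography:

- **Species tables** — groups sized like the terrestrial synthesis (wild
  mammals ~20 Mt with heavy-tailed log-normal masses, birds ~3 Mt,
  arthropods ~1 Gt of tiny movers), day range `d = c m^0.25` with
  log-normal noise (sigma 0.4). The 0.25 exponent is a literature-style
  convention, configurable. Because distance rises with mass, species
  over 50 kg hold a larger share of movement than of biomass, matching
  the large-animal dominance pattern qualitatively.
- **Tracks** — great-circle migration legs (with per-individual waypoint
  jitter) at 45 km/h cruise plus a 60-day correlated-random-walk foraging
  period; hourly fixes with 5% dropout. The exact integrated length is
  recorded as truth.
- **Country tables** — per-mode demand `alpha gdp^beta` with log-normal
  noise, calibrated to a plausible present-day profile (high-income road
  ~10,000 km/yr, air elasticity > 1, walking nearly flat in GDP); 30% of
  entries masked with odds proportional to 1/GDP, emulating the decline
  of data availability toward low-income countries.
- **Historical series** — marine components decaying exponentially from
  80,000 to 30,000 Gt km/yr over 1850-2020 with end-state shares
  70/15/10/5, and human modes growing logistically 40-fold from a
  walking-dominated start; endpoint truths are exact by construction.

Each bundle draws from substreams spawned off one `SeedSequence`, so
identical (seed, config) reproduces bit-identical data and adding a
generator never perturbs another. Truth is always recomputable from the
emitted data by brute force: noise is part of the data, not an error term
around the truth.

What passing these tests shows — and does not. The generators share the
pipeline's structural assumptions (log-linear demand, segment-wise
movement, additive groups); recovery on them validates the bookkeeping,
the estimators and the bias directions, not the realism of any particular
published biomass or distance, which enter only as fixture inputs.

## Fixtures and the report

`biomove/data/headline_values.yaml` stores the reported headline inputs
(group movements with ranges and bounds, biomasses, populations,
per-mode components, COT averages, case-study parameters), each with
units and a provenance string; the few back-solved entries (e.g. the tern
annual distance, the 1850 human movement level implied by the 40-fold
growth) say so in their provenance. The report builder recomputes every
derived number through the library operations and tracks exactly which
outputs each missing input would disable, so deleting a fixture breaks
precisely its dependents.

Numerical conventions: ties round away from zero; composition shares sum
to exactly 100% before display rounding; zero denominators raise
`UndefinedValueError` rather than returning sentinels; all validation
errors name the offending record or field.

## Problem sizes

Defaults are desk-scale: tens to hundreds of species per synthetic
table, 8-25 tracked individuals at hourly fixes, 115 countries x 4
modes, 200 regression replicates for coverage experiments. Everything in
the test suite and acceptance script completes in well under a minute on
one CPU.

## Limitations

Fine-scale foraging tortuosity below the fix interval is invisible to
any trajectory method used here, so distances are systematically
under- rather than over-estimated. The diel-vertical-migration and
several case-study totals cannot be decomposed from their published
factors and are carried as fixture values only. The mobility module
reproduces the two-step architecture, not any specific national
statistics; its scenario multipliers are stand-ins for source-level
quality tiers. Vertical movement, behavioural segmentation and
utilization distributions are out of scope.
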