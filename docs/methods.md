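# Methods

This note documents the models implemented in `esvopt`, the choices
made where the method family leaves the design open, and what the
synthetic test data do and do not demonstrate.

## Land-use accounting

Class areas are cell counts × cell area with nodata cells excluded
from every denominator. Composition shares are taken over the table's
own total by default; an explicit basin total can be supplied, since
published per-class tables do not always sum exactly to the stated
basin area (the bundled 1990 column is 2,333 hm² short of the 2020
total — shares at two decimals are insensitive to the choice for all
but one class).

The single land-use dynamic degree is the standard annualized relative
change `K = ((U_b − U_a)/U_a)·(1/T)·100`, undefined for a zero start
area, rounded to two decimals only at the reporting layer. All six
published 1990–2020 values are reproduced by this formula.

Markov projection uses the row-stochastic form of the inter-epoch
cross-tabulation; rows with zero area become identity rows so the
matrix stays stochastic. The calibration interval is the most recent
epoch pair by default and is configurable — nothing in the method pins
it, so it is a modelling choice, not an estimate.

## Equivalent-factor valuation

`VC_i = Q · PI · Σ_f Ea · EC_f(i)` with all internal values in yuan
and reports in 10⁹ yuan. Decisions worth recording:

* **Ea.** The four published standard equivalents
  (2006/2043/2107/2181 yuan/hm² for 1990/2000/2010/2020) are bundled
  as authoritative constants; for any other year Ea is computed as 1/7
  of mean per-hectare grain output value (yield × price), the
  conventional anchoring of one equivalent. The constant path wins
  when both are available.
* **Composition point of Q and PI.** The corrections are applied
  multiplicatively to Ea. The method literature shows the corrections
  but not where they compose; the choice is isolated in
  `corrected_coefficients` so an alternative (e.g. per-function
  corrections) is a one-line swap.
* **Table versions.** The 9-function "2003" table is used for
  1990/2000/2010, the 11-function "2015-improved" table (adds water
  supply and nutrient-cycle maintenance) for 2020 and all forward
  scenarios. The bundled numeric tables are *representative* of the
  published convention, reconstructed rather than transcribed from the
  originals — so absolute ESV totals computed with them are
  illustrative, while every identity, linearity and margin property is
  exact. Construction land is zero in both versions by convention.
* **Engel logistic.** `L = 1/(1+e^{−(1/En−3)})` saturates to 1 in
  double precision for En ≲ 0.03; monotonicity is strict away from
  saturation and non-strict inside it.
* **FVC fallback.** If fractional vegetation cover is not supplied it
  can be derived from NDVI by the dimidiate pixel model with 5th/95th
  percentile endpoints.
* **Natural breaks.** Five display levels come from an exact
  Fisher-style dynamic program minimizing within-class SSE. Because
  breaks are upper-inclusive, equal values can never straddle a break,
  so the DP runs on unique values with multiplicities — O(u²k) in the
  number of distinct values, which keeps class-valued rasters (≤ 6
  distinct coefficients) instant. Ties break toward the lower class.

## Grey forecasting — GM(1,1)

Fitting follows the standard construction: 1-AGO accumulation,
least squares on the whitened equation `x⁰(k) = −a·z¹(k) + b` with the
midpoint background value. Prediction, however, uses the
bias-corrected discretization: growth ratio `q = (2−a)/(2+a)` and
level `c = 2b/(2+a)`, so `x̂⁰(k) = c·q^{k−1}`. The conventional
`e^{−a}` response carries a systematic discretization bias of order
`a³` that is visible (≈10⁻³ relative) even on noiseless exponential
input; the corrected form continues any geometric series exactly and
reduces to a constant as `a → 0`, which is the behaviour the model
class assumes. The model requires ≥ 4 strictly positive observations.

## Grey multi-objective program

Six continuous variables (areas in hm² at basin scale justify an LP
rather than an integer program). Objective coefficient vectors
(economic benefit, ESV, ecological capacity with the 12 % biodiversity
deduction already folded in) are printed model inputs, not estimates.
Constraint families: fixed total area; a population capacity row
`a21·(x1+x2+x3) + a22·x5 ≤ P` whose coefficients are grey intervals
[0.05, 0.07] and [4.31, 6.73]; a cropland floor from food demand
`P·S·f0/(f1·f2·f3)` (≈ 81,233 hm² at the study constants, entering as
a box bound); a green-equivalent cover floor `0.46x1 + x2 + 0.49x3 ≥
20 %` of the basin; and per-class box bounds including the cropland
cap of 957,862 hm², which is carried as a fixed constant because its
provenance (a discounted Markov projection) is not reproducible.

Open design points and how they were resolved:

* **Grey whitening.** Each interval resolves to `lo + λ(hi−lo)`,
  default λ = 0.5, with a mandatory sensitivity sweep over
  λ ∈ {0, 0.5, 1}² . At the upper corner the population row is
  unsatisfiable even at the box minimum once the total-area equality
  forces area out of capped unused land — such corners are reported
  with diagnostics, never dropped.
* **Scalarization.** Multi-objective modes maximize a weighted sum of
  min–max normalized objectives (each normalized by its own optimum
  and minimum over the same feasible region), equal weights by
  default; normalization constants drop from the argmax so the
  composed objective stays linear. A lexicographic mode (optimize in
  priority order, pinning each achieved level) is available behind a
  switch. Scaling all weights by a constant provably leaves the argmax
  unchanged, and the suite tests this.
* **Population row membership.** The row applies to x1+x2+x3 exactly
  as the constraint is printed, although its prose description
  ("agricultural and urban land") suggests a different set.

The observed 2020 structure violates the 2035 box (construction below
its floor, unused above its cap): the planning region deliberately
excludes the current state, and `feasibility_check` documents this
rather than hiding it.

Because the whitening rule and the scalarization of the original study
are unstated, its reported scenario area shifts are not reproduction
targets; the grey sensitivity table is the deliverable instead.

## Patch-based allocation

A behavioural re-implementation of the expansion-learning + patch CA
family, desk-scale:

* **Suitability.** Positives are cells newly of the target class
  between two epochs; negatives are unchanged cells sampled at a
  configurable rate; a random forest (60 trees, leaf ≥ 5) scores the
  whole grid. Classes with < 30 observed expansions fall back to a
  flat 0.5 surface. Factor rasters are min–max normalized with the
  constants retained for scoring other epochs.
* **Demand execution.** Demands (hm²) are rounded to whole cells by
  largest remainder. Net class deficits are first converted into gross
  per-pair conversion quotas by a minimum-churn transshipment LP on
  the permitted-transition digraph — net demand can legitimately flow
  through chains (water → unused → cultivated), exactly as observed
  gross transitions do, and a direct donor→recipient assignment can
  starve a narrowly-permitted class. The CA then fills each quota by
  converting the highest-scoring eligible cells (score = suitability ×
  neighbourhood share of the target class in a truncated 3×3
  neighbourhood), admitting isolated patch seeds with probability
  0.02 once the per-class suitability threshold (start 0.9, decay
  δ = 0.9 per round) allows. Default tolerance is 0.1 % of total area;
  a run that cannot meet demand raises, naming the unmet classes.
* **Determinism.** One integer seed drives sampling, seeding and tie
  jitter; identical seeds give bit-identical maps, different seeds the
  same class areas with different cell patterns.
* **Validation.** Overall accuracy, Cohen's kappa (cross-checked
  against scikit-learn) and the figure of merit
  `FOM = B/(A+B+C+D)` over cells where change was observed or
  simulated (misses, hits, wrong-class, false alarms). When neither
  map changes anything the FOM denominator is empty and the score is
  defined as 1 (vacuous agreement on change).

## Synthetic generator

The generator emulates what the real study takes from remote sensing
and yearbooks: a patchy base map (class-labelled Voronoi seeds,
default composition ≈ the arid-basin mix: half grassland, a third
unused), a second epoch realizing a row-stochastic transition kernel
with conversions grown as contiguous patches (geometric patch sizes,
mean 25 cells) so the allocator faces spatially structured change; 18
driving factors of which one per modelled transition carries a
logistic link (a mean shift equal to the stated slope on a
unit-variance field, so conversion log-odds are linear in the factor
with that slope; default slope 3 ⇒ theoretical AUC ≈ 0.98) and the
rest are noise; and exponential-trend socioeconomic series with
multiplicative log-normal noise — the structure grey forecasting
assumes.

What passing tests on this data do **not** show: realism of any
particular basin's geography or climate, classification error in the
source maps, non-exponential socioeconomic dynamics, or correlated
driving factors. One deliberate subtlety: *smoothed* pure-noise
factors act as location proxies for clustered change under a random
train/test split (spatial leakage), so the chance-level AUC property
is stated for unsmoothed noise.

## Problem sizes and numerical conventions

Analysis drivers use a 200×200 region (40,000 cells); the test suite
uses 80×80–200×200. The transshipment and scenario LPs solve through
HiGHS; LP optima are verified against brute-force vertex enumeration
on random instances with the study's constraint shapes to 10⁻⁸
relative. Areas are conserved exactly by construction in transition
matrices and to 10⁻⁶ relative in projections; report rounding (two
decimals) happens only at the presentation layer. All randomness flows
from one integer seed per run; configuration hashes are recorded in
every pipeline bundle.

## Known limitations

* The bundled equivalent tables are representative, not authoritative;
  swap in transcribed tables via the documented CSV schema for real
  assessments.
* The CA is mechanism-faithful but not parameter-compatible with any
  released simulation package; hyperparameters (neighbourhood weights,
  seed probability, decay) are conventional defaults surfaced in
  `CAParams`.
* Scenario ESV uses structure-level (per-class) valuation; map-level
  scenario valuation differences from patch geometry are not modelled.
* No uncertainty propagation on valuation coefficients and no monetary
  discounting.
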