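# Methods

## Overview

`foodscape` converts a binary, tract-level food-desert flag into a
continuous score over space. Two feature families feed one classifier:

1. **Live food-environment features** computed from retailer listings and
   travel times around any point — geographically precise and refreshable.
2. **Census features** observed once per tract, made spatially continuous
   by universal kriging — smooth but temporally stale.

The classifier's predicted probability of the LILA label is the food
desert score; because both feature families are defined at every point, so
is the score.

## Representative points and distances

A tract is represented by the **area centroid** of its polygon (uniform-
density center of mass; holes subtract area, MultiPolygon parts combine by
area weight). For concave tracts the centroid may fall outside the
polygon; it is used anyway and flagged. All point-to-point distances are
great-circle on a sphere of radius 6371.0088 km. Travel *times* — the
quantity that actually gates retailer membership — come from a routing
provider; the synthetic provider returns distance / mode speed with
optional seeded lognormal noise.

## Retailer neighborhoods

Around an origin, retailers are organised into four lists: walking and
driving, within 10 or 20 minutes, with inclusive bounds (exactly 10.0 min
is in the short list). A retailer unreachable or beyond 20 minutes in a
mode is absent from that mode's lists but may appear under the other mode.
Only walking and driving are modelled; transit modes are out of scope.
Travel times are cached on first lookup, keyed by origin rounded to 5
decimals, retailer id and mode.

## Name canonicalization

Listings render a chain under many spellings. Normalization lowercases,
strips punctuation, and removes stop-words: ordinary ones plus a curated,
user-extensible *generic* list (retail words such as "supercenter",
"mart", "store", "restaurant", their variants, and corporate suffixes
"co", "company", "inc", ...). The generic list is a deliberate choice, not
auto-derived; `frequent_token_report` exists to support that curation. A
name whose tokens are all stop-words keeps its lowercased original and is
flagged.

Similarity is Ratcliff-Obershelp, `2·c_m/(|s1|+|s2|)`, with `c_m` counted
by recursive longest-matching-substring decomposition (longest block; ties
to the earliest start in the first string, then the second). Because that
decomposition is order-dependent in rare tie cases, the pair is put into a
canonical order (shorter first, ties lexicographic) before matching, which
makes the measure symmetric by construction. Lengths include the single
spaces between tokens.

Merging processes unique normalized names shortest-to-longest; a name
adopts the best already-assigned canonical name (highest similarity, then
shortest, then lexicographic) when similarity **strictly exceeds** 0.8,
else founds a new entity. Entities occurring at least 4 times are queued
for annotation.

## Crowd annotation and health classes

Stores get a 5-question schema (retailer type; fresh produce; whole
grains; low-fat dairy; prepared healthy options), restaurants a 4-question
one (venue type; healthy mains; fried-food dominance; fresh vegetables) —
a reconstruction of a shortened nutrition-environment audit. Five
annotators answer per entity; per question the plurality wins and an exact
tie is recorded as `"tie"`, contributing "unknown" downstream rather than
being silently resolved. The consensus retailer type fixes the health
class: supermarkets, large groceries, supercenters, produce stores and
farmers' markets are healthy; fast food, small groceries and convenience
stores are less healthy; delis and other restaurants remain unknown.
Entities never surveyed fall back to a configurable listing-tag keyword
map.

## Live features (44, fixed order)

Per mode x horizon (4 blocks): mRFEI, unhealthy index, a shared missing
indicator, healthy / less-healthy / unknown counts, total count. Per mode:
rating-band counts (medium = rating in [2, 4] inclusive, high > 4; unrated
counted in neither) for grocery-like vs restaurant-like venues, the health
proximity ratio with missing indicator, and mean rating with missing
indicator. Choices worth noting:

- `R_d` for the proximity ratios is the 20-minute list of the mode; the
  10-minute horizon was the alternative, and the longer one is used
  because it is the stated "acceptable commute".
- Durations are floored at 0.1 min in the ratio so co-located retailers
  cannot produce degenerate weights; the ratio's rescale-invariance is
  exact only above that floor.
- Unknown-health retailers are excluded from every numerator and
  denominator; their count is preserved as its own feature.
- Undefined ratios are NaN plus a paired 0/1 indicator: gradient-boosted
  trees consume the NaN natively, the indicator keeps the encoding
  portable.

## Scaling and kriging

Census features with any missing value are dropped (logged). The rest are
robust-scaled, `(x − Q2)/(Q3 − Q1)`, quartiles by linear interpolation
over the full data set; zero-IQR columns are dropped. Scaling precedes
kriging.

Each retained feature is kriged independently. The empirical
semivariogram uses 15 great-circle lag bins up to half the maximum
pairwise distance; a spherical model

    gamma(h) = nugget + psill (1.5 h/r − 0.5 (h/r)^3),  h <= r

is fitted by `scipy.optimize.least_squares` with soft-L1 loss (transition
1.0) on residuals standardized by the spread of the empirical values,
bounds nugget, psill >= 0 and r in (0, 4·max-lag]. The variogram is fitted
on residuals after ordinary-least-squares removal of the linear drift
(1, lon, lat), so a trend does not masquerade as correlation; optimizer
failure falls back to flagged moment estimates. Prediction solves the
universal-kriging system in semivariogram form with the same drift basis,
LU-factorised once per feature; a singular system gets 1e-10 diagonal
jitter, logged. Consequences verified by tests: exact interpolation at
zero nugget, exact reproduction of constants and of any plane, continuity
in the query point. On pure white noise the fit attributes the variance to
the nugget; the residual sill is negligible but its range parameter is
unidentified and may sit anywhere, so only the nugget and sill magnitudes
are meaningful there.

## LILA labels

A tract is a food desert iff it is low-access — at least 500 residents
**or** at least a 33% share living farther from the nearest
supermarket-class retailer (supermarket or supercenter) than 0.5 miles
(urban) / 10 miles (rural) — **and** low-income by the NMTC rule (poverty
rate >= 20% or median family income <= 80% of the area median). Both
boundaries are inclusive. The label distance is great-circle, not travel
time: the travel-time innovation lives in the features, while the label
reproduces the established index. Labels may also be supplied directly as
a CSV column, which the pipeline prefers when present.

## Scorer

LightGBM binary classifier, learning rate fixed at 0.05, tuned over
n_estimators in [50, 500], num_leaves in [8, 128], max_depth in [3, 12] by
Bayesian optimization of mean 5-fold stratified CV accuracy: 8 seeded
random initial configurations, then expected-improvement proposals from a
Matern-5/2 Gaussian-process surrogate on the unit-scaled space, 30
evaluations total by default. Stratification guards against class
imbalance in small cities. The final model refits on all data; raw
ensemble probabilities are reported without recalibration. Importances
are gain-based, normalized to sum 1, ties broken by name. All randomness
(folds, LightGBM, design, surrogate, candidates) flows from one seed and
runs single-threaded, giving bit-identical hyperparameters, CV metrics and
scores per seed.

`score_at_point` rebuilds the live features at an arbitrary point from the
providers, evaluates every kriged field there, and scores; points outside
the study bounding box are rejected rather than extrapolated.

## Route exposure

Routes are inputs (GeoJSON LineStrings with an ETA); no route planning is
performed. Sample points sit at equal arc-length spacing (default 100 m,
endpoints included, ceil(length/spacing) arcs). Mean exposure is the
trapezoid-rule length-weighted mean of sampled scores — symmetric under
reversing the route — and total exposure multiplies it by the ETA
(score-minutes), which is what the recommendation ranks. "Similar ETA"
means within 10% of the fastest (configurable); ties break by ETA then
route id.

## Synthetic city

The generator emulates the study inputs with known structure:

- Square tracts on a grid (default 10x10, 1 km tracts); latent
  *deprivation* is a zero-mean, unit-variance Gaussian field with
  spherical covariance (range 4 km) over tract centers.
- 60 census features (standing in for the real hundreds) = loadings in
  ±[0.3, 1] on deprivation + independent noise; one fifth are pure noise;
  two columns receive missing cells to exercise preprocessing. Poverty is
  a logistic transform of deprivation (mean ≈ 0.23), income ratio a
  clipped decreasing linear transform.
- Retailers per tract are Poisson: healthy intensity 1.1 − 0.7·deprivation,
  less-healthy 1.6 + 1.0·deprivation (clipped at 0), plus 0.5
  unknown-class venues — so deprived areas have worse retail mixes, as in
  real cities. Each retailer takes a chain identity from a 16-chain pool
  with a noisy name variant (article, corporate suffix, generic token, or
  spaced-letter typo) and type-derived tags, ratings and review counts.
- Travel times come from the distance/speed router (walk 5 km/h, drive
  30 km/h, lognormal sigma 0.1, keyed deterministically per pair).
- Five annotators answer each chain's questionnaire truthfully, each
  answer independently corrupted with probability 0.2 to a uniformly
  chosen wrong option — so per-question majority correctness should match
  P(Bin(5, 0.2) <= 2) ≈ 0.942, which the tests verify empirically.
- Ground-truth labels apply the LILA rule to a planted resident-point
  sample (40 uniform points per tract) against the true supermarket
  locations. An alternative `label_driver="driving_access"` makes the
  true, noiseless time-weighted healthy driving access the causal label
  (threshold 0.35, with driving slowed to 12 km/h so the 20-minute reach
  is local); this is the configuration under which the driving health
  proximity ratio should — and does — surface at the top of the
  importances.
- The urban flag is an independent 0.86 coin; population is Poisson(3000).

All randomness descends from one seed through named `SeedSequence` child
streams (field, census, retailers, names, responses, residents, misc), so
a seed reproduces the city byte-for-byte and artifact types can be
regenerated independently.

Planted scenarios support directional checks: a supermarket within 500 ft
of a chosen desert tract's boundary; a 12-outlet fast-food strip along the
most-deprived tract row; and an equal-ETA route pair whose corridor route
follows that row while the bypass detours through the least-deprived row.
The rows are deterministic functions of the planted field, so the contrast
between the two routes is structural rather than seed luck.

**What the generator does not emulate:** street networks (travel time is
distance/speed), demographic microsimulation, listing errors other than
name variants, annotator collusion or per-annotator bias, temporal change,
and the full dimensionality and collinearity structure of real census
feature sets. Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure — not performance on any
real city.

## Problem sizes and runtime choices

Default test and acceptance sizes are desk-scale by design: 10x10 tracts
for end-to-end runs, 15x15 (225 tracts) for the headline AUROC, 12x12 for
the access-driven importance check, 400 points for variogram recovery,
and 30 small cities (≥ 2,000 questions) for the consensus-recovery rate.
The optimization budget is 30 evaluations in the pipeline and 8–15 in
tests, which already saturates the small search space on these data sizes.

## Known limitations

- The kriging system is dense; thousands of tracts per feature would want
  neighborhood kriging, which is not implemented.
- Universal kriging's linear drift is the minimal choice; strong nonlinear
  trends end up in the variogram instead.
- The crowd module models annotator error as independent and uniform; real
  annotator quality control (gold questions, per-worker weights) is out of
  scope.
- Health classes are binary (plus unknown); the questionnaire's non-type
  answers are aggregated and stored but do not yet feed features.
- `score_at_point` trusts the provider for travel times at unseen points;
  with the fixture-backed providers this means distance/speed routing, not
  road networks.
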