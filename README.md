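# foodscape

A pipeline for turning a static, tract-level food-desert label into a
**continuous, real-time food-desert score**: a number in [0, 1] defined at
every point of a study area, refreshed from live retailer listings and
travel times rather than decade-old census snapshots — plus a route layer
that scores the food environment a traveller is exposed to and recommends
the healthiest among similar-ETA route alternatives.

It is written for spatial epidemiologists and civic-data engineers who have
(1) census tracts with an established Low-Income Low-Access (LILA)
food-desert flag, (2) a Yelp-like feed of food retailers, and (3) a source
of walking/driving travel times — and who want a model of food access that
does not jump at tract boundaries or miss the supermarket that opened last
year.

## Method

For each tract the area centroid serves as a representative point. Around
any query point the pipeline builds four travel-time-filtered retailer
lists (walking/driving x 10/20 minutes; anything beyond a 20-minute commute
in a mode is discarded for that mode) and computes live food-environment
features, including:

- the modified Retail Food Environment Index over each list,
  `mRFEI = 100 · n_healthy / (n_healthy + n_less_healthy)`,
  and its complementary unhealthy index;
- travel-time-weighted **health proximity ratios** per mode,
  `H_m = Σ_{i∈R_d} X_i·D_i / Σ_{i∈R_d} D_i`,
  where `R_d` is the acceptable-commute retailer set, `X_i` indicates a
  healthy retailer and `D_i` is the travel time in minutes;
- rating-band counts (medium = rating in [2, 4], high > 4) for grocery-like
  and restaurant-like venues.

Retailer identities are cleaned first: names are lowercased, stripped of
ordinary and generic retail stop-words, and merged by Ratcliff-Obershelp
similarity `d_ro = 2·c_m/(|s1|+|s2|)` with a strict 0.8 threshold, shortest
name winning. Each frequent entity is classified by five crowd annotators
through a shortened nutrition-environment questionnaire; per question the
plurality answer wins, and the consensus retailer type maps to
healthy / less-healthy / unknown by the CDC category rule.

Census features are robust-scaled (`(x − Q2)/(Q3 − Q1)`) and made
continuous by universal kriging with a spherical variogram (parameters
fitted per feature by soft-L1 minimisation; linear drift in lon/lat). A
LightGBM binary classifier is trained on kriged census features plus live
features against the LILA label, with number of trees, leaves and depth
chosen by Bayesian optimization of five-fold stratified CV accuracy; its
predicted probability is the food desert score. Route exposure integrates
that score along a route polyline and `recommend` returns the lowest-
exposure route within an ETA tolerance of the fastest.

No live API clients are included: retailer search and routing sit behind
provider interfaces backed by fixture files or the bundled synthetic city.

## Worked example

```
$ foodscape synth --seed 0 --grid 10x10 --out city \
    --scenario unhealthy_corridor --scenario equal_eta_route_pair
$ foodscape run --city-dir city --out run --seed 0
...
"train": {
  "n_rows": 100,
  "n_features": 102,
  "hyperparameters": {"n_estimators": 133, "num_leaves": 103, "max_depth": 8},
  "cv_accuracy": 0.72,
  "cv_auroc": 0.707475
},
"route": {"n_routes": 2, "recommended": "bypass"}
```

The synthetic city plants 100 square-km tracts whose latent deprivation
drives both the census features and the retail mix; 54 of them are
ground-truth LILA food deserts. The trained scorer reaches mean five-fold
CV accuracy 0.72 / AUROC 0.71 at this small size (at 225 tracts the AUROC
rises above 0.85), on 102 features (58 retained kriged census features —
two of the 60 are dropped for missing values — plus the 44 live features). Between the two planted equal-ETA routes, the one bypassing the
fast-food corridor is recommended. Score any point afterwards:

```
$ foodscape score-point --run-dir run --city-dir city --lon -84.51 --lat 33.63
0.096922
```

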