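"""A seeded synthetic city exercising every stage of the pipeline.

The generator emulates the study's inputs with known structure so that
each module can be tested against planted ground truth:

* a grid of square census tracts whose latent *deprivation* is a smooth
  Gaussian field with spherical covariance (configurable spatial range);
* census features as noisy linear loadings on deprivation, with poverty and
  income derived monotonically from it;
* healthy and less-healthy retailers from per-tract Poisson processes whose
  intensities respectively decrease and increase with deprivation, each
  retailer carrying a noisy name variant of a chain (injected stop-words,
  spaced-letter typos) plus listing tags, ratings and review counts;
* walking/driving travel times = great-circle distance / mode speed with
  seeded lognormal noise;
* five annotators per questionnaire, each answer independently corrupted
  with a configurable error probability;
* ground-truth food-desert labels obtained by applying the LILA rule to a
  planted resident-point geometry.

All randomness flows from a single seed through named child streams (one
per artifact type), so a seed reproduces the city byte-for-byte and
individual artifacts can be regenerated independently.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

from . import labeling
from .crowd_annotation import SCHEMAS, QuestionnaireResponse
from .geodata_io import TractRecord, haversine_km_matrix
from .name_canonicalization import NameMatchConfig, normalize
from .providers import (
    ListRetailerProvider,
    RetailerRecord,
    SyntheticRoutingProvider,
    TravelEstimate,
    TravelTimeCache,
)
from .route_exposure import Route

# km per degree of latitude on the sphere all distances use
KM_PER_DEG_LAT = 6371.0088 * math.pi / 180.0


@dataclass(frozen=True)
class CityConfig:
    seed: int = 0
    grid: tuple[int, int] = (10, 10)  # rows, cols of square tracts
    tract_size_km: float = 1.0
    n_census_features: int = 60
    deprivation_range_km: float = 4.0
    healthy_base: float = 1.1  # healthy retailers per tract at mean deprivation
    healthy_slope: float = 0.7  # decrease per deprivation s.d.
    unhealthy_base: float = 1.6
    unhealthy_slope: float = 1.0  # increase per deprivation s.d.
    neutral_rate: float = 0.5  # unknown-class venues per tract
    annotator_error_rate: float = 0.2
    n_annotators: int = 5
    walk_kmh: float = 5.0
    drive_kmh: float = 30.0
    duration_noise_sd: float = 0.1
    p_urban: float = 0.86
    population_mean: int = 3000
    n_resident_points: int = 40
    n_missing_features: int = 2  # columns given NaN cells (preprocessing food)
    origin_lon: float = -84.55
    origin_lat: float = 33.60
    search_radius_km: float = 12.0
    #: "lila" plants labels by the LILA rule on resident geometry; the
    #: "driving_access" alternative makes time-weighted healthy driving
    #: access the causal label driver: label = (true noiseless driving
    #: health proximity ratio < driving_access_threshold).
    label_driver: str = "lila"
    driving_access_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.grid[0] * self.grid[1] < 9:
            raise ValueError("grid must contain at least 9 tracts")
        if not 0.0 <= self.annotator_error_rate < 0.5:
            raise ValueError("annotator_error_rate must lie in [0, 0.5)")
        if self.label_driver not in ("lila", "driving_access"):
            raise ValueError("label_driver must be 'lila' or 'driving_access'")
        if self.walk_kmh <= 0 or self.drive_kmh <= 0:
            raise ValueError("speeds must be positive")


# (base chain name, retailer type, venue kind, tags)
HEALTHY_CHAINS = (
    ("kroger", "supermarket", "store", ("supermarket", "grocery")),
    ("publix", "supermarket", "store", ("supermarket", "grocery")),
    ("aldi", "supermarket", "store", ("supermarket",)),
    ("harvest supercenter", "supercenter", "store", ("supercenter",)),
    ("greenleaf grocery", "large_grocery", "store", ("grocery",)),
    ("sprouts produce", "produce_store", "store", ("organic_store",)),
    ("city farmers market", "farmers_market", "store", ("farmers_market",)),
)
UNHEALTHY_CHAINS = (
    ("burger palace", "fast_food", "restaurant", ("fast_food", "restaurant")),
    ("fried chicken shack", "fast_food", "restaurant", ("fast_food", "restaurant")),
    ("taco quick", "fast_food", "restaurant", ("fast_food", "restaurant")),
    ("quick stop", "convenience", "store", ("convenience_store",)),
    ("gas n go", "convenience", "store", ("convenience_store",)),
    ("bp food", "convenience", "store", ("convenience_store",)),
    ("corner pantry", "small_grocery", "store", ("small_grocery",)),
)
NEUTRAL_CHAINS = (
    ("daily deli", "deli", "restaurant", ("deli", "restaurant")),
    ("casa pasta", "restaurant_other", "restaurant", ("restaurants",)),
)
ALL_CHAINS = HEALTHY_CHAINS + UNHEALTHY_CHAINS + NEUTRAL_CHAINS

_TYPE_OPTIONS = {
    "store": (
        "supermarket", "large_grocery", "supercenter", "produce_store",
        "small_grocery", "convenience", "farmers_market",
    ),
    "restaurant": ("fast_food", "deli", "restaurant_other"),
}
_YESNO = ("yes", "no")


def true_answers(retailer_type: str, venue_kind: str) -> tuple[str, ...]:
    """Ground-truth questionnaire answers implied by a retailer's type."""
    healthyish = retailer_type in {
        "supermarket", "large_grocery", "supercenter", "produce_store", "farmers_market",
    }
    if venue_kind == "store":
        yn = "yes" if healthyish else "no"
        return (retailer_type, yn, yn, yn, yn)
    fast = retailer_type == "fast_food"
    return (
        retailer_type,
        "no" if fast else "yes",
        "yes" if fast else "no",
        "no" if fast else "yes",
    )


def _answer_options(venue_kind: str, q_index: int) -> tuple[str, ...]:
    return _TYPE_OPTIONS[venue_kind] if q_index == 0 else _YESNO


@dataclass
class SyntheticCity:
    config: CityConfig
    tracts: list[TractRecord]
    centroids: dict[str, tuple[float, float]]
    deprivation: dict[str, float]
    retailers: list[RetailerRecord]
    true_type: dict[str, str]  # retailer_id -> retailer type
    true_health: dict[str, str]  # retailer_id -> healthy/less_healthy/unknown
    chain_of: dict[str, str]  # retailer_id -> canonical chain name
    estimates: list[TravelEstimate]
    responses: list[QuestionnaireResponse]
    true_chain_answers: dict[str, tuple[str, ...]]
    chain_kind: dict[str, str]  # canonical chain -> store/restaurant
    ground_truth_labels: dict[str, bool]
    resident_points: dict[str, np.ndarray]
    routes: list[Route] = field(default_factory=list)

    def retailer_provider(self) -> ListRetailerProvider:
        return ListRetailerProvider(self.retailers)

    def routing_provider(self) -> SyntheticRoutingProvider:
        return SyntheticRoutingProvider(
            walk_kmh=self.config.walk_kmh,
            drive_kmh=self.config.drive_kmh,
            noise_sd=self.config.duration_noise_sd,
            seed=self.config.seed,
        )


def spherical_covariance(dist_km: np.ndarray, range_km: float) -> np.ndarray:
    """Spherical covariance C(h) = 1 - (1.5 h/r - 0.5 (h/r)^3), 0 beyond r."""
    ratio = np.clip(np.asarray(dist_km, dtype=float) / range_km, 0.0, 1.0)
    return 1.0 - (1.5 * ratio - 0.5 * ratio**3)


def gaussian_field(
    lonlat: np.ndarray, range_km: float, rng: np.random.Generator,
    nugget: float = 0.0, sill: float = 1.0,
) -> np.ndarray:
    """A zero-mean Gaussian random field with spherical covariance, via
    jittered Cholesky of the covariance between the supplied points."""
    d = haversine_km_matrix(lonlat, lonlat)
    cov = sill * spherical_covariance(d, range_km) + nugget * np.eye(len(lonlat))
    chol = np.linalg.cholesky(cov + 1e-8 * np.eye(len(lonlat)))
    return chol @ rng.standard_normal(len(lonlat))


def _name_variant(base: str, rng: np.random.Generator) -> str:
    """A listing-style spelling of a chain name: optional article, corporate
    suffix, generic token, or spaced-out first token."""
    tokens = base.split()
    style = rng.integers(0, 6)
    if style == 1:
        tokens = ["the"] + tokens
    elif style == 2:
        tokens = tokens + [str(rng.choice(["co", "company", "inc"]))]
    elif style == 3:
        tokens = tokens + [str(rng.choice(["store", "mart"]))]
    elif style == 4 and len(tokens[0]) >= 2:
        tokens = [" ".join(tokens[0])] + tokens[1:]
    return " ".join(w.capitalize() for w in " ".join(tokens).split())


def generate_city(config: CityConfig) -> SyntheticCity:
    rows, cols = config.grid
    n_tracts = rows * cols
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("field", "census", "retailers", "names", "responses", "residents", "misc"),
            np.random.SeedSequence(config.seed).spawn(7),
        )
    }

    dlat = config.tract_size_km / KM_PER_DEG_LAT
    dlon = config.tract_size_km / (KM_PER_DEG_LAT * math.cos(math.radians(config.origin_lat)))

    tract_ids, polygons, centers = [], [], []
    for r in range(rows):
        for c in range(cols):
            tract_ids.append(f"T{r:03d}{c:03d}")
            lon0 = config.origin_lon + c * dlon
            lat0 = config.origin_lat + r * dlat
            polygons.append(
                Polygon(
                    [
                        (lon0, lat0),
                        (lon0 + dlon, lat0),
                        (lon0 + dlon, lat0 + dlat),
                        (lon0, lat0 + dlat),
                    ]
                )
            )
            centers.append((lon0 + dlon / 2.0, lat0 + dlat / 2.0))
    centers_arr = np.array(centers)

    deprivation = gaussian_field(centers_arr, config.deprivation_range_km, streams["field"])

    # --- census features: linear loadings on deprivation + noise -------------
    rng_c = streams["census"]
    n_feat = config.n_census_features
    loadings = rng_c.uniform(0.3, 1.0, size=n_feat) * rng_c.choice([-1.0, 1.0], size=n_feat)
    n_pure_noise = max(n_feat // 5, 1)
    loadings[rng_c.choice(n_feat, size=n_pure_noise, replace=False)] = 0.0
    noise_sd = rng_c.uniform(0.5, 1.5, size=n_feat)
    census = loadings[None, :] * deprivation[:, None] + noise_sd[None, :] * rng_c.standard_normal(
        (n_tracts, n_feat)
    )
    feature_names = [f"cf_{j:03d}" for j in range(n_feat)]
    missing_cols = list(rng_c.choice(n_feat, size=min(config.n_missing_features, n_feat), replace=False))
    for j in missing_cols:
        cells = rng_c.choice(n_tracts, size=max(1, n_tracts // 30), replace=False)
        census[cells, j] = np.nan

    poverty = 1.0 / (1.0 + np.exp(-(-1.2 + 1.0 * deprivation)))
    income_ratio = np.clip(1.0 - 0.35 * deprivation, 0.2, 2.5)
    urban = streams["misc"].random(n_tracts) < config.p_urban
    population = streams["misc"].poisson(config.population_mean, size=n_tracts)

    # --- retailers -----------------------------------------------------------
    rng_r = streams["retailers"]
    rng_n = streams["names"]
    retailers: list[RetailerRecord] = []
    true_type: dict[str, str] = {}
    true_health: dict[str, str] = {}
    chain_of: dict[str, str] = {}
    counter = 0
    for i, tract_id in enumerate(tract_ids):
        d = deprivation[i]
        lam_h = max(config.healthy_base - config.healthy_slope * d, 0.0)
        lam_u = max(config.unhealthy_base + config.unhealthy_slope * d, 0.0)
        draws = (
            (HEALTHY_CHAINS, rng_r.poisson(lam_h), "healthy"),
            (UNHEALTHY_CHAINS, rng_r.poisson(lam_u), "less_healthy"),
            (NEUTRAL_CHAINS, rng_r.poisson(config.neutral_rate), "unknown"),
        )
        minx, miny, maxx, maxy = polygons[i].bounds
        for pool, count, health in draws:
            for _ in range(count):
                base, rtype, _kind, tags = pool[rng_r.integers(0, len(pool))]
                lon = rng_r.uniform(minx, maxx)
                lat = rng_r.uniform(miny, maxy)
                rid = f"R{counter:05d}"
                counter += 1
                rating = float(np.clip(round(rng_r.normal(3.5, 0.8) * 2) / 2, 0.5, 5.0))
                retailers.append(
                    RetailerRecord(
                        retailer_id=rid,
                        name=_name_variant(base, rng_n),
                        address=f"{100 + counter} {tract_id} St",
                        lon=lon,
                        lat=lat,
                        rating=rating,
                        review_count=int(rng_r.poisson(40)),
                        price_range=int(rng_r.integers(1, 5)),
                        tags=frozenset(tags),
                    )
                )
                true_type[rid] = rtype
                true_health[rid] = health
                chain_of[rid] = normalize(base, NameMatchConfig())

    # --- travel estimates (origin = tract centroid) --------------------------
    router = SyntheticRoutingProvider(
        walk_kmh=config.walk_kmh,
        drive_kmh=config.drive_kmh,
        noise_sd=config.duration_noise_sd,
        seed=config.seed,
    )
    estimates: list[TravelEstimate] = []
    if retailers:
        ret_lonlat = np.array([[r.lon, r.lat] for r in retailers])
        dists = haversine_km_matrix(centers_arr, ret_lonlat)
        for i, tract_id in enumerate(tract_ids):
            for j in np.nonzero(dists[i] <= config.search_radius_km)[0]:
                rec = retailers[j]
                origin = centers[i]
                for mode in ("walking", "driving"):
                    estimates.append(
                        TravelEstimate(
                            tract_id, rec.retailer_id, mode,
                            router.travel_time(origin, rec, mode),
                        )
                    )

    # --- questionnaire responses ---------------------------------------------
    rng_q = streams["responses"]
    responses: list[QuestionnaireResponse] = []
    truth: dict[str, tuple[str, ...]] = {}
    chain_kind: dict[str, str] = {}
    for base, rtype, kind, _tags in ALL_CHAINS:
        canon = normalize(base, NameMatchConfig())
        truth[canon] = true_answers(rtype, kind)
        chain_kind[canon] = kind
        for a in range(config.n_annotators):
            answers = []
            for q, ans in enumerate(truth[canon]):
                if rng_q.random() < config.annotator_error_rate:
                    options = [o for o in _answer_options(kind, q) if o != ans]
                    ans = str(rng_q.choice(options))
                answers.append(ans)
            responses.append(
                QuestionnaireResponse(canon, f"annotator_{a}", kind, tuple(answers))
            )

    # --- resident points, far population, ground-truth labels ----------------
    rng_p = streams["residents"]
    supermarkets = [r for r in retailers if true_type[r.retailer_id] in labeling.SUPERMARKET_TYPES]
    tracts: list[TractRecord] = []
    labels: dict[str, bool] = {}
    resident_points: dict[str, np.ndarray] = {}
    lila = labeling.LilaConfig()
    for i, tract_id in enumerate(tract_ids):
        minx, miny, maxx, maxy = polygons[i].bounds
        pts = np.column_stack(
            [
                rng_p.uniform(minx, maxx, config.n_resident_points),
                rng_p.uniform(miny, maxy, config.n_resident_points),
            ]
        )
        resident_points[tract_id] = pts
        rec = TractRecord(
            tract_id=tract_id,
            polygon=polygons[i],
            urban=bool(urban[i]),
            population=int(population[i]),
            poverty_rate=float(poverty[i]),
            median_family_income_ratio=float(income_ratio[i]),
            census_features={
                name: float(census[i, j]) for j, name in enumerate(feature_names)
            },
        )
        far_count, far_share = labeling.far_population(rec, supermarkets, lila, pts)
        rec.far_count = far_count
        rec.far_share = far_share
        rec.validate()
        tracts.append(rec)
        labels[tract_id] = labeling.lila_label(rec, lila)

    if config.label_driver == "driving_access":
        # Causal driver = true, noiseless time-weighted healthy driving
        # access; the pipeline only sees its noisy, crowd-classified proxy.
        for i, tract_id in enumerate(tract_ids):
            num = den = 0.0
            if retailers:
                minutes = dists[i] / config.drive_kmh * 60.0
                for j in np.nonzero(minutes <= 20.0)[0]:
                    d = max(float(minutes[j]), 0.1)
                    health = true_health[retailers[j].retailer_id]
                    if health == "unknown":
                        continue
                    den += d
                    if health == "healthy":
                        num += d
            h_true = num / den if den > 0 else 0.0
            labels[tract_id] = h_true < config.driving_access_threshold

    return SyntheticCity(
        config=config,
        tracts=tracts,
        centroids={tid: centers[i] for i, tid in enumerate(tract_ids)},
        deprivation={tid: float(deprivation[i]) for i, tid in enumerate(tract_ids)},
        retailers=retailers,
        true_type=true_type,
        true_health=true_health,
        chain_of=chain_of,
        estimates=estimates,
        responses=responses,
        true_chain_answers=truth,
        chain_kind=chain_kind,
        ground_truth_labels=labels,
        resident_points=resident_points,
    )


SCENARIOS = ("new_supermarket_near_desert", "unhealthy_corridor", "equal_eta_route_pair")


def plant_scenario(
    city: SyntheticCity, scenario: str, tract_id: str | None = None
) -> SyntheticCity:
    """Deterministically modify a city to enable directional tests.

    * ``new_supermarket_near_desert``: one supermarket placed within 500 ft
      of the boundary of a ground-truth desert tract (``tract_id`` selects
      which; default the first in sorted order).
    * ``unhealthy_corridor``: a dense fast-food strip along the mid-city
      east-west row.
    * ``equal_eta_route_pair``: two equal-ETA routes sharing endpoints, one
      along the corridor's latitude, one bypassing it through the city's
      least-deprived row.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; one of {SCENARIOS}")
    city = replace(
        city,
        retailers=list(city.retailers),
        true_type=dict(city.true_type),
        true_health=dict(city.true_health),
        chain_of=dict(city.chain_of),
        routes=list(city.routes),
    )

    if scenario == "new_supermarket_near_desert":
        desert_ids = sorted(t for t, lab in city.ground_truth_labels.items() if lab)
        if not desert_ids:
            raise ValueError("city has no desert tract to plant a supermarket near")
        if tract_id is not None:
            if tract_id not in desert_ids:
                raise ValueError(f"tract {tract_id!r} is not a ground-truth desert")
            chosen = tract_id
        else:
            chosen = desert_ids[0]
        tract = next(t for t in city.tracts if t.tract_id == chosen)
        minx, miny, maxx, maxy = tract.polygon.bounds
        # 500 ft ~ 0.1524 km inside the eastern boundary, mid-height.
        offset_deg = 0.1524 / (KM_PER_DEG_LAT * math.cos(math.radians((miny + maxy) / 2)))
        lon, lat = maxx - offset_deg / 2.0, (miny + maxy) / 2.0
        rid = "R_PLANTED_SUPERMARKET"
        city.retailers.append(
            RetailerRecord(
                retailer_id=rid,
                name="Fresh Fields",
                address=f"1 {tract.tract_id} Blvd",
                lon=lon,
                lat=lat,
                rating=4.5,
                review_count=120,
                tags=frozenset({"supermarket", "grocery"}),
                health_class="healthy",
            )
        )
        city.true_type[rid] = "supermarket"
        city.true_health[rid] = "healthy"
        city.chain_of[rid] = "fresh fields"
        return city

    lons = [c[0] for c in city.centroids.values()]
    west, east = min(lons), max(lons)
    # The corridor hugs the most-deprived row (where fast food clusters in
    # the generator's world); the bypass detours through the least-deprived
    # row.  Both are deterministic functions of the planted field.
    dep_by_lat: dict[float, list[float]] = {}
    for tid, (_, lat) in city.centroids.items():
        dep_by_lat.setdefault(round(lat, 9), []).append(city.deprivation[tid])
    row_means = sorted(
        (float(np.mean(vals)), lat) for lat, vals in dep_by_lat.items()
    )
    corridor_lat = row_means[-1][1]
    bypass_lat = row_means[0][1]

    if scenario == "unhealthy_corridor":
        for k, frac in enumerate(np.linspace(0.1, 0.9, 12)):
            rid = f"R_PLANTED_FF{k:02d}"
            city.retailers.append(
                RetailerRecord(
                    retailer_id=rid,
                    name=f"Burger Palace {k}",
                    address=f"{k} Corridor Rd",
                    lon=west + frac * (east - west),
                    lat=corridor_lat,
                    rating=2.0,
                    review_count=25,
                    tags=frozenset({"fast_food", "restaurant"}),
                    health_class="less_healthy",
                )
            )
            city.true_type[rid] = "fast_food"
            city.true_health[rid] = "less_healthy"
            city.chain_of[rid] = "burger palace"
        return city

    corridor = Route(
        route_id="corridor",
        polyline=((west, corridor_lat), (east, corridor_lat)),
        eta=15.0,
        mode="driving",
    )
    bypass = Route(
        route_id="bypass",
        polyline=(
            (west, corridor_lat), (west, bypass_lat),
            (east, bypass_lat), (east, corridor_lat),
        ),
        eta=15.0,
        mode="driving",
    )
    city.routes.extend([corridor, bypass])
    return city


# --------------------------------------------------------------------------
# Writers: the exact plain-text formats the ingest side of the pipeline reads.
# --------------------------------------------------------------------------

def write_city(city: SyntheticCity, outdir) -> dict[str, str]:
    """Write every artifact; identical seeds yield byte-identical files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tracts": os.path.join(outdir, "tracts.geojson"),
        "features": os.path.join(outdir, "features.csv"),
        "retailers": os.path.join(outdir, "retailers.jsonl"),
        "travel_cache": os.path.join(outdir, "travel_cache.json"),
        "responses": os.path.join(outdir, "responses.csv"),
        "labels": os.path.join(outdir, "labels.csv"),
    }

    from .geodata_io import write_tracts

    write_tracts(city.tracts, paths["tracts"], paths["features"])

    with open(paths["retailers"], "w", encoding="utf-8") as fh:
        for r in sorted(city.retailers, key=lambda r: r.retailer_id):
            fh.write(
                json.dumps(
                    {
                        "retailer_id": r.retailer_id,
                        "name": r.name,
                        "address": r.address,
                        "lon": r.lon,
                        "lat": r.lat,
                        "rating": r.rating,
                        "review_count": r.review_count,
                        "price_range": r.price_range,
                        "tags": sorted(r.tags),
                    },
                    sort_keys=True,
                )
                + "\n"
            )

    cache = TravelTimeCache()
    for est in city.estimates:
        origin = city.centroids[est.origin_id]
        cache.put(origin, est.retailer_id, est.mode, est.duration)
    cache.save(paths["travel_cache"])

    with open(paths["responses"], "w", encoding="utf-8") as fh:
        max_q = max(len(s) for s in SCHEMAS.values())
        header = ["canonical_name", "annotator_id", "venue_kind"] + [
            f"q{i + 1}" for i in range(max_q)
        ]
        fh.write(",".join(header) + "\n")
        for resp in sorted(city.responses, key=lambda r: (r.canonical_name, r.annotator_id)):
            row = [resp.canonical_name, resp.annotator_id, resp.venue_kind]
            row += list(resp.answers) + [""] * (max_q - len(resp.answers))
            fh.write(",".join(row) + "\n")

    with open(paths["labels"], "w", encoding="utf-8") as fh:
        fh.write("tract_id,label\n")
        for tid in sorted(city.ground_truth_labels):
            fh.write(f"{tid},{int(city.ground_truth_labels[tid])}\n")

    if city.routes:
        paths["routes"] = os.path.join(outdir, "routes.geojson")
        features = [
            {
                "type": "Feature",
                "properties": {"route_id": r.route_id, "eta": r.eta, "mode": r.mode},
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[lon, lat] for lon, lat in r.polyline],
                },
            }
            for r in city.routes
        ]
        with open(paths["routes"], "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)

    return paths
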