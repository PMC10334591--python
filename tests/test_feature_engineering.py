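"""Live food-environment indices: mRFEI, unhealthy index, rating bands,
health proximity ratios, and the assembled feature vector."""

import math

import numpy as np
import pytest

from foodscape.feature_engineering import (
    FEATURE_NAMES,
    assemble_features,
    health_proximity_ratio,
    mrfei,
    rating_band_counts,
    unhealthy_index,
)
from foodscape.providers import RetailerNeighborhood, RetailerRecord


def _rec(rid, health="healthy", rating=None, tags=()):
    return RetailerRecord(
        retailer_id=rid,
        name=rid,
        address=rid,
        lon=0.0,
        lat=0.0,
        rating=rating,
        tags=frozenset(tags),
        health_class=health,
    )


def _entries(spec):
    """spec: list of (health, duration) or (health, duration, rating, tags)."""
    out = []
    for i, item in enumerate(spec):
        health, dur = item[0], item[1]
        rating = item[2] if len(item) > 2 else None
        tags = item[3] if len(item) > 3 else ()
        out.append((_rec(f"r{i}", health, rating, tags), dur))
    return out


class TestMrfei:
    def test_three_healthy_one_less(self):
        e = _entries([("healthy", 5)] * 3 + [("less_healthy", 5)])
        assert mrfei(e) == 75.0
        assert unhealthy_index(e) == 25.0

    def test_no_healthy(self):
        e = _entries([("less_healthy", 5)] * 5)
        assert mrfei(e) == 0.0
        assert unhealthy_index(e) == 100.0

    def test_empty_classified_set_is_missing(self):
        assert mrfei([]) is None
        assert mrfei(_entries([("unknown", 5)])) is None
        assert unhealthy_index([]) is None

    def test_unknowns_excluded_from_both_counts(self):
        e = _entries([("healthy", 5), ("unknown", 5), ("less_healthy", 5)])
        assert mrfei(e) == 50.0

    def test_complement_identity_on_random_neighborhoods(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            e = _entries(
                [
                    (rng.choice(["healthy", "less_healthy", "unknown"]), rng.uniform(1, 20))
                    for _ in range(rng.integers(1, 15))
                ]
            )
            m, u = mrfei(e), unhealthy_index(e)
            if m is not None:
                assert m + u == 100.0

    def test_adding_healthy_never_decreases_adding_less_never_increases(self):
        e = _entries([("healthy", 5), ("less_healthy", 5), ("less_healthy", 5)])
        base = mrfei(e)
        assert mrfei(e + _entries([("healthy", 9)])) >= base
        assert mrfei(e + _entries([("less_healthy", 9)])) <= base


class TestRatingBands:
    def test_band_boundaries(self):
        e = _entries(
            [("healthy", 5, 4.5), ("healthy", 5, 4.0), ("healthy", 5, 1.5), ("healthy", 5, None)]
        )
        assert rating_band_counts(e) == (1, 1)  # 4.0 is medium, 4.5 high

    def test_category_split(self):
        e = _entries(
            [
                ("healthy", 5, 3.0, ("grocery",)),
                ("less_healthy", 5, 3.0, ("fast_food", "restaurant")),
            ]
        )
        assert rating_band_counts(e, "grocery_like") == (1, 0)
        assert rating_band_counts(e, "restaurant_like") == (1, 0)

    def test_no_rated_retailers(self):
        assert rating_band_counts(_entries([("healthy", 5)])) == (0, 0)


class TestHealthProximityRatio:
    def test_all_healthy_is_one(self):
        assert health_proximity_ratio(_entries([("healthy", d) for d in (3, 9, 14)])) == 1.0

    def test_time_weighting(self):
        # healthy at 12 min, less healthy at 6 min -> 12/18
        e = _entries([("healthy", 12.0), ("less_healthy", 6.0)])
        assert health_proximity_ratio(e) == pytest.approx(12.0 / 18.0)

    def test_empty_is_missing(self):
        assert health_proximity_ratio([]) is None
        assert health_proximity_ratio(_entries([("unknown", 5)])) is None

    def test_zero_duration_floor(self):
        e = _entries([("healthy", 0.0), ("less_healthy", 0.1)])
        assert health_proximity_ratio(e) == pytest.approx(0.5)

    def test_complement_identity_against_direct_summation(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            spec = [
                (rng.choice(["healthy", "less_healthy"]), float(rng.uniform(0.5, 20)))
                for _ in range(rng.integers(1, 12))
            ]
            flipped = [
                ("less_healthy" if h == "healthy" else "healthy", d) for h, d in spec
            ]
            h = health_proximity_ratio(_entries(spec))
            h_flip = health_proximity_ratio(_entries(flipped))
            assert h + h_flip == pytest.approx(1.0, abs=1e-12)
            # direct summation oracle
            num = sum(d for hh, d in spec if hh == "healthy")
            den = sum(d for _, d in spec)
            assert h == pytest.approx(num / den, abs=1e-12)

    def test_invariant_under_uniform_rescaling(self):
        rng = np.random.default_rng(2)
        spec = [
            (rng.choice(["healthy", "less_healthy"]), float(rng.uniform(1, 20)))
            for _ in range(8)
        ]
        base = health_proximity_ratio(_entries(spec))
        for k in (0.25, 3.0, 17.0):
            scaled = [(h, d * k) for h, d in spec]
            assert health_proximity_ratio(_entries(scaled)) == pytest.approx(base, abs=1e-12)


class TestAssemble:
    def test_empty_neighborhood_all_missing(self):
        feats = assemble_features("o", RetailerNeighborhood("o"))
        assert list(feats.values) == list(FEATURE_NAMES)
        for key in ("walk10", "walk20", "drive10", "drive20"):
            assert feats[f"{key}_total_count"] == 0
            assert feats[f"{key}_index_missing"] == 1.0
            assert math.isnan(feats[f"{key}_mrfei"])
        assert feats["walking_health_proximity_missing"] == 1.0

    def test_single_healthy_walkable_retailer(self):
        rec = _rec("r0", "healthy", rating=4.5, tags=("grocery",))
        hood = RetailerNeighborhood(
            "o", walk10=[(rec, 5.0)], walk20=[(rec, 5.0)]
        )
        feats = assemble_features("o", hood)
        assert feats["walk10_mrfei"] == 100.0
        assert feats["walking_health_proximity_ratio"] == 1.0
        assert feats["drive20_total_count"] == 0

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(3)
        entries20 = _entries(
            [
                (
                    rng.choice(["healthy", "less_healthy", "unknown"]),
                    float(rng.uniform(0.5, 20)),
                    float(rng.choice([1.5, 3.0, 4.0, 4.5])),
                    ("fast_food", "restaurant") if rng.random() < 0.5 else ("grocery",),
                )
                for _ in range(15)
            ]
        )
        walk10 = [(r, d) for r, d in entries20 if d <= 10.0]
        hood = RetailerNeighborhood("o", walk10=walk10, walk20=entries20)
        feats = assemble_features("o", hood)

        # spreadsheet-style recomputation of the walking 20-min block
        healthy = [e for e in entries20 if e[0].health_class == "healthy"]
        less = [e for e in entries20 if e[0].health_class == "less_healthy"]
        unknown = [e for e in entries20 if e[0].health_class == "unknown"]
        assert feats["walk20_healthy_count"] == len(healthy)
        assert feats["walk20_less_healthy_count"] == len(less)
        assert feats["walk20_unknown_count"] == len(unknown)
        assert feats["walk20_mrfei"] == pytest.approx(
            100.0 * len(healthy) / (len(healthy) + len(less))
        )
        num = sum(d for r, d in healthy)
        den = sum(d for r, d in healthy + less)
        assert feats["walking_health_proximity_ratio"] == pytest.approx(num / den)
        rest_med = sum(
            1
            for r, _ in entries20
            if "restaurant" in r.tags and r.rating is not None and 2 <= r.rating <= 4
        )
        assert feats["walking_restaurant_like_medium_rating_count"] == rest_med
        rated = [r.rating for r, _ in entries20 if r.rating is not None]
        assert feats["walking_mean_rating"] == pytest.approx(sum(rated) / len(rated))
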