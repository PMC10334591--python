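"""Live food-environment features for a point, from its retailer neighborhood.

For each travel mode (walking, driving) and horizon (10, 20 minutes) the
module computes the modified Retail Food Environment Index

    mRFEI = 100 * n_healthy / (n_healthy + n_less_healthy)

over the travel-time-filtered retailer list (travel time, not Euclidean
distance, decides membership), its complementary unhealthy index, and the
healthy / less-healthy / unknown counts.  Per mode it adds rating-band
counts (medium = rating in [2, 4], high = rating > 4) split into
grocery-like and restaurant-like venues, a mean listing rating, and the
travel-time-weighted Health Proximity Ratio

    H_m = sum_{i in R_d} X_i * D_i / sum_{i in R_d} D_i

where R_d is the acceptable-commute (20-minute) retailer set for the mode,
X_i is 1 for healthy retailers and 0 otherwise, and D_i the travel time in
minutes.  Ratios with an empty denominator are encoded as NaN plus a paired
binary missing indicator; unknown-health retailers are excluded from every
ratio but preserved in their own count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import math

from .crowd_annotation import AnnotationConsensus
from .providers import RetailerNeighborhood, RetailerRecord

#: Minimum travel time (minutes) used in proximity weights, so co-located
#: retailers cannot zero out the denominator.
MIN_DURATION_MIN = 0.1

_RESTAURANT_TAGS = frozenset(
    {"restaurant", "restaurants", "fast_food", "fastfood", "deli", "delis", "cafe"}
)

Entry = tuple[RetailerRecord, float]


def _effective_health(
    record: RetailerRecord,
    consensus: Mapping[str, AnnotationConsensus] | None,
) -> str:
    if consensus is not None and record.canonical_name in consensus:
        cls = consensus[record.canonical_name].health_class
        if cls != "unknown":
            return cls
    return record.health_class


def _counts(entries: Iterable[Entry], consensus=None) -> tuple[int, int, int]:
    healthy = less = unknown = 0
    for rec, _ in entries:
        cls = _effective_health(rec, consensus)
        if cls == "healthy":
            healthy += 1
        elif cls == "less_healthy":
            less += 1
        else:
            unknown += 1
    return healthy, less, unknown


def mrfei(entries: Iterable[Entry], consensus=None) -> float | None:
    """mRFEI in [0, 100]; None when no retailer has a known health class."""
    healthy, less, _ = _counts(entries, consensus)
    if healthy + less == 0:
        return None
    return 100.0 * healthy / (healthy + less)


def unhealthy_index(entries: Iterable[Entry], consensus=None) -> float | None:
    """100 × less-healthy share of classified retailers; complements mRFEI."""
    healthy, less, _ = _counts(entries, consensus)
    if healthy + less == 0:
        return None
    return 100.0 * less / (healthy + less)


def is_restaurant_like(record: RetailerRecord) -> bool:
    tags = {t.lower() for t in record.tags}
    return bool(tags & _RESTAURANT_TAGS)


def rating_band_counts(
    entries: Iterable[Entry], category: str = "all"
) -> tuple[int, int]:
    """(medium, high) rating counts: medium = rating in [2, 4], high > 4.

    ``category`` restricts to "grocery_like" or "restaurant_like" venues;
    unrated retailers count in neither band.
    """
    medium = high = 0
    for rec, _ in entries:
        if category == "restaurant_like" and not is_restaurant_like(rec):
            continue
        if category == "grocery_like" and is_restaurant_like(rec):
            continue
        if rec.rating is None:
            continue
        if 2.0 <= rec.rating <= 4.0:
            medium += 1
        elif rec.rating > 4.0:
            high += 1
    return medium, high


def health_proximity_ratio(entries: Iterable[Entry], consensus=None) -> float | None:
    """Travel-time-weighted healthy fraction H_m in [0, 1]; None when the
    classified neighborhood is empty.  Durations are floored at 0.1 min."""
    num = den = 0.0
    for rec, dur in entries:
        cls = _effective_health(rec, consensus)
        if cls == "unknown":
            continue
        d = max(float(dur), MIN_DURATION_MIN)
        den += d
        if cls == "healthy":
            num += d
    if den == 0.0:
        return None
    return num / den


def _mean_rating(entries: Iterable[Entry]) -> float | None:
    rated = [rec.rating for rec, _ in entries if rec.rating is not None]
    if not rated:
        return None
    return float(sum(rated)) / len(rated)


_COMBOS = (("walking", 10, "walk10"), ("walking", 20, "walk20"),
           ("driving", 10, "drive10"), ("driving", 20, "drive20"))


def _build_feature_names() -> list[str]:
    names: list[str] = []
    for _, _, key in _COMBOS:
        names += [
            f"{key}_mrfei",
            f"{key}_unhealthy_index",
            f"{key}_index_missing",
            f"{key}_healthy_count",
            f"{key}_less_healthy_count",
            f"{key}_unknown_count",
            f"{key}_total_count",
        ]
    for mode in ("walking", "driving"):
        for cat in ("grocery_like", "restaurant_like"):
            names += [f"{mode}_{cat}_medium_rating_count", f"{mode}_{cat}_high_rating_count"]
    for mode in ("walking", "driving"):
        names += [
            f"{mode}_health_proximity_ratio",
            f"{mode}_health_proximity_missing",
            f"{mode}_mean_rating",
            f"{mode}_mean_rating_missing",
        ]
    return names


#: The frozen, ordered roster of engineered live features (44 in total).
FEATURE_NAMES: tuple[str, ...] = tuple(_build_feature_names())


@dataclass
class FoodEnvFeatures:
    """Engineered live food-environment feature vector for one point."""

    origin_id: str
    values: dict[str, float] = field(default_factory=dict)

    def vector(self) -> list[float]:
        return [self.values[name] for name in FEATURE_NAMES]

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def assemble_features(
    origin_id: str,
    neighborhood: RetailerNeighborhood,
    consensus: Mapping[str, AnnotationConsensus] | None = None,
) -> FoodEnvFeatures:
    """The full ordered live-feature vector for one representative point.

    Missing ratios are NaN with their paired ``*_missing`` indicator set to
    1; gradient-boosted trees consume the NaN natively while the indicator
    keeps the encoding portable to other learners.
    """
    v: dict[str, float] = {}
    for mode, _, key in _COMBOS:
        entries = getattr(neighborhood, key)
        healthy, less, unknown = _counts(entries, consensus)
        m = mrfei(entries, consensus)
        u = unhealthy_index(entries, consensus)
        v[f"{key}_mrfei"] = math.nan if m is None else m
        v[f"{key}_unhealthy_index"] = math.nan if u is None else u
        v[f"{key}_index_missing"] = 1.0 if m is None else 0.0
        v[f"{key}_healthy_count"] = float(healthy)
        v[f"{key}_less_healthy_count"] = float(less)
        v[f"{key}_unknown_count"] = float(unknown)
        v[f"{key}_total_count"] = float(len(entries))

    for mode, key20 in (("walking", "walk20"), ("driving", "drive20")):
        entries = getattr(neighborhood, key20)
        for cat in ("grocery_like", "restaurant_like"):
            med, high = rating_band_counts(entries, cat)
            v[f"{mode}_{cat}_medium_rating_count"] = float(med)
            v[f"{mode}_{cat}_high_rating_count"] = float(high)

        h = health_proximity_ratio(entries, consensus)
        v[f"{mode}_health_proximity_ratio"] = math.nan if h is None else h
        v[f"{mode}_health_proximity_missing"] = 1.0 if h is None else 0.0
        r = _mean_rating(entries)
        v[f"{mode}_mean_rating"] = math.nan if r is None else r
        v[f"{mode}_mean_rating_missing"] = 1.0 if r is None else 0.0

    assert set(v) == set(FEATURE_NAMES)
    ordered = {name: v[name] for name in FEATURE_NAMES}
    return FoodEnvFeatures(origin_id=origin_id, values=ordered)
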