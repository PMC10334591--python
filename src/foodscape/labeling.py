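"""Tract-level Low-Income Low-Access (LILA) food-desert labels.

A tract is *low access* when a significant number (>= 500) or share
(>= 33%) of its residents lives farther from the nearest supermarket than
half a mile in urban tracts or ten miles in rural tracts.  It is *low
income* under the Treasury New Markets Tax Credit rule: poverty rate >= 20%
or median family income <= 80% of the area median.  The food-desert label
is the conjunction of both.  Distance here is great-circle to the nearest
supermarket-class retailer (supermarket or supercenter); the travel-time
machinery elsewhere feeds the model's features, not this label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .geodata_io import KM_PER_MILE, TractRecord, haversine_km_matrix
from .providers import RetailerRecord

SUPERMARKET_TYPES = frozenset({"supermarket", "supercenter"})


@dataclass(frozen=True)
class LilaConfig:
    far_count_threshold: int = 500
    far_share_threshold: float = 0.33
    urban_distance_miles: float = 0.5
    rural_distance_miles: float = 10.0
    poverty_threshold: float = 0.20
    income_ratio_threshold: float = 0.80

    def __post_init__(self) -> None:
        for name in (
            "far_count_threshold",
            "far_share_threshold",
            "urban_distance_miles",
            "rural_distance_miles",
            "poverty_threshold",
            "income_ratio_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def is_supermarket(retailer: RetailerRecord, retailer_type: str | None = None) -> bool:
    """Supermarket-class retailers anchor the access criterion."""
    if retailer_type is not None:
        return retailer_type in SUPERMARKET_TYPES
    tags = {t.lower() for t in retailer.tags}
    return bool(tags & {"supermarket", "supermarkets", "supercenter"})


def far_population(
    tract: TractRecord,
    supermarkets: Sequence[RetailerRecord],
    config: LilaConfig = LilaConfig(),
    resident_points: np.ndarray | None = None,
) -> tuple[int, float]:
    """(far_count, far_share) of residents beyond the access distance.

    ``resident_points`` is an (n, 2) lon/lat sample of where the tract's
    residents live; each sampled resident represents population / n people.
    When no sample is given the tract's stored ``far_count``/``far_share``
    (e.g. census-derived) are returned unchanged.
    """
    if tract.population <= 0:
        return 0, 0.0
    if resident_points is None:
        return tract.far_count, tract.far_share
    resident_points = np.asarray(resident_points, dtype=float)
    threshold_km = (
        config.urban_distance_miles if tract.urban else config.rural_distance_miles
    ) * KM_PER_MILE
    if len(supermarkets) == 0:
        far_frac = 1.0
    else:
        market_lonlat = np.array([[s.lon, s.lat] for s in supermarkets])
        nearest = haversine_km_matrix(resident_points, market_lonlat).min(axis=1)
        far_frac = float(np.mean(nearest > threshold_km))
    far_count = int(round(far_frac * tract.population))
    return far_count, far_frac


def low_access(far_count: int, far_share: float, config: LilaConfig = LilaConfig()) -> bool:
    return far_count >= config.far_count_threshold or far_share >= config.far_share_threshold


def low_income(tract: TractRecord, config: LilaConfig = LilaConfig()) -> bool:
    return (
        tract.poverty_rate >= config.poverty_threshold
        or tract.median_family_income_ratio <= config.income_ratio_threshold
    )


def lila_label(tract: TractRecord, config: LilaConfig = LilaConfig()) -> bool:
    """True iff the tract is both low-access and low-income."""
    return low_access(tract.far_count, tract.far_share, config) and low_income(tract, config)


def label_tracts(
    tracts: Iterable[TractRecord], config: LilaConfig = LilaConfig()
) -> dict[str, bool]:
    return {t.tract_id: lila_label(t, config) for t in tracts}
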