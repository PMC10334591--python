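"""Retailer search, travel-time lookup, and travel-time-filtered neighborhoods.

Both the retailer-search and the routing side are provider-abstracted: a
provider may be a fixture file, the synthetic city, or (as an extension
point) a live API client.  Around any query point, retailers are organised
into four lists — walking/driving within 10 or 20 minutes — and everything
beyond a 20-minute commute in a mode is discarded for that mode.  Thresholds
are inclusive.  Travel times are cached on first lookup so repeated feature
builds never re-query a provider.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Protocol

import numpy as np

from .geodata_io import haversine_km

#: Sentinel duration for origin/retailer pairs a provider cannot route.
UNREACHABLE = math.inf

SHORT_HORIZON_MIN = 10.0
LONG_HORIZON_MIN = 20.0
MODES = ("walking", "driving")


@dataclass
class RetailerRecord:
    """One food retailer as pulled from a Yelp-like listing source."""

    retailer_id: str
    name: str
    address: str
    lon: float
    lat: float
    rating: float | None = None
    review_count: int = 0
    price_range: int | None = None
    tags: frozenset[str] = frozenset()
    canonical_name: str | None = None
    health_class: str = "unknown"  # healthy | less_healthy | unknown

    def __post_init__(self) -> None:
        if self.rating is not None and not 0.5 <= self.rating <= 5.0:
            raise ValueError(f"retailer {self.retailer_id}: rating {self.rating} outside [0.5, 5]")
        if isinstance(self.tags, (set, list, tuple)):
            self.tags = frozenset(self.tags)


@dataclass(frozen=True)
class TravelEstimate:
    origin_id: str
    retailer_id: str
    mode: str
    duration: float  # minutes; UNREACHABLE when no route exists

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown travel mode {self.mode!r}")
        if not (self.duration >= 0.0 or math.isinf(self.duration)):
            raise ValueError("duration must be >= 0 minutes")


@dataclass
class RetailerNeighborhood:
    """The four travel-time-filtered retailer lists around one origin.

    Each entry is ``(retailer, duration_minutes)``.  By construction
    walk10 ⊆ walk20 and drive10 ⊆ drive20, and no entry exceeds 20 minutes
    for its mode.
    """

    origin_id: str
    walk10: list[tuple[RetailerRecord, float]] = field(default_factory=list)
    walk20: list[tuple[RetailerRecord, float]] = field(default_factory=list)
    drive10: list[tuple[RetailerRecord, float]] = field(default_factory=list)
    drive20: list[tuple[RetailerRecord, float]] = field(default_factory=list)

    def for_mode(self, mode: str, horizon: int) -> list[tuple[RetailerRecord, float]]:
        key = {"walking": "walk", "driving": "drive"}[mode] + str(horizon)
        return getattr(self, key)


class RetailerSearchProvider(Protocol):
    def search(self, lon: float, lat: float, radius_km: float) -> list[RetailerRecord]: ...


class RoutingProvider(Protocol):
    def travel_time(self, origin: tuple[float, float], retailer: RetailerRecord, mode: str) -> float: ...


class FixtureRetailerProvider:
    """Retailer search backed by a JSON-lines fixture file (one record per line)."""

    def __init__(self, path: str):
        self.retailers: list[RetailerRecord] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                raw = json.loads(line)
                raw["tags"] = frozenset(raw.get("tags", ()))
                self.retailers.append(RetailerRecord(**raw))

    def search(self, lon: float, lat: float, radius_km: float) -> list[RetailerRecord]:
        hits = [
            r for r in self.retailers if haversine_km(lon, lat, r.lon, r.lat) <= radius_km
        ]
        return sorted(hits, key=lambda r: r.retailer_id)


class ListRetailerProvider:
    """In-memory provider over an explicit retailer list (synthetic city)."""

    def __init__(self, retailers: Iterable[RetailerRecord]):
        self.retailers = list(retailers)

    def search(self, lon: float, lat: float, radius_km: float) -> list[RetailerRecord]:
        hits = [
            r for r in self.retailers if haversine_km(lon, lat, r.lon, r.lat) <= radius_km
        ]
        return sorted(hits, key=lambda r: r.retailer_id)


class SyntheticRoutingProvider:
    """Travel times from great-circle distance, mode speed, and seeded noise.

    duration = distance / speed × exp(ε), ε ~ N(0, noise_sd²) drawn
    deterministically per (origin, retailer, mode) so repeated queries and
    repeated runs agree.  ``noise_sd = 0`` gives exact distance/speed times.
    """

    def __init__(
        self,
        walk_kmh: float = 5.0,
        drive_kmh: float = 30.0,
        noise_sd: float = 0.0,
        seed: int = 0,
    ):
        if walk_kmh <= 0 or drive_kmh <= 0:
            raise ValueError("speeds must be positive")
        self.speeds = {"walking": walk_kmh, "driving": drive_kmh}
        self.noise_sd = noise_sd
        self.seed = seed
        self.call_count = 0

    def travel_time(self, origin: tuple[float, float], retailer: RetailerRecord, mode: str) -> float:
        if mode not in MODES:
            raise ValueError(f"unknown travel mode {mode!r}")
        self.call_count += 1
        dist_km = haversine_km(origin[0], origin[1], retailer.lon, retailer.lat)
        minutes = dist_km / self.speeds[mode] * 60.0
        if self.noise_sd > 0.0 and minutes > 0.0:
            # Stable per-(origin, retailer, mode) noise: crc32 keying keeps
            # the draw identical across processes and repeated queries.
            key = f"{origin[0]:.5f},{origin[1]:.5f}|{retailer.retailer_id}|{mode}"
            sub = np.random.default_rng([self.seed, zlib.crc32(key.encode())])
            minutes *= math.exp(sub.normal(0.0, self.noise_sd))
        return minutes


class TravelTimeCache:
    """JSON-backed memo of travel times, keyed by rounded origin + retailer + mode."""

    def __init__(self, path: str | None = None):
        self.path = path
        self._store: dict[str, float] = {}
        if path is not None:
            try:
                with open(path, encoding="utf-8") as fh:
                    raw = json.load(fh)
                self._store = {k: (UNREACHABLE if v is None else float(v)) for k, v in raw.items()}
            except FileNotFoundError:
                pass

    @staticmethod
    def key(origin: tuple[float, float], retailer_id: str, mode: str) -> str:
        return f"{round(origin[0], 5):.5f},{round(origin[1], 5):.5f}|{retailer_id}|{mode}"

    def get(self, origin, retailer_id, mode) -> float | None:
        return self._store.get(self.key(origin, retailer_id, mode))

    def put(self, origin, retailer_id, mode, duration: float) -> None:
        self._store[self.key(origin, retailer_id, mode)] = duration

    def save(self, path: str | None = None) -> None:
        path = path or self.path
        if path is None:
            raise ValueError("no path configured for travel-time cache")
        serializable = {
            k: (None if math.isinf(v) else v) for k, v in sorted(self._store.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(serializable, fh, sort_keys=True)

    def __len__(self) -> int:
        return len(self._store)


def search_retailers(
    point: tuple[float, float],
    source: RetailerSearchProvider,
    radius_km: float = 12.0,
) -> list[RetailerRecord]:
    """All retailers near a point; duplicate (name, address) pairs collapsed.

    The default radius comfortably exceeds the 20-minute driving reach at
    the synthetic provider's default 30 km/h, so the travel-time filter, not
    the search radius, decides membership.
    """
    seen: dict[tuple[str, str], RetailerRecord] = {}
    for rec in source.search(point[0], point[1], radius_km):
        key = (rec.name.strip().lower(), rec.address.strip().lower())
        seen.setdefault(key, rec)
    return sorted(seen.values(), key=lambda r: r.retailer_id)


def travel_time(
    origin: tuple[float, float],
    retailer: RetailerRecord,
    mode: str,
    source: RoutingProvider,
    cache: TravelTimeCache | None = None,
) -> float:
    """Travel time in minutes, memoised; UNREACHABLE when no route exists."""
    if cache is not None:
        hit = cache.get(origin, retailer.retailer_id, mode)
        if hit is not None:
            return hit
    minutes = source.travel_time(origin, retailer, mode)
    if cache is not None:
        cache.put(origin, retailer.retailer_id, mode, minutes)
    return minutes


def build_neighborhood(
    origin_id: str,
    retailers: Iterable[RetailerRecord],
    estimates: Iterable[TravelEstimate],
) -> RetailerNeighborhood:
    """Threshold travel estimates into the four mode/horizon lists.

    A retailer beyond 20 minutes (or unreachable) in one mode is absent from
    that mode's lists but may still appear under the other mode.  Bounds are
    inclusive: exactly 10.0 minutes lands in the short list.
    """
    by_id = {r.retailer_id: r for r in retailers}
    durations: dict[tuple[str, str], float] = {}
    for est in estimates:
        if est.origin_id != origin_id or est.retailer_id not in by_id:
            continue
        key = (est.retailer_id, est.mode)
        if key in durations:
            raise ValueError(f"duplicate travel estimate for {key}")
        durations[key] = est.duration

    hood = RetailerNeighborhood(origin_id=origin_id)
    for rid in sorted(by_id):
        rec = by_id[rid]
        for mode in MODES:
            dur = durations.get((rid, mode))
            if dur is None or math.isinf(dur) or dur > LONG_HORIZON_MIN:
                continue
            if mode == "walking":
                hood.walk20.append((rec, dur))
                if dur <= SHORT_HORIZON_MIN:
                    hood.walk10.append((rec, dur))
            else:
                hood.drive20.append((rec, dur))
                if dur <= SHORT_HORIZON_MIN:
                    hood.drive10.append((rec, dur))
    return hood
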