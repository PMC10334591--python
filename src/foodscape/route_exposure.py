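"""Food-environment exposure along candidate routes.

A traveller moving through a city experiences a changing food environment;
this module integrates the continuous food-desert score along a route's
polyline.  Sample points are placed at equal arc-length spacing (endpoints
always included), scored, and combined by the trapezoid rule into a
length-weighted mean exposure; the time-integrated total is that mean times
the route's ETA.  Among candidate routes whose ETA is within a tolerance of
the fastest, the one with the lowest total exposure — the healthiest food
environment en route — is recommended.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .geodata_io import haversine_km

ScoreFn = Callable[[float, float], float]


@dataclass(frozen=True)
class Route:
    route_id: str
    polyline: tuple[tuple[float, float], ...]  # (lon, lat), >= 2 points
    eta: float  # minutes
    mode: str = "driving"

    def __post_init__(self) -> None:
        if len(self.polyline) < 2:
            raise ValueError(f"route {self.route_id}: polyline needs >= 2 points")
        for a, b in zip(self.polyline, self.polyline[1:]):
            if a == b:
                raise ValueError(f"route {self.route_id}: repeated consecutive point {a}")
        if not self.eta > 0:
            raise ValueError(f"route {self.route_id}: eta must be positive")


@dataclass
class RouteExposure:
    route_id: str
    sample_points: list[tuple[float, float, float]]  # (lon, lat, score)
    mean_exposure: float
    total_exposure: float  # mean score × eta minutes


def _cumulative_lengths(polyline: Sequence[tuple[float, float]]) -> np.ndarray:
    segs = [
        haversine_km(a[0], a[1], b[0], b[1]) * 1000.0
        for a, b in zip(polyline, polyline[1:])
    ]
    return np.concatenate([[0.0], np.cumsum(segs)])


def sample_route(
    polyline: Sequence[tuple[float, float]], spacing_meters: float
) -> list[tuple[float, float]]:
    """Points at equal arc-length spacing along a polyline, endpoints included.

    The polyline is divided into ceil(length / spacing) equal arcs; spacing
    larger than the whole route degenerates to just the two endpoints.
    """
    if spacing_meters <= 0:
        raise ValueError("spacing must be positive")
    if len(polyline) < 2:
        raise ValueError("degenerate polyline")
    cum = _cumulative_lengths(polyline)
    total = float(cum[-1])
    if total == 0.0:
        raise ValueError("degenerate (zero-length) polyline")
    n_arcs = max(1, math.ceil(total / spacing_meters))
    targets = np.linspace(0.0, total, n_arcs + 1)

    pts: list[tuple[float, float]] = []
    seg = 0
    for t in targets:
        while seg < len(cum) - 2 and cum[seg + 1] < t:
            seg += 1
        seg_len = cum[seg + 1] - cum[seg]
        frac = 0.0 if seg_len == 0 else (t - cum[seg]) / seg_len
        frac = min(max(frac, 0.0), 1.0)
        a, b = polyline[seg], polyline[seg + 1]
        pts.append((a[0] + frac * (b[0] - a[0]), a[1] + frac * (b[1] - a[1])))
    return pts


def exposure(
    route: Route, score_fn: ScoreFn, spacing_meters: float = 100.0
) -> RouteExposure:
    """Integrate the food-desert score along the route.

    mean_exposure is the trapezoid-rule length-weighted mean of the sampled
    scores (symmetric under reversing the route); total_exposure multiplies
    it by the ETA, giving a score-minutes measure of time spent exposed.
    """
    pts = sample_route(route.polyline, spacing_meters)
    scores = [float(score_fn(lon, lat)) for lon, lat in pts]
    for s in scores:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"route {route.route_id}: score {s} outside [0, 1]")
    if len(scores) == 1:  # pragma: no cover - sample_route returns >= 2
        mean = scores[0]
    else:
        weights = np.ones(len(scores))
        weights[0] = weights[-1] = 0.5
        mean = float(np.average(scores, weights=weights))
    return RouteExposure(
        route_id=route.route_id,
        sample_points=[(p[0], p[1], s) for p, s in zip(pts, scores)],
        mean_exposure=mean,
        total_exposure=mean * route.eta,
    )


def recommend(
    routes: Sequence[Route],
    score_fn: ScoreFn,
    eta_tolerance_fraction: float = 0.1,
    spacing_meters: float = 100.0,
) -> str:
    """Healthiest among similar-ETA routes.

    Candidates are the routes with eta <= (1 + tolerance) × fastest eta;
    the minimal total exposure wins, ties broken by smaller eta, then
    route_id.
    """
    if not routes:
        raise ValueError("no routes to recommend from")
    min_eta = min(r.eta for r in routes)
    candidates = [r for r in routes if r.eta <= (1.0 + eta_tolerance_fraction) * min_eta]
    ranked = sorted(
        candidates,
        key=lambda r: (exposure(r, score_fn, spacing_meters).total_exposure, r.eta, r.route_id),
    )
    return ranked[0].route_id


def read_routes_geojson(path: str) -> list[Route]:
    """Routes from a GeoJSON FeatureCollection of LineStrings with an
    ``eta`` (minutes) property."""
    with open(path, encoding="utf-8") as fh:
        collection = json.load(fh)
    routes = []
    for i, feat in enumerate(collection.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "LineString":
            raise ValueError(f"feature {i}: expected LineString, got {geom.get('type')}")
        props = feat.get("properties") or {}
        routes.append(
            Route(
                route_id=str(props.get("route_id", f"route_{i}")),
                polyline=tuple((float(x), float(y)) for x, y in geom["coordinates"]),
                eta=float(props["eta"]),
                mode=str(props.get("mode", "driving")),
            )
        )
    return routes


def write_report(exposures: Sequence[RouteExposure], path: str) -> None:
    payload = {
        e.route_id: {
            "mean_exposure": e.mean_exposure,
            "total_exposure": e.total_exposure,
            "n_samples": len(e.sample_points),
        }
        for e in exposures
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
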