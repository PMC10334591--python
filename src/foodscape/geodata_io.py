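"""Tract geometry and tabular I/O, representative points, spherical distance.

Census tracts arrive as a GeoJSON FeatureCollection of (multi)polygons plus a
CSV of per-tract attributes (population metrics and the census feature
vector).  Each tract is represented downstream by a single point: the area
centroid of its polygon (uniform-density center of mass, holes subtracted,
MultiPolygon parts combined by area weight).  All coordinates are WGS84
lon/lat; distances between points are great-circle.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088
KM_PER_MILE = 1.609344

#: CSV columns that are tract metadata rather than census features.
METRIC_COLUMNS = (
    "urban",
    "population",
    "far_count",
    "far_share",
    "poverty_rate",
    "median_family_income_ratio",
    "label",
)


@dataclass
class TractRecord:
    """One census tract: geometry, population metrics, census features."""

    tract_id: str
    polygon: BaseGeometry
    urban: bool = True
    population: int = 0
    far_count: int = 0
    far_share: float = 0.0
    poverty_rate: float = 0.0
    median_family_income_ratio: float = 1.0
    census_features: dict[str, float] = field(default_factory=dict)
    label: bool | None = None

    def validate(self) -> None:
        if not (0 <= self.far_count <= max(self.population, 0)):
            raise ValueError(
                f"tract {self.tract_id}: far_count {self.far_count} exceeds "
                f"population {self.population}"
            )
        if not 0.0 <= self.far_share <= 1.0:
            raise ValueError(f"tract {self.tract_id}: far_share outside [0, 1]")
        if not self.polygon.is_valid:
            raise ValueError(f"tract {self.tract_id}: invalid polygon geometry")


@dataclass(frozen=True)
class RepresentativePoint:
    """Area centroid of a tract, standing in for the tract in queries.

    ``outside`` flags the (legitimate) concave-polygon case where the area
    centroid falls outside the tract itself.
    """

    tract_id: str
    lon: float
    lat: float
    outside: bool = False


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance in km between two WGS84 lon/lat points."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def haversine_km_matrix(lonlat_a: np.ndarray, lonlat_b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances (km) between two (n, 2) lon/lat arrays."""
    a = np.radians(np.asarray(lonlat_a, dtype=float))
    b = np.radians(np.asarray(lonlat_b, dtype=float))
    phi_a = a[:, 1][:, None]
    phi_b = b[:, 1][None, :]
    dphi = phi_b - phi_a
    dlam = b[:, 0][None, :] - a[:, 0][:, None]
    h = np.sin(dphi / 2.0) ** 2 + np.cos(phi_a) * np.cos(phi_b) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.clip(np.sqrt(h), 0.0, 1.0))


def centroid(polygon: BaseGeometry) -> tuple[float, float]:
    """Area centroid (lon, lat) of a polygon or multipolygon.

    The centroid is the uniform-density center of mass over the enclosed
    area — not the vertex mean — with holes subtracting area and
    MultiPolygon parts combined by area weight.
    """
    if polygon.is_empty or polygon.area == 0.0:
        raise ValueError("degenerate (zero-area) polygon has no area centroid")
    c = polygon.centroid
    return float(c.x), float(c.y)


def representative_point(tract: TractRecord) -> RepresentativePoint:
    lon, lat = centroid(tract.polygon)
    outside = not tract.polygon.covers(tract.polygon.centroid)
    if outside:
        warnings.warn(
            f"tract {tract.tract_id}: area centroid falls outside the polygon "
            "(concave geometry); using it anyway",
            stacklevel=2,
        )
    return RepresentativePoint(tract.tract_id, lon, lat, outside=outside)


def _coerce_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in {"1", "true", "t", "yes"}
    return bool(x)


def read_tracts(path: str, features_path: str) -> list[TractRecord]:
    """Read tract polygons (GeoJSON) joined with per-tract attributes (CSV).

    The join on ``tract_id`` is inner; tracts present in only one source are
    dropped with a warning.  Columns of the CSV not listed in
    :data:`METRIC_COLUMNS` form the census feature vector.  Missing feature
    cells are kept as NaN — removal of incomplete features happens later in
    preprocessing.
    """
    with open(path, encoding="utf-8") as fh:
        collection = json.load(fh)
    if collection.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: expected a GeoJSON FeatureCollection")

    geoms: dict[str, BaseGeometry] = {}
    for feat in collection["features"]:
        props = feat.get("properties") or {}
        tract_id = str(props.get("tract_id", feat.get("id", "")))
        if not tract_id:
            raise ValueError("GeoJSON feature without a tract_id")
        if tract_id in geoms:
            raise ValueError(f"duplicate tract_id {tract_id!r} in {path}")
        try:
            geom = shape(feat["geometry"])
        except Exception as exc:  # pragma: no cover - exercised via error path
            raise ValueError(f"unparseable geometry for tract {tract_id!r}: {exc}") from exc
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"tract {tract_id!r}: geometry is {geom.geom_type}, not a polygon")
        if not geom.is_valid:
            raise ValueError(f"tract {tract_id!r}: invalid (self-intersecting?) polygon")
        geoms[tract_id] = geom

    table = pd.read_csv(features_path, dtype={"tract_id": str})
    if table["tract_id"].duplicated().any():
        dup = table["tract_id"][table["tract_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate tract_id {dup!r} in {features_path}")
    table = table.set_index("tract_id")

    geo_ids = set(geoms)
    csv_ids = set(table.index)
    for missing in sorted(geo_ids - csv_ids):
        warnings.warn(f"tract {missing!r} has geometry but no CSV row; dropped", stacklevel=2)
    for missing in sorted(csv_ids - geo_ids):
        warnings.warn(f"tract {missing!r} has a CSV row but no geometry; dropped", stacklevel=2)

    feature_cols = [c for c in table.columns if c not in METRIC_COLUMNS]
    if len(set(feature_cols)) != len(feature_cols):  # pragma: no cover
        raise ValueError("census feature column names are not unique")

    records = []
    for tract_id in sorted(geo_ids & csv_ids):
        row = table.loc[tract_id]
        label = None
        if "label" in table.columns and not pd.isna(row["label"]):
            label = _coerce_bool(row["label"])
        rec = TractRecord(
            tract_id=tract_id,
            polygon=geoms[tract_id],
            urban=_coerce_bool(row.get("urban", True)),
            population=int(row.get("population", 0)),
            far_count=int(row.get("far_count", 0)),
            far_share=float(row.get("far_share", 0.0)),
            poverty_rate=float(row.get("poverty_rate", 0.0)),
            median_family_income_ratio=float(row.get("median_family_income_ratio", 1.0)),
            census_features={c: float(row[c]) for c in feature_cols},
            label=label,
        )
        rec.validate()
        records.append(rec)
    return records


def write_tracts(records: list[TractRecord], path: str, features_path: str) -> None:
    """Write tracts back to GeoJSON + CSV (inverse of :func:`read_tracts`)."""
    features = []
    for rec in records:
        features.append(
            {
                "type": "Feature",
                "properties": {"tract_id": rec.tract_id},
                "geometry": mapping(rec.polygon),
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, sort_keys=True)

    rows = []
    for rec in records:
        row: dict[str, object] = {
            "tract_id": rec.tract_id,
            "urban": rec.urban,
            "population": rec.population,
            "far_count": rec.far_count,
            "far_share": rec.far_share,
            "poverty_rate": rec.poverty_rate,
            "median_family_income_ratio": rec.median_family_income_ratio,
        }
        if rec.label is not None:
            row["label"] = rec.label
        row.update(rec.census_features)
        rows.append(row)
    pd.DataFrame(rows).to_csv(features_path, index=False, float_format="%.17g")
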