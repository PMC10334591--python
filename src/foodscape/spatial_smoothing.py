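"""Robust scaling and universal kriging of census-tract features.

Census features live at tract level and jump at tract boundaries.  To obtain
geographically continuous surfaces, each retained feature is (1) robust
scaled,

    x_scaled = (x - Q2) / (Q3 - Q1),

with quartiles over the whole data set (median/IQR resist outliers far
better than mean/variance), and (2) interpolated by universal kriging: a
linear drift in (lon, lat) plus a correlated residual whose spatial
structure is a spherical variogram

    gamma(h) = nugget + psill * (1.5 h/r - 0.5 (h/r)^3)   for 0 < h <= r,
    gamma(h) = nugget + psill                              for h > r,

with gamma(0) = 0.  Variogram parameters are fitted per feature to the
binned empirical semivariogram by soft-L1 (Huber, transition 1.0 on
standardized residuals) minimisation.  Distances are great-circle km.

The kriging system is solved in semivariogram form,

    [ Gamma  F ] [lambda]   [gamma_0]
    [ F^T    0 ] [  mu  ] = [  f_0  ],

with drift basis f = (1, lon, lat); the prediction is lambda . z.  With a
zero nugget the predictor interpolates the data exactly, and any function in
the drift space (e.g. a plane) is reproduced exactly regardless of the
variogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import least_squares

from .geodata_io import haversine_km_matrix

logger = logging.getLogger(__name__)


def drop_incomplete(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove every feature column containing at least one missing value."""
    removed = [c for c in features.columns if features[c].isna().any()]
    kept = features.drop(columns=removed)
    if kept.shape[1] == 0:
        raise ValueError("all feature columns contain missing values")
    if removed:
        logger.info("dropped %d incomplete feature columns: %s", len(removed), removed)
    return kept, removed


def robust_scale(column: np.ndarray) -> np.ndarray:
    """(x - median) / IQR with linearly interpolated quartiles.

    Raises on zero IQR; callers drop such columns (see
    :func:`scale_features`).
    """
    x = np.asarray(column, dtype=float)
    q1, q2, q3 = np.percentile(x, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    if iqr == 0.0:
        raise ValueError("zero interquartile range")
    return (x - q2) / iqr


def scale_features(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Robust-scale every column; columns with zero IQR are dropped, logged."""
    dropped: list[str] = []
    scaled: dict[str, np.ndarray] = {}
    for col in features.columns:
        try:
            scaled[col] = robust_scale(features[col].to_numpy())
        except ValueError:
            dropped.append(col)
    if not scaled:
        raise ValueError("every feature column has zero IQR")
    if dropped:
        logger.info("dropped %d zero-IQR columns: %s", len(dropped), dropped)
    return pd.DataFrame(scaled, index=features.index), dropped


@dataclass
class VariogramModel:
    kind: str = "spherical"
    nugget: float = 0.0
    partial_sill: float = 1.0
    range_km: float = 1.0
    fallback: bool = False  # True when the optimizer failed and moment
    # estimates were used instead

    def __post_init__(self) -> None:
        if self.nugget < 0 or self.partial_sill < 0 or self.range_km <= 0:
            raise ValueError("variogram parameters out of range")

    def gamma(self, h: np.ndarray) -> np.ndarray:
        """Semivariance at distance h (km); gamma(0) = 0 exactly."""
        h = np.asarray(h, dtype=float)
        ratio = np.clip(h / self.range_km, 0.0, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * ratio - 0.5 * ratio**3)
        return np.where(h == 0.0, 0.0, g)


def empirical_variogram(
    lonlat: np.ndarray, values: np.ndarray, n_bins: int = 15
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned empirical semivariogram (lag centers, semivariances, pair counts).

    Lags run up to half the maximum pairwise great-circle distance.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    z = np.asarray(values, dtype=float)
    d = haversine_km_matrix(lonlat, lonlat)
    iu = np.triu_indices(len(z), k=1)
    dists = d[iu]
    semis = 0.5 * (z[iu[0]] - z[iu[1]]) ** 2
    max_lag = dists.max() / 2.0
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    centers, gammas, counts = [], [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (dists > lo) & (dists <= hi)
        if mask.sum() == 0:
            continue
        centers.append(dists[mask].mean())
        gammas.append(semis[mask].mean())
        counts.append(int(mask.sum()))
    return np.array(centers), np.array(gammas), np.array(counts)


def fit_variogram(
    lonlat: np.ndarray, values: np.ndarray, n_bins: int = 15
) -> VariogramModel:
    """Spherical variogram fitted to the empirical semivariogram by soft-L1.

    Residuals are standardized by the spread of the empirical semivariances
    before the Huber-type (soft-L1, transition 1.0) loss is applied.  If the
    optimizer fails, method-of-moments initial estimates are returned with
    the ``fallback`` flag set.
    """
    lonlat = np.asarray(lonlat, dtype=float)
    z = np.asarray(values, dtype=float)
    if len(z) < 10:
        raise ValueError("variogram fitting needs at least 10 locations")
    lags, gammas, _ = empirical_variogram(lonlat, z, n_bins=n_bins)
    var = float(np.var(z))
    max_lag = float(lags.max())
    range_lo = max(1e-4 * max_lag, 1e-9)

    nugget0 = float(np.clip(gammas[0], 0.0, max(var, 1e-12)))
    psill0 = max(var - nugget0, 1e-6 * max(var, 1.0))
    range0 = 0.5 * max_lag
    scale = max(float(np.std(gammas)), 1e-12)

    def residuals(theta):
        model = VariogramModel(nugget=theta[0], partial_sill=theta[1], range_km=theta[2])
        return (model.gamma(lags) - gammas) / scale

    try:
        sol = least_squares(
            residuals,
            x0=[nugget0, psill0, range0],
            bounds=([0.0, 0.0, range_lo], [np.inf, np.inf, 4.0 * max_lag]),
            loss="soft_l1",
            f_scale=1.0,
        )
        if not sol.success:
            raise RuntimeError(sol.message)
        nugget, psill, rng = sol.x
        return VariogramModel(nugget=float(nugget), partial_sill=float(psill), range_km=float(rng))
    except Exception as exc:  # moment fallback, flagged
        logger.warning("variogram optimizer failed (%s); using moment estimates", exc)
        return VariogramModel(
            nugget=nugget0, partial_sill=psill0, range_km=range0, fallback=True
        )


class KrigedField:
    """A single census feature interpolated continuously over the study area."""

    def __init__(
        self,
        feature_name: str,
        lonlat: np.ndarray,
        values: np.ndarray,
        variogram: VariogramModel | None = None,
        n_bins: int = 15,
    ):
        self.feature_name = feature_name
        self.lonlat = np.asarray(lonlat, dtype=float)
        self.values = np.asarray(values, dtype=float)
        n = len(self.values)
        if self.lonlat.shape != (n, 2):
            raise ValueError("lonlat must be (n, 2) matching values")

        if variogram is None:
            # Fit the variogram on residuals after removing the linear drift,
            # so the trend does not masquerade as spatial correlation.
            drift = self._drift(self.lonlat)
            beta, *_ = np.linalg.lstsq(drift, self.values, rcond=None)
            variogram = fit_variogram(self.lonlat, self.values - drift @ beta, n_bins=n_bins)
        self.variogram = variogram

        gamma_mat = self.variogram.gamma(haversine_km_matrix(self.lonlat, self.lonlat))
        drift = self._drift(self.lonlat)
        k = drift.shape[1]
        a = np.zeros((n + k, n + k))
        a[:n, :n] = gamma_mat
        a[:n, n:] = drift
        a[n:, :n] = drift.T
        self._n = n
        try:
            self._factor = lu_factor(a)
        except Exception:
            a[:n, :n] += np.eye(n) * 1e-10
            logger.warning("singular kriging system for %s; jitter added", feature_name)
            self._factor = lu_factor(a)
        self._rhs_pad = k

        lons, lats = self.lonlat[:, 0], self.lonlat[:, 1]
        self.bbox = (lons.min(), lats.min(), lons.max(), lats.max())

    @staticmethod
    def _drift(lonlat: np.ndarray) -> np.ndarray:
        return np.column_stack([np.ones(len(lonlat)), lonlat[:, 0], lonlat[:, 1]])

    def predict_many(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        gamma0 = self.variogram.gamma(haversine_km_matrix(self.lonlat, queries))
        rhs = np.vstack([gamma0, self._drift(queries).T])
        lam = lu_solve(self._factor, rhs)[: self._n]
        return self.values @ lam

    def predict(self, lon: float, lat: float) -> float:
        return float(self.predict_many(np.array([[lon, lat]]))[0])

    def to_dict(self) -> dict:
        return {
            "feature_name": self.feature_name,
            "lonlat": self.lonlat.tolist(),
            "values": self.values.tolist(),
            "variogram": {
                "kind": self.variogram.kind,
                "nugget": self.variogram.nugget,
                "partial_sill": self.variogram.partial_sill,
                "range_km": self.variogram.range_km,
                "fallback": self.variogram.fallback,
            },
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "KrigedField":
        vg = VariogramModel(**payload["variogram"])
        return cls(
            payload["feature_name"],
            np.array(payload["lonlat"]),
            np.array(payload["values"]),
            variogram=vg,
        )
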