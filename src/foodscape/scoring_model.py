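"""Gradient-boosted food-desert scorer with Bayesian hyperparameter search.

A LightGBM binary classifier maps a point's feature vector — kriged census
features plus the live food-environment features — to the probability that
the point sits in a food desert: the continuous "food desert score".
Hyperparameters (number of trees, leaves per tree, maximum tree depth) are
chosen by Bayesian optimization of mean five-fold stratified
cross-validated accuracy: a Gaussian-process surrogate (Matern 5/2) over
the unit-cube-scaled integer space, expected-improvement acquisition, and a
seeded random initial design.  The final model is refit on all data with
the best configuration.  Every random draw flows from one seed, so a fixed
seed reproduces hyperparameters, CV metrics and scores bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .feature_engineering import assemble_features
from .providers import (
    MODES,
    TravelEstimate,
    TravelTimeCache,
    build_neighborhood,
    search_retailers,
    travel_time,
)

#: Search space: (low, high) inclusive integer bounds per hyperparameter.
SEARCH_SPACE = {
    "n_estimators": (50, 500),
    "num_leaves": (8, 128),
    "max_depth": (3, 12),
}
LEARNING_RATE = 0.05
N_FOLDS = 5
N_INITIAL = 8


@dataclass
class TrainedScorer:
    model: LGBMClassifier
    feature_names: list[str]
    hyperparameters: dict[str, int]
    cv_metrics: dict[str, list[float]]
    seed: int
    history: list[tuple[dict[str, int], float]] = field(default_factory=list)

    @property
    def cv_accuracy(self) -> float:
        return float(np.mean(self.cv_metrics["accuracy"]))

    @property
    def cv_auroc(self) -> float:
        return float(np.mean(self.cv_metrics["auroc"]))


def _make_model(params: dict[str, int], seed: int) -> LGBMClassifier:
    return LGBMClassifier(
        n_estimators=int(params["n_estimators"]),
        num_leaves=int(params["num_leaves"]),
        max_depth=int(params["max_depth"]),
        learning_rate=LEARNING_RATE,
        random_state=seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbosity=-1,
    )


def crossval_metrics(
    x, y: np.ndarray, params: dict[str, int], seed: int
) -> dict[str, list[float]]:
    """Per-fold accuracy and AUROC of a configuration under stratified 5-fold CV."""
    if not isinstance(x, pd.DataFrame):
        x = pd.DataFrame(np.asarray(x, dtype=float))
        x.columns = [f"f{i}" for i in range(x.shape[1])]
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    accs, aucs = [], []
    for train_idx, test_idx in skf.split(x, y):
        model = _make_model(params, seed)
        model.fit(x.iloc[train_idx], y[train_idx])
        proba = model.predict_proba(x.iloc[test_idx])[:, 1]
        accs.append(float(accuracy_score(y[test_idx], proba >= 0.5)))
        aucs.append(float(roc_auc_score(y[test_idx], proba)))
    return {"accuracy": accs, "auroc": aucs}


def _to_unit(params_arr: np.ndarray) -> np.ndarray:
    lo = np.array([b[0] for b in SEARCH_SPACE.values()], dtype=float)
    hi = np.array([b[1] for b in SEARCH_SPACE.values()], dtype=float)
    return (params_arr - lo) / (hi - lo)


def _sample_params(rng: np.random.Generator, n: int) -> np.ndarray:
    cols = [
        rng.integers(lo, hi + 1, size=n) for lo, hi in SEARCH_SPACE.values()
    ]
    return np.column_stack(cols).astype(float)


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    imp = mu - best
    z = imp / sigma
    return imp * norm.cdf(z) + sigma * norm.pdf(z)


def tune_and_train(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    budget: int = 30,
) -> TrainedScorer:
    """Bayesian-optimized LightGBM scorer.

    ``budget`` is the total number of hyperparameter configurations
    evaluated (seeded random initial design of 8, then EI-guided proposals).
    The returned scorer is refit on the full data with the best
    configuration; ``cv_metrics`` holds that configuration's fold metrics.
    """
    if isinstance(features, pd.DataFrame):
        feature_names = [str(c) for c in features.columns]
        x = features.astype(float).copy()
        x.columns = feature_names
    else:
        arr = np.asarray(features, dtype=float)
        feature_names = [f"f{i}" for i in range(arr.shape[1])]
        x = pd.DataFrame(arr, columns=feature_names)
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; nothing to learn")
    if counts.min() < N_FOLDS:
        raise ValueError(
            f"minority class has {counts.min()} rows; too few for {N_FOLDS}-fold "
            "stratified CV"
        )

    rng = np.random.default_rng(seed)
    evaluated: dict[tuple[int, ...], float] = {}
    history: list[tuple[dict[str, int], float]] = []

    def evaluate(row: np.ndarray) -> float:
        key = tuple(int(v) for v in row)
        if key in evaluated:
            return evaluated[key]
        params = dict(zip(SEARCH_SPACE, key))
        acc = float(np.mean(crossval_metrics(x, y, params, seed)["accuracy"]))
        evaluated[key] = acc
        history.append((params, acc))
        return acc

    design = _sample_params(rng, min(N_INITIAL, budget))
    for row in design:
        evaluate(row)

    kernel = ConstantKernel(1.0) * Matern(length_scale=[0.3, 0.3, 0.3], nu=2.5)
    while len(evaluated) < budget:
        keys = np.array(list(evaluated), dtype=float)
        scores = np.array([evaluated[tuple(int(v) for v in k)] for k in keys])
        gp = GaussianProcessRegressor(
            kernel=kernel, alpha=1e-6, normalize_y=True, random_state=seed
        )
        with warnings.catch_warnings():
            # surrogate kernel hyperparameters hitting their bounds is
            # routine on small evaluation histories
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            gp.fit(_to_unit(keys), scores)
        candidates = _sample_params(rng, 256)
        mu, sigma = gp.predict(_to_unit(candidates), return_std=True)
        ei = _expected_improvement(mu, sigma, scores.max())
        order = np.argsort(-ei)
        for idx in order:
            key = tuple(int(v) for v in candidates[idx])
            if key not in evaluated:
                evaluate(candidates[idx])
                break
        else:  # every candidate already tried (tiny spaces)
            break

    best_key = max(sorted(evaluated), key=lambda k: evaluated[k])
    best_params = dict(zip(SEARCH_SPACE, (int(v) for v in best_key)))
    cv = crossval_metrics(x, y, best_params, seed)
    final = _make_model(best_params, seed)
    final.fit(x, y)
    return TrainedScorer(
        model=final,
        feature_names=feature_names,
        hyperparameters=best_params,
        cv_metrics=cv,
        seed=seed,
        history=history,
    )


def _vectorize(scorer: TrainedScorer, features) -> np.ndarray:
    if isinstance(features, dict):
        missing = [n for n in scorer.feature_names if n not in features]
        if missing:
            raise KeyError(f"missing feature(s): {', '.join(missing)}")
        return np.array([[float(features[n]) for n in scorer.feature_names]])
    if isinstance(features, pd.DataFrame):
        missing = [n for n in scorer.feature_names if n not in features.columns]
        if missing:
            raise KeyError(f"missing feature(s): {', '.join(missing)}")
        return features[scorer.feature_names].to_numpy(dtype=float)
    arr = np.atleast_2d(np.asarray(features, dtype=float))
    if arr.shape[1] != len(scorer.feature_names):
        raise ValueError(
            f"expected {len(scorer.feature_names)} features, got {arr.shape[1]}"
        )
    return arr


def score(scorer: TrainedScorer, features) -> float | np.ndarray:
    """Food-desert score(s) in [0, 1] for one vector/dict or a feature frame."""
    arr = _vectorize(scorer, features)
    frame = pd.DataFrame(arr, columns=scorer.feature_names)
    proba = scorer.model.predict_proba(frame)[:, 1]
    return float(proba[0]) if arr.shape[0] == 1 and not isinstance(
        features, pd.DataFrame
    ) else proba


def feature_importance(scorer: TrainedScorer) -> list[tuple[str, float]]:
    """Gain-based importances, normalized to sum 1, descending (ties by name)."""
    gains = scorer.model.booster_.feature_importance(importance_type="gain")
    total = gains.sum()
    if total == 0:
        total = 1.0
    pairs = [
        (name, float(g) / total) for name, g in zip(scorer.feature_names, gains)
    ]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


class _BoosterModel:
    """predict_proba facade over a bare LightGBM Booster (for loaded models)."""

    def __init__(self, booster):
        self.booster_ = booster

    def predict_proba(self, x) -> np.ndarray:
        p = np.asarray(self.booster_.predict(x))
        return np.column_stack([1.0 - p, p])


def save_scorer(scorer: TrainedScorer, path: str) -> None:
    """Serialize model, feature names, hyperparameters and seed to one JSON file."""
    import json

    payload = {
        "model": scorer.model.booster_.model_to_string(),
        "feature_names": scorer.feature_names,
        "hyperparameters": scorer.hyperparameters,
        "cv_metrics": scorer.cv_metrics,
        "seed": scorer.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_scorer(path: str) -> TrainedScorer:
    import json

    import lightgbm as lgb

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    booster = lgb.Booster(model_str=payload["model"])
    return TrainedScorer(
        model=_BoosterModel(booster),
        feature_names=payload["feature_names"],
        hyperparameters=payload["hyperparameters"],
        cv_metrics=payload["cv_metrics"],
        seed=payload["seed"],
    )


def score_at_point(
    scorer: TrainedScorer,
    kriged_fields: dict,
    retailer_provider,
    routing_provider,
    lon: float,
    lat: float,
    consensus: dict | None = None,
    cache: TravelTimeCache | None = None,
    radius_km: float = 12.0,
    bbox: tuple[float, float, float, float] | None = None,
) -> float:
    """The continuous, real-time index: live features + kriged census
    features assembled at an arbitrary point, then scored.

    Raises when the point falls outside the study bounding box
    (lon_min, lat_min, lon_max, lat_max) — by default the box of the kriged
    training data; pass the tract extent to allow the whole study area.
    Extrapolating the drift beyond the study area is not meaningful.
    """
    boxes = [f.bbox for f in kriged_fields.values()]
    if bbox is not None:
        lon_min, lat_min, lon_max, lat_max = bbox
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise ValueError(
                f"point ({lon:.5f}, {lat:.5f}) lies outside the study bounding box"
            )
    elif boxes:
        lon_min = min(b[0] for b in boxes)
        lat_min = min(b[1] for b in boxes)
        lon_max = max(b[2] for b in boxes)
        lat_max = max(b[3] for b in boxes)
        if not (lon_min <= lon <= lon_max and lat_min <= lat <= lat_max):
            raise ValueError(
                f"point ({lon:.5f}, {lat:.5f}) lies outside the study bounding box"
            )

    origin_id = f"pt_{lon:.5f}_{lat:.5f}"
    retailers = search_retailers((lon, lat), retailer_provider, radius_km=radius_km)
    estimates = [
        TravelEstimate(
            origin_id,
            r.retailer_id,
            mode,
            travel_time((lon, lat), r, mode, routing_provider, cache),
        )
        for r in retailers
        for mode in MODES
    ]
    hood = build_neighborhood(origin_id, retailers, estimates)
    live = assemble_features(origin_id, hood, consensus)

    vec = dict(live.values)
    for name, fld in kriged_fields.items():
        vec[name] = fld.predict(lon, lat)
    return float(score(scorer, vec))
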