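"""Robust scaling, variogram fitting, and universal kriging."""

import numpy as np
import pandas as pd
import pytest

from foodscape.spatial_smoothing import (
    KrigedField,
    VariogramModel,
    drop_incomplete,
    empirical_variogram,
    fit_variogram,
    robust_scale,
    scale_features,
)
from foodscape.synthetic_data import gaussian_field


@pytest.fixture(scope="module")
def scatter_400():
    rng = np.random.default_rng(42)
    return np.column_stack(
        [rng.uniform(-84.6, -84.45, 400), rng.uniform(33.60, 33.73, 400)]
    )


class TestPreprocessing:
    def test_drop_incomplete_removes_columns_with_any_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, np.nan], "c": [0.0, 0.0]})
        kept, removed = drop_incomplete(df)
        assert list(kept.columns) == ["a", "c"]
        assert removed == ["b"]

    def test_drop_incomplete_identity_when_complete(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        kept, removed = drop_incomplete(df)
        assert removed == [] and kept.equals(df)

    def test_all_columns_missing_errors(self):
        with pytest.raises(ValueError):
            drop_incomplete(pd.DataFrame({"a": [np.nan, 1.0]}))

    def test_robust_scale_worked_example(self):
        out = robust_scale(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
        assert out == pytest.approx([-1.0, -0.5, 0.0, 0.5, 1.0])

    def test_scaled_median_zero_iqr_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(rng.uniform(-50, 50), rng.uniform(0.1, 30), size=101)
            s = robust_scale(x)
            assert np.median(s) == pytest.approx(0.0, abs=1e-12)
            q1, q3 = np.percentile(s, [25, 75])
            assert q3 - q1 == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        for a, b in [(2.0, 3.0), (0.1, -7.0), (115.0, 0.4)]:
            assert robust_scale(a * x + b) == pytest.approx(robust_scale(x), abs=1e-9)

    def test_matches_sklearn_robust_scaler(self):
        from sklearn.preprocessing import RobustScaler

        rng = np.random.default_rng(2)
        x = rng.standard_gamma(2.0, size=80)
        ours = robust_scale(x)
        theirs = RobustScaler().fit_transform(x[:, None])[:, 0]
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_zero_iqr_column_dropped_by_scale_features(self):
        df = pd.DataFrame({"flat": [3.0] * 10, "ok": np.arange(10.0)})
        scaled, dropped = scale_features(df)
        assert dropped == ["flat"] and list(scaled.columns) == ["ok"]


class TestVariogram:
    def test_gamma_shape_and_monotonicity(self):
        vg = VariogramModel(nugget=0.2, partial_sill=1.0, range_km=3.0)
        h = np.linspace(0, 6, 200)
        g = vg.gamma(h)
        assert g[0] == 0.0  # gamma(0) = 0 despite the nugget
        assert np.all(np.diff(g[1:]) >= -1e-12)
        assert g[-1] == pytest.approx(1.2)
        assert vg.gamma(np.array([3.0]))[0] == pytest.approx(1.2)

    def test_constant_values_give_zero_sill(self, scatter_400):
        vg = fit_variogram(scatter_400[:50], np.full(50, 4.2))
        assert vg.partial_sill == pytest.approx(0.0, abs=1e-8)
        assert vg.nugget == pytest.approx(0.0, abs=1e-8)

    def test_recovers_planted_range_within_30_percent(self, scatter_400):
        rng = np.random.default_rng(7)
        z = gaussian_field(scatter_400, 3.0, rng)
        vg = fit_variogram(scatter_400, z)
        assert 0.7 * 3.0 <= vg.range_km <= 1.3 * 3.0
        assert vg.nugget < 0.3 * vg.partial_sill

    def test_white_noise_attributes_variance_to_nugget(self, scatter_400):
        rng = np.random.default_rng(8)
        z = rng.standard_normal(400)
        vg = fit_variogram(scatter_400, z)
        assert vg.nugget == pytest.approx(z.var(), rel=0.25)
        assert vg.partial_sill < 0.5 * vg.nugget

    def test_binning_covers_half_max_distance(self, scatter_400):
        lags, gammas, counts = empirical_variogram(scatter_400[:80], np.arange(80.0))
        assert len(lags) <= 15 and np.all(counts > 0)
        from foodscape.geodata_io import haversine_km_matrix

        dmax = haversine_km_matrix(scatter_400[:80], scatter_400[:80]).max()
        assert lags.max() <= dmax / 2 + 1e-9


@pytest.fixture(scope="module")
def smooth_field(scatter_400):
    rng = np.random.default_rng(9)
    z = gaussian_field(scatter_400, 4.0, rng)
    return scatter_400, z


class TestKriging:
    def test_exact_interpolation_with_zero_nugget(self, smooth_field):
        lonlat, z = smooth_field
        fld = KrigedField(
            "f", lonlat[:100], z[:100],
            variogram=VariogramModel(nugget=0.0, partial_sill=1.0, range_km=3.0),
        )
        pred = fld.predict_many(lonlat[:100])
        assert pred == pytest.approx(z[:100], abs=1e-6)

    def test_constant_field_reproduced_everywhere(self, scatter_400):
        fld = KrigedField(
            "c", scatter_400[:60], np.full(60, 7.5),
            variogram=VariogramModel(nugget=0.0, partial_sill=1.0, range_km=3.0),
        )
        q = scatter_400[300:340]
        assert fld.predict_many(q) == pytest.approx(np.full(40, 7.5), abs=1e-8)

    def test_linear_trend_recovered_by_drift(self, scatter_400):
        z = 2.0 * scatter_400[:, 0] + 3.0 * scatter_400[:, 1] + 1.0
        fld = KrigedField(
            "plane", scatter_400[:120], z[:120],
            variogram=VariogramModel(nugget=0.0, partial_sill=1.0, range_km=2.0),
        )
        held = scatter_400[200:260]
        truth = 2.0 * held[:, 0] + 3.0 * held[:, 1] + 1.0
        assert np.abs(fld.predict_many(held) - truth).max() < 1e-3

    def test_prediction_is_continuous(self, smooth_field):
        lonlat, z = smooth_field
        fld = KrigedField("f", lonlat[:150], z[:150])
        p0 = fld.predict(-84.52, 33.66)
        deltas = [1e-3, 1e-4, 1e-5, 1e-6, 1e-7]
        diffs = [abs(fld.predict(-84.52 + d, 33.66 + d) - p0) for d in deltas]
        assert diffs == sorted(diffs, reverse=True) or max(diffs) < 1e-9
        assert diffs[-1] < 1e-4

    def test_beats_nearest_neighbor_on_heldout_smooth_field(self, smooth_field):
        from foodscape.geodata_io import haversine_km_matrix

        lonlat, z = smooth_field
        train, test = slice(0, 250), slice(250, 400)
        fld = KrigedField("f", lonlat[train], z[train])
        pred = fld.predict_many(lonlat[test])
        rmse_k = np.sqrt(np.mean((pred - z[test]) ** 2))
        nn = haversine_km_matrix(lonlat[test], lonlat[train]).argmin(axis=1)
        rmse_nn = np.sqrt(np.mean((z[train][nn] - z[test]) ** 2))
        assert rmse_k < rmse_nn

    def test_serialization_roundtrip(self, smooth_field):
        lonlat, z = smooth_field
        fld = KrigedField(
            "f", lonlat[:40], z[:40],
            variogram=VariogramModel(nugget=0.05, partial_sill=0.9, range_km=2.5),
        )
        clone = KrigedField.from_dict(fld.to_dict())
        q = lonlat[300:320]
        assert clone.predict_many(q) == pytest.approx(fld.predict_many(q), abs=1e-12)
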