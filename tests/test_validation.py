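"""Suitability surface, quantile bins, Boyce, ROC, density regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from rsfscape import (
    CovariateStack,
    SuitabilitySurface,
    boyce_index,
    build_smoothed_stack,
    density_regression,
    predict_surface,
    quantile_bins,
    raster_correlation,
    roc_from_scores,
    roc_metrics,
)
from rsfscape.model import INTERCEPT, FittedRSF
from rsfscape.scaling import column_key

from conftest import make_grid


def make_fit(beta, standardization, covariates=None, scale_km=None):
    covs = covariates or [c for c in beta if c != INTERCEPT]
    return FittedRSF(
        covariates=covs,
        beta=beta,
        se={},
        z={},
        p={},
        sigma2_id=0.0,
        loglik=0.0,
        k=len(covs) + 2,
        n=100,
        aicc=0.0,
        converged=True,
        standardization=standardization,
        scale_km=scale_km or {},
    )


def surface_from(values, n_bins=10):
    grid = make_grid(values.shape[0])
    return SuitabilitySurface(
        grid=grid, values=values, bins=quantile_bins(values, n_bins), n_bins=n_bins
    )


class TestQuantileBins:
    def test_values_1_to_100(self):
        vals = np.arange(1.0, 101.0).reshape(10, 10)
        bins = quantile_bins(vals, 10)
        assert set(vals[bins == 10]) == set(range(91, 101))
        assert set(vals[bins == 1]) == set(range(1, 11))

    def test_constant_degenerate_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            bins = quantile_bins(np.full((5, 5), 2.0), 10)
        assert set(bins.ravel()) == {1}

    def test_equal_counts_on_random_raster(self):
        rng = np.random.default_rng(0)
        vals = rng.standard_normal((100, 100))
        bins = quantile_bins(vals, 10)
        counts = np.bincount(bins.ravel(), minlength=11)[1:]
        assert (counts == 1000).all()  # continuous values: no ties

    def test_ties_go_to_lower_bin(self):
        vals = np.array([[1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]])
        bins = quantile_bins(vals, 5)
        assert (bins[0][:3] == 1).all()  # tied run collapsed downward

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            quantile_bins(np.arange(5.0).reshape(1, 5), 10)

    def test_nodata_gets_bin_zero(self):
        vals = np.arange(100.0).reshape(10, 10)
        vals[0, 0] = np.nan
        bins = quantile_bins(vals, 10)
        assert bins[0, 0] == 0 and (bins[bins > 0] >= 1).all()


class TestPredictSurface:
    def _smoothed(self, layer, scale=2.0, name="c"):
        grid = make_grid(layer.shape[0])
        stack = CovariateStack(grid=grid, layers={name: layer})
        sm = build_smoothed_stack(stack, (scale,))
        return sm

    def test_null_model_is_half(self):
        rng = np.random.default_rng(1)
        sm = self._smoothed(rng.standard_normal((40, 40)))
        fit = make_fit({INTERCEPT: 0.0, column_key("c", 2.0): 0.0},
                       {column_key("c", 2.0): (0.0, 1.0)})
        surf = predict_surface(fit, sm)
        valid = np.isfinite(surf.values)
        np.testing.assert_allclose(surf.values[valid], 0.5, atol=1e-12)

    def test_monotone_in_covariate(self):
        rng = np.random.default_rng(2)
        sm = self._smoothed(rng.standard_normal((40, 40)))
        fit = make_fit({INTERCEPT: 0.1, column_key("c", 2.0): 1.3},
                       {column_key("c", 2.0): (0.0, 1.0)})
        surf = predict_surface(fit, sm)
        z = sm.layers[("c", 2.0)]
        valid = np.isfinite(surf.values)
        order = np.argsort(z[valid])
        assert (np.diff(surf.values[valid][order]) >= 0).all()

    def test_cellwise_oracle(self):
        """Agreement with per-cell scalar recomputation on a 20x20 grid."""
        rng = np.random.default_rng(3)
        layer = rng.standard_normal((20, 20))
        sm = self._smoothed(layer, scale=0.5)
        mu, sd = 0.2, 1.4
        b0, b1 = -0.3, 0.8
        fit = make_fit({INTERCEPT: b0, column_key("c", 0.5): b1},
                       {column_key("c", 0.5): (mu, sd)})
        surf = predict_surface(fit, sm)
        z = sm.layers[("c", 0.5)]
        for i in range(20):
            for j in range(20):
                if np.isfinite(z[i, j]):
                    expected = expit(b0 + b1 * (z[i, j] - mu) / sd)
                    assert abs(surf.values[i, j] - expected) <= 1e-10

    def test_missing_layer_rejected(self):
        sm = self._smoothed(np.zeros((20, 20)))
        fit = make_fit({INTERCEPT: 0.0, column_key("other", 4.0): 1.0},
                       {column_key("other", 4.0): (0.0, 1.0)})
        with pytest.raises(ValueError, match="other"):
            predict_surface(fit, sm)


class TestBoyce:
    def _surface(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return surface_from(rng.uniform(size=(n, n)))

    def _points_in_bins(self, surface, counts):
        """Place counts[b] evaluation points in cells of bin b+1."""
        xs, ys = surface.grid.center_grids()
        pts = []
        for b, c in enumerate(counts, start=1):
            ii, jj = np.nonzero(surface.bins == b)
            pts.append(np.column_stack([xs[ii[:c], jj[:c]], ys[ii[:c], jj[:c]]]))
        return np.vstack(pts)

    def test_rank_proportional_counts_give_one(self):
        surf = self._surface()
        pts = self._points_in_bins(surf, [10 * i for i in range(1, 11)])
        res = boyce_index(surf, pts)
        assert res.index == pytest.approx(1.0)
        np.testing.assert_allclose(res.predicted.sum(), 1.0, atol=1e-12)
        np.testing.assert_allclose(res.expected.sum(), 1.0, atol=1e-12)

    def test_reversed_counts_give_minus_one(self):
        surf = self._surface()
        pts = self._points_in_bins(surf, [10 * (11 - i) for i in range(1, 11)])
        assert boyce_index(surf, pts).index == pytest.approx(-1.0)

    def test_null_mean_near_zero(self):
        """Uniform evaluation points: mean Boyce within 0.15 of 0 (100 draws)."""
        surf = self._surface(seed=5)
        xs, ys = surf.grid.center_grids()
        rng = np.random.default_rng(6)
        vals = []
        for _ in range(100):
            k = rng.integers(0, xs.size, size=200)
            pts = np.column_stack([xs.ravel()[k], ys.ravel()[k]])
            vals.append(boyce_index(surf, pts).index)
        assert abs(np.mean(vals)) < 0.15
        assert np.max(np.abs(vals)) <= 1.0

    def test_rank_invariance_under_monotone_transform(self):
        surf = self._surface(seed=7)
        transformed = surface_from(np.exp(3 * surf.values))
        rng = np.random.default_rng(8)
        xs, ys = surf.grid.center_grids()
        k = rng.integers(0, xs.size, size=500)
        pts = np.column_stack([xs.ravel()[k], ys.ravel()[k]])
        a = boyce_index(surf, pts).index
        b = boyce_index(transformed, pts).index
        assert a == pytest.approx(b, abs=1e-12)

    def test_all_points_off_grid_rejected(self):
        surf = self._surface()
        with pytest.raises(ValueError):
            boyce_index(surf, np.array([[1e9, 1e9]]))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        labels = np.concatenate([np.zeros(50), np.ones(50)])
        res = roc_from_scores(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert res.sensitivity == pytest.approx(1.0)
        assert res.specificity == pytest.approx(1.0)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(100):
            scores = rng.uniform(size=2000)
            labels = rng.integers(0, 2, size=2000)
            aucs.append(roc_from_scores(scores, labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_auc_equals_mann_whitney(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal(20)
        labels = np.array([1] * 8 + [0] * 12)
        res = roc_from_scores(scores, labels)
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res.auc == pytest.approx(u / (8 * 12), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores(np.arange(5.0), np.ones(5))

    def test_surface_wrapper(self):
        surf = surface_from(np.random.default_rng(3).uniform(size=(30, 30)))
        xs, ys = surf.grid.center_grids()
        labelled = pd.DataFrame(
            {
                "x": xs.ravel()[:100],
                "y": ys.ravel()[:100],
                "label": np.tile([0, 1], 50),
            }
        )
        res = roc_metrics(surf, labelled)
        assert 0.0 <= res.auc <= 1.0


class TestDensityRegression:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(4)
        surf = surface_from(rng.uniform(size=(60, 60)))
        xs, ys = surf.grid.center_grids()
        pts = pd.DataFrame({"x": xs[15:20, 15:40:5].ravel(), "y": ys[15:20, 15:40:5].ravel()})
        r_m = np.sqrt(100.0 / np.pi) * 1000
        means = []
        for x, y in zip(pts["x"], pts["y"]):
            sel = (xs - x) ** 2 + (ys - y) ** 2 <= r_m**2
            means.append(surf.values[sel].mean())
        pts["density"] = 2.0 + 3.0 * np.asarray(means)
        res = density_regression(surf, pts)
        assert res.slope == pytest.approx(3.0, abs=1e-8)
        assert res.intercept == pytest.approx(2.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-8)

    def test_buffer_area_is_100_km2(self):
        from shapely.geometry import Point

        from rsfscape.validation import DENSITY_BUFFER_RADIUS_KM

        buf = Point(0, 0).buffer(DENSITY_BUFFER_RADIUS_KM * 1000, quad_segs=64)
        assert buf.area / 1e6 == pytest.approx(100.0, rel=0.01)

    def test_zero_variance_predictor_rejected(self):
        surf = SuitabilitySurface(
            grid=make_grid(30),
            values=np.full((30, 30), 0.5),
            bins=np.ones((30, 30), dtype=int),
        )
        pts = pd.DataFrame(
            {"x": [5000.0, 7000.0, 9000.0], "y": [5000.0, 7000.0, 9000.0], "density": [1.0, 2.0, 3.0]}
        )
        with pytest.raises(ValueError, match="variance"):
            density_regression(surf, pts)


class TestRasterCorrelation:
    def test_self_and_negation(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((20, 20))
        assert raster_correlation(a, a) == pytest.approx(1.0)
        assert raster_correlation(a, -a) == pytest.approx(-1.0)

    def test_independent_fields_near_zero(self):
        rng = np.random.default_rng(6)
        vals = [
            raster_correlation(rng.standard_normal((30, 30)), rng.standard_normal((30, 30)))
            for _ in range(50)
        ]
        assert abs(np.mean(vals)) < 0.05

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            raster_correlation(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_respects_joint_validity(self):
        a = np.arange(9.0).reshape(3, 3)
        b = a.copy()
        a[0, 0] = np.nan
        b[2, 2] = np.nan
        assert raster_correlation(a, b) == pytest.approx(1.0)
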