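"""Feature extraction, encoding models, RF maps and Gaussian summaries."""

import numpy as np
import pandas as pd
import pytest

import gazerf as gz
from gazerf.rfmap import (
    FIXATION_GRID,
    RF_GRID,
    RFModelConfig,
    extract_patch_features,
    fit_gaussian_rf,
    fit_response_model,
    get_extractor,
    map_rf,
    normalize_performance,
    offset_feature_stack,
    offset_grid,
    rf_consistency,
    saccade_rf_timecourse,
)


class TestExtractors:
    def test_uniform_image_gives_identical_cells(self):
        images = {"gray": np.full((128, 128), 0.5)}
        for name in ("gabor-bank", "random-projection"):
            grids = extract_patch_features(images, RF_GRID, get_extractor(name))
            F = grids["gray"].features
            assert np.allclose(F, F[0, 0])

    def test_cache_determinism(self):
        images, _ = gz.make_image_set(2, seed=5)
        a = extract_patch_features(images, RF_GRID, get_extractor("gabor-bank"))
        b = extract_patch_features(images, RF_GRID, get_extractor("gabor-bank"))
        for k in images:
            assert np.array_equal(a[k].features, b[k].features)

    def test_nearest_cell_matches_exhaustive_search(self, rng):
        images, _ = gz.make_image_set(1, seed=5)
        g = extract_patch_features(images, RF_GRID, get_extractor("random-projection"))["img000"]
        xs = rng.uniform(-14, 14, 500)
        ys = rng.uniform(-14, 14, 500)
        iy, ix = g.nearest_index(xs, ys)
        for k in range(0, 500, 7):
            dx = np.abs(g.x_centers - xs[k])
            dy = np.abs(g.y_centers - ys[k])
            assert dx[ix[k]] <= dx.min() + 1e-9
            assert dy[iy[k]] <= dy.min() + 1e-9

    def test_unknown_extractor_rejected(self):
        with pytest.raises(KeyError):
            get_extractor("vgg-features")


class TestResponseModel:
    def _design(self, rng, n=500):
        images, _ = gz.make_image_set(10, seed=1)
        grids = extract_patch_features(images, FIXATION_GRID, get_extractor("gabor-bank"))
        ids = rng.choice(sorted(images), n)
        x = rng.uniform(-7, 7, n)
        y = rng.uniform(-7, 7, n)
        X = np.stack([grids[i].features_at(np.array([a]), np.array([b]))[0]
                      for i, a, b in zip(ids, x, y)])
        return X, ids

    def test_realizable_target_fits_perfectly(self, rng):
        X, ids = self._design(rng)
        w = rng.standard_normal(X.shape[1])
        resp = X @ w
        res = fit_response_model(X, resp, ids, RFModelConfig(alpha=10.0))
        assert res["performance"] >= 0.99
        # the default (heavier) regularization still fits well
        res_default = fit_response_model(X, resp, ids)
        assert res_default["performance"] >= 0.6

    def test_shuffled_labels_near_zero(self, rng):
        X, ids = self._design(rng)
        resp = rng.permutation(X @ rng.standard_normal(X.shape[1]))
        res = fit_response_model(X, resp, ids)
        assert abs(res["performance"]) < 0.2

    def test_grouped_cv_never_leaks_images(self, rng):
        X, ids = self._design(rng, n=200)
        res = fit_response_model(X, X[:, 0], ids)
        folds = res["folds"]
        for k in np.unique(folds):
            assert not (set(ids[folds == k]) & set(ids[folds != k]))

    def test_fewer_images_than_folds_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        ids = np.array(["a", "b"] * 10)
        with pytest.raises(ValueError):
            fit_response_model(X, X[:, 0], ids)


class TestNormalizePerformance:
    @pytest.mark.parametrize("rm,rsc,expect,excluded", [
        (0.3, 0.6, 0.25, False),
        (0.7, 0.6, 1.0, False),   # clip at 1 before squaring
        (0.3, 0.0, None, True),
        (0.3, -0.2, None, True),
    ])
    def test_values(self, rm, rsc, expect, excluded):
        val, exc = normalize_performance(rm, rsc)
        assert exc is excluded
        if expect is not None:
            assert np.isclose(val, expect)

    def test_monotone_in_model_performance(self):
        vals = [normalize_performance(r, 0.8)[0] for r in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestGaussianFits:
    def test_unit_circular_gaussian_fwhm(self):
        ox, oy = offset_grid()
        X, Y = np.meshgrid(ox, oy)
        surface = np.exp(-(X**2 + Y**2) / (2 * 2.0))  # sd sqrt(2): squares to sd 1
        g = fit_gaussian_rf(surface, ox, oy)
        assert np.isclose(g.a, 1.0, atol=0.01) and np.isclose(g.b, 1.0, atol=0.01)
        assert np.isclose(g.fwhm, 2.355, atol=0.01)

    def test_known_elliptical_gaussian_recovered(self):
        ox, oy = offset_grid()
        X, Y = np.meshgrid(ox, oy)
        th = 0.6
        u = (X - 1.0) * np.cos(th) + (Y + 2.0) * np.sin(th)
        v = -(X - 1.0) * np.sin(th) + (Y + 2.0) * np.cos(th)
        Z = 0.5 * np.exp(-(u**2 / (2 * 2.0**2) + v**2 / (2 * 1.0**2)))
        g = fit_gaussian_rf(Z, ox, oy, preprocess=False)
        assert np.hypot(g.center_x - 1.0, g.center_y + 2.0) < 0.25
        assert abs(g.a - 2.0) / 2.0 < 0.1 and abs(g.b - 1.0) < 0.1

    def test_off_window_gaussian_has_partial_coverage(self):
        ox, oy = offset_grid()
        X, Y = np.meshgrid(ox, oy)
        Z = np.exp(-(((X - 6) ** 2 + (Y - 6) ** 2) / (2 * 3.0**2)))
        g = fit_gaussian_rf(Z, ox, oy, preprocess=False)
        # numeric oracle: integrate the normalized axis-aligned density
        # inside the window (the fit here is effectively axis-aligned)
        ax = np.linspace(-7, 7, 281)
        GX, GY = np.meshgrid(ax, ax)
        dens = np.exp(-(((GX - g.center_x) ** 2) / (2 * g.a**2)
                        + ((GY - g.center_y) ** 2) / (2 * g.b**2)))
        dens /= 2 * np.pi * g.a * g.b
        oracle = dens.sum() * (ax[1] - ax[0]) ** 2
        assert g.coverage < 0.9
        assert np.isclose(g.coverage, oracle, atol=0.05)


class TestRFRecoveryChain:
    def test_map_peak_and_null_calibration(self, bench, rng):
        """Foveal ground truth peaks at the grid center; shuffles stay in the null band."""
        fx = bench.valid_fixations
        ox, oy = offset_grid()
        stack = offset_feature_stack(bench.grids, fx["image_id"].to_numpy(),
                                     fx["x"].to_numpy(), fx["y"].to_numpy(), ox, oy)
        u = bench.session.unit_ids[0]  # ground-truth RF at (0, 0)
        resp = bench.source.window_rates(u, fx["onset"].to_numpy(), 40.0, 190.0)
        m = map_rf(stack, resp, fx["image_id"].to_numpy())
        mm = m.mean_map()
        iy, ix = np.unravel_index(np.nanargmax(mm), mm.shape)
        assert np.hypot(ox[ix], oy[iy]) <= 1.0
        # response-shuffled control: no offset beats the shuffled-null 99th pct
        ok = np.isfinite(resp)
        null_peaks = []
        for _ in range(3):
            m0 = map_rf(stack[ok], rng.permutation(resp[ok]), fx["image_id"].to_numpy()[ok])
            null_peaks.append(np.nanmax(np.abs(m0.mean_map())))
        assert np.nanmax(mm) > max(null_peaks)

    def test_cross_split_evidence_exceeds_shuffled(self, bench, rng):
        fx = bench.valid_fixations
        ox, oy = offset_grid()
        stack = offset_feature_stack(bench.grids, fx["image_id"].to_numpy(),
                                     fx["x"].to_numpy(), fx["y"].to_numpy(), ox, oy)
        u = bench.session.unit_ids[2]
        resp = bench.source.window_rates(u, fx["onset"].to_numpy(), 40.0, 190.0)
        ok = np.isfinite(resp)
        ev = rf_consistency(map_rf(stack[ok], resp[ok], fx["image_id"].to_numpy()[ok]))
        ev0 = rf_consistency(map_rf(stack[ok], rng.permutation(resp[ok]),
                                    fx["image_id"].to_numpy()[ok]))
        assert ev > 0.5
        assert ev > ev0 + 0.2


class TestSaccadeAnchors:
    def test_fp1_fp2_midpoint_structure(self, lagged100):
        """FP1 evidence dominates before, FP2 after lag + saccade duration."""
        se = lagged100.endpoints.reset_index(drop=True)
        u = lagged100.session.unit_ids[0]
        bins = gz.BinSpec(-150, 250, 50, 50)  # coarse bins keep this test fast
        binned = lagged100.source.binned(u, se["onset"].to_numpy(), bins)
        cfg = RFModelConfig(offset_extent=5.0)
        ev = saccade_rf_timecourse(lagged100.grids, se, binned, cfg)
        c = bins.centers
        pre = c < 0
        post = c > 150
        assert np.nanmean(ev["fp1"][pre]) > np.nanmean(ev["fp2"][pre]) + 0.2
        assert np.nanmean(ev["fp2"][post]) > np.nanmean(ev["fp1"][post]) + 0.2
        both = np.maximum(ev["fp1"], ev["fp2"])
        assert np.all(ev["midpoint"] <= both + 0.15)

    def test_unknown_anchor_rejected(self, lagged100):
        se = lagged100.endpoints.reset_index(drop=True)
        with pytest.raises(ValueError, match="anchor"):
            saccade_rf_timecourse(lagged100.grids, se, np.zeros((len(se), 1)),
                                  anchors=("fp3",))


class TestAdjustMatchFit:
    def test_identity_when_curves_match(self):
        t = np.linspace(0, 1, 31)
        out = gz.adjust_match_fit(t, t, t * 0.5)
        assert np.isclose(out["slope"], 1.0) and np.isclose(out["intercept"], 0.0)
        assert np.allclose(out["adjusted_rf2"], t * 0.5)

    def test_constructed_scaling_recovered(self):
        t = np.linspace(0.1, 0.9, 31)
        out = gz.adjust_match_fit(t, 0.8 * t, 0.8 * t + 0.0)
        assert np.isclose(out["slope"], 1.25)
        assert np.allclose(out["adjusted_rf2"], t)

    def test_degenerate_fit_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            gz.adjust_match_fit(np.ones(5), np.ones(5), np.ones(5))
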