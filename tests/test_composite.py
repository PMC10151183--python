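"""Rasterisation, pixel-wise correlation, territories, spatial PCA and the
per-score regression — each against an independent brute-force oracle."""

import numpy as np
import pytest

from dsdkit.composite import (
    RasterConfig,
    correlation_map,
    extract_territories,
    fit_composite,
    fit_score_model,
    pca_scores,
    predict_score,
    rasterize_coordinate,
    spatial_pca,
)
from dsdkit.errors import (
    ConfigurationError,
    DegenerateDataError,
    NoTerritoryError,
)
from dsdkit.types import ScoreTable

from conftest import make_locmaps


class TestRasterConfig:
    def test_defaults_match_standard_geometry(self):
        cfg = RasterConfig()
        assert cfg.grid_size == 260
        assert cfg.pixel_size == 0.05
        assert cfg.sigma_pixels == pytest.approx(20.0)  # 1 mm kernel

    def test_grid_too_small_for_kernel_rejected(self):
        with pytest.raises(ConfigurationError, match="8"):
            RasterConfig(grid_size=100, pixel_size=0.05, smoothing_sigma=1.0)


class TestRasterize:
    def test_probability_mass_sums_to_one(self):
        rg = RasterConfig().fit()
        for coord in ([3.0, 7.0], [0.3, 12.5], [6.2, 6.2]):
            lm = rasterize_coordinate(np.array(coord), rg)
            assert lm.grid.sum() == pytest.approx(1.0, abs=1e-9)
            assert lm.grid.min() >= 0

    def test_argmax_at_coordinate_pixel(self):
        """Peak pixel = floor(coord / pixel_size) in direct-mm mode, matching
        a directly evaluated discretised Gaussian."""
        rg = RasterConfig().fit()
        coord = np.array([4.21, 9.87])
        lm = rasterize_coordinate(coord, rg)
        expected_pixel = tuple(np.floor(coord / 0.05).astype(int))
        assert lm.pixel == expected_pixel
        assert np.unravel_index(lm.grid.argmax(), lm.grid.shape) == expected_pixel
        # direct evaluation of the discretised Gaussian at a probe pixel
        ix, iy = expected_pixel
        probe = (ix + 7, iy - 5)
        d2 = ((probe[0] - ix) ** 2 + (probe[1] - iy) ** 2) / (20.0**2)
        ratio = lm.grid[probe] / lm.grid[expected_pixel]
        assert ratio == pytest.approx(np.exp(-0.5 * d2), rel=1e-9)

    def test_border_coordinate_clipped_with_warning(self):
        rg = RasterConfig().fit()
        with pytest.warns(UserWarning, match="clipped"):
            lm = rasterize_coordinate(np.array([99.0, 5.0]), rg)
        assert rg.clipped_count == 1
        assert lm.grid.sum() == pytest.approx(1.0, abs=1e-9)  # renormalised

    def test_autoscale_keeps_cohort_inside_window(self):
        coords = np.array([[0.0, 0.0], [40.0, 25.0], [13.0, 80.0]])
        rg = RasterConfig(mapping_mode="autoscale").fit(coords)
        pix = rg.to_pixel(coords)
        margin_px = int(3.0 / 0.05)  # 3 sigma in pixels
        assert pix.min() >= margin_px - 1
        assert pix.max() <= 260 - margin_px + 1
        assert rg.clipped_count == 0


class TestCorrelationMap:
    def test_score_equal_to_pixel_probability_gives_r_one(self):
        coords = np.array([[1.0, 1.0], [5.0, 2.0], [2.5, 6.0], [7.0, 7.0]])
        locmaps, rg = make_locmaps(coords)
        p = locmaps[0].pixel
        scores = np.array([lm.grid[p] for lm in locmaps])
        rmap = correlation_map(locmaps, scores)
        assert rmap.r[p] == pytest.approx(1.0)

    def test_matches_textbook_pearson_per_pixel(self):
        """4 patients, hand-set grids: every pixel equals the two-pass
        textbook Pearson formula."""
        rng = np.random.default_rng(3)
        coords = rng.uniform(1, 9, size=(4, 2))
        locmaps, rg = make_locmaps(coords, grid_size=64)
        scores = np.array([3.0, -1.0, 2.5, 10.0])
        rmap = correlation_map(locmaps, scores)
        X = np.stack([lm.grid for lm in locmaps])
        for pix in [(10, 12), (31, 40), (55, 5), tuple(locmaps[2].pixel)]:
            x = X[(slice(None), *pix)]
            if x.std() == 0:
                expected = 0.0
            else:
                xm, ym = x.mean(), scores.mean()
                expected = (
                    ((x - xm) * (scores - ym)).sum()
                    / np.sqrt(((x - xm) ** 2).sum() * ((scores - ym) ** 2).sum())
                )
            assert rmap.r[pix] == pytest.approx(expected, abs=1e-10)

    def test_constant_score_rejected(self):
        locmaps, _ = make_locmaps([[1.0, 1.0], [2.0, 5.0], [6.0, 3.0]])
        with pytest.raises(DegenerateDataError, match="no variance"):
            correlation_map(locmaps, np.array([4.0, 4.0, 4.0]))

    def test_permutation_null_smoke(self):
        """Permuting scores under a fixed seed yields a usable max-|r| null."""
        rng = np.random.default_rng(0)
        coords = rng.uniform(1, 9, size=(12, 2))
        locmaps, _ = make_locmaps(coords, grid_size=64)
        scores = coords[:, 0] + rng.normal(0, 0.5, 12)
        observed = np.abs(correlation_map(locmaps, scores).r).max()
        null = [
            np.abs(correlation_map(locmaps, rng.permutation(scores)).r).max()
            for _ in range(20)
        ]
        assert observed >= np.median(null)  # real signal beats typical null


class TestTerritories:
    def _rmap(self, r):
        from dsdkit.composite import CorrelationMap2D

        return CorrelationMap2D(r=r, n_patients=10)

    def test_all_subthreshold_is_an_error(self):
        r = np.full((40, 40), 0.1)
        with pytest.raises(NoTerritoryError, match="no informative territory"):
            extract_territories(self._rmap(r), np.array([[5, 5]]))

    def test_two_disjoint_blobs_found_by_flood_fill(self):
        r = np.zeros((40, 40))
        r[5:10, 5:10] = 0.5
        r[25:30, 25:30] = -0.5  # negative correlations count via |R|
        terr = extract_territories(
            self._rmap(r), np.array([[6, 6], [26, 26]]), threshold=0.2
        )
        assert terr.n_clusters_with_patients == 2
        assert terr.mask.sum() == 50
        # flood-fill oracle: the two blobs are the only components
        assert len(terr.kept_labels) == 2

    def test_component_without_patients_dropped(self):
        r = np.zeros((40, 40))
        r[5:10, 5:10] = 0.5
        r[25:30, 25:30] = 0.5
        terr = extract_territories(self._rmap(r), np.array([[6, 6]]))
        assert terr.n_clusters_with_patients == 1
        assert terr.mask.sum() == 25
        assert not terr.mask[26, 26]

    def test_more_than_three_keeps_most_populated(self):
        r = np.zeros((40, 40))
        blobs = [(2, 2), (2, 20), (20, 2), (20, 20)]
        for bx, by in blobs:
            r[bx : bx + 3, by : by + 3] = 0.4
        peaks = [[3, 3], [3, 3], [3, 21], [3, 21], [21, 3], [21, 21]]
        with pytest.warns(UserWarning, match="kept 3"):
            terr = extract_territories(self._rmap(r), np.array(peaks))
        assert terr.n_clusters_with_patients == 3
        assert terr.mask.sum() == 27  # 3 blobs of 9
        assert not terr.mask[21, 21]  # least-populated blob dropped

    def test_eight_connectivity_joins_diagonals(self):
        r = np.zeros((10, 10))
        r[2, 2] = 0.5
        r[3, 3] = 0.5  # diagonal neighbour -> one component
        terr = extract_territories(self._rmap(r), np.array([[2, 2]]))
        assert len(terr.kept_labels) == 1
        assert terr.mask.sum() == 2


class TestSpatialPCA:
    def _territory(self, shape, pixels):
        from dsdkit.composite import TerritoryMask

        mask = np.zeros(shape, dtype=bool)
        for p in pixels:
            mask[p] = True
        return TerritoryMask(mask=mask, labels=mask.astype(int),
                             kept_labels=[1], n_clusters_with_patients=1)

    def test_identical_maps_rejected(self):
        locmaps, _ = make_locmaps([[2.0, 2.0]] * 5)
        terr = self._territory((260, 260), [(40, 40), (41, 40), (42, 40)])
        with pytest.raises(DegenerateDataError, match="degenerate localization"):
            spatial_pca(locmaps, terr)

    def test_matches_dense_eigendecomposition(self):
        """4 patients x 3 pixels: components and variance ratios equal the
        eigendecomposition of the sample covariance (up to sign)."""
        rng = np.random.default_rng(5)
        coords = rng.uniform(1, 9, (4, 2))
        locmaps, _ = make_locmaps(coords, grid_size=64)
        terr = self._territory((64, 64), [(10, 10), (20, 30), (40, 12)])
        pca = spatial_pca(locmaps, terr, k=3)
        X = np.stack([lm.grid[terr.mask] for lm in locmaps])
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / (len(X) - 1)
        w, V = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        for i in range(3):
            v = V[:, i] * np.sign(V[np.argmax(np.abs(V[:, i])), i])
            c = pca.components[i]
            c = c * np.sign(c[np.argmax(np.abs(c))])
            np.testing.assert_allclose(np.abs(c @ v), 1.0, atol=1e-8)
        expected_ratios = np.maximum(w, 0) / np.maximum(w, 0).sum()
        np.testing.assert_allclose(pca.variance_ratios, expected_ratios,
                                   atol=1e-8)

    def test_orthonormal_components_sorted_ratios(self):
        rng = np.random.default_rng(8)
        coords = rng.uniform(1, 9, (15, 2))
        locmaps, _ = make_locmaps(coords, grid_size=64)
        terr = self._territory(
            (64, 64), [tuple(p) for p in rng.integers(5, 60, (30, 2))]
        )
        pca = spatial_pca(locmaps, terr, k=3)
        gram = pca.components @ pca.components.T
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
        assert np.all(np.diff(pca.variance_ratios) <= 1e-12)
        assert pca.variance_ratios.sum() <= 1.0 + 1e-12


class TestPcaScores:
    def _fixture(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(1, 9, (6, 2))
        locmaps, _ = make_locmaps(coords, grid_size=64)
        from dsdkit.composite import TerritoryMask

        mask = np.zeros((64, 64), dtype=bool)
        mask[10:14, 10:14] = True
        terr = TerritoryMask(mask, mask.astype(int), [1], 1)
        return locmaps, spatial_pca(locmaps, terr, k=3)

    def test_training_mean_projects_to_zero(self):
        locmaps, pca = self._fixture()
        mean_map = locmaps[0]
        grid = np.zeros_like(mean_map.grid)
        grid[pca.mask] = pca.mean
        from dsdkit.composite import LocalizationMap

        lm = LocalizationMap(grid=grid, patient_id="mean", pixel=(0, 0))
        np.testing.assert_allclose(pca_scores(lm, pca), 0.0, atol=1e-12)

    def test_mean_plus_component_projects_to_unit(self):
        locmaps, pca = self._fixture()
        grid = np.zeros((64, 64))
        grid[pca.mask] = pca.mean + pca.components[0]
        from dsdkit.composite import LocalizationMap

        lm = LocalizationMap(grid=grid, patient_id="c1", pixel=(0, 0))
        np.testing.assert_allclose(pca_scores(lm, pca), [1.0, 0.0, 0.0],
                                   atol=1e-10)

    def test_matches_hand_matrix_product(self):
        locmaps, pca = self._fixture()
        lm = locmaps[3]
        expected = pca.components @ (lm.grid[pca.mask] - pca.mean)
        np.testing.assert_allclose(pca_scores(lm, pca), expected, atol=1e-12)


class TestScoreRegression:
    def test_exact_linear_recovery_via_normal_equations(self):
        rng = np.random.default_rng(1)
        S = rng.standard_normal((12, 3))
        y = 2.0 + 3.0 * S[:, 0] - 1.0 * S[:, 1] + 0.0 * S[:, 2]
        model = fit_score_model(S, y, "exact")
        # normal-equations oracle
        X = np.column_stack([np.ones(12), S])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(model.weights, beta[1:], atol=1e-8)
        np.testing.assert_allclose(model.weights, [3.0, -1.0, 0.0], atol=1e-8)
        assert model.r2_train == pytest.approx(1.0)

    def test_saturated_n4_refused_by_precondition(self):
        S = np.eye(4)[:, :3]
        with pytest.raises(ConfigurationError, match=">= 5"):
            fit_score_model(S, np.arange(4.0))

    def test_collinear_predictors_min_norm_with_warning(self):
        rng = np.random.default_rng(4)
        s1 = rng.standard_normal(8)
        S = np.column_stack([s1, s1, s1])  # rank 1
        y = 1.0 + s1
        with pytest.warns(UserWarning, match="collinear"):
            model = fit_score_model(S, y)
        pred = predict_score(model, S)
        np.testing.assert_allclose(pred, y, atol=1e-8)

    def test_predict_arithmetic_and_clipping(self):
        from dsdkit.composite import ScoreModel

        m = ScoreModel("s", intercept=1.0, weights=np.array([2.0, 0.0, 0.0]),
                       n_train=10, r2_train=1.0)
        assert predict_score(m, np.array([3.0, 9.0, -4.0])) == pytest.approx(7.0)
        m0 = ScoreModel("s", intercept=5.0, weights=np.zeros(3), n_train=10,
                        r2_train=0.0)
        assert predict_score(m0, np.array([1.0, 2.0, 3.0])) == pytest.approx(5.0)
        low = ScoreModel("s", intercept=-5.0, weights=np.zeros(3), n_train=10,
                         r2_train=0.0)
        assert predict_score(low, np.zeros(3), clip_range=(0.0, 20.0)) == 0.0


class TestCompositeFit:
    def _cohort(self, seed, n=24):
        """Locmap cohort with one coordinate-driven score and one noise score."""
        rng = np.random.default_rng(seed)
        centers = np.array([[2.0, 2.0], [8.0, 8.0]])
        labels = rng.integers(0, 2, n)
        coords = centers[labels] + 0.4 * rng.standard_normal((n, 2))
        locmaps, rg = make_locmaps(coords, grid_size=128)
        planted = 20.0 + 30.0 * labels + rng.normal(0, 2.0, n)
        noise = rng.normal(50.0, 10.0, n)
        table = ScoreTable(
            patient_ids=[f"p{i}" for i in range(n)],
            score_names=["planted", "noise"],
            values=np.column_stack([planted, noise]),
            max_scale=np.array([100.0, 100.0]),
        )
        return locmaps, table, rg

    def test_planted_score_modeled_and_deterministic(self):
        locmaps, table, rg = self._cohort(0)
        res1 = fit_composite(locmaps, table, rg)
        res2 = fit_composite(locmaps, table, rg)
        assert "planted" in res1.score_fits
        assert res1.score_fits["planted"].model.r2_train > 0.8
        assert len(res1.score_fits) <= len(table.score_names)
        np.testing.assert_array_equal(
            res1.score_fits["planted"].model.weights,
            res2.score_fits["planted"].model.weights,
        )

    def test_noise_scores_flagged_more_often_than_planted(self):
        """Over 20 seeds, territory extraction fails for pure-noise scores
        more often than for coordinate-driven scores."""
        import warnings as _w

        planted_flags = noise_flags = 0
        for seed in range(20):
            locmaps, table, rg = self._cohort(seed, n=14)
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                res = fit_composite(locmaps, table, rg)
            planted_flags += "planted" in res.unmodelable
            noise_flags += "noise" in res.unmodelable
        assert noise_flags > planted_flags

    def test_predictions_round_trip_through_bundle(self, tmp_path):
        """save -> load reproduces predictions bit-identically."""
        from dsdkit.io import load_model_bundle, save_model_bundle

        locmaps, table, rg = self._cohort(1)
        res = fit_composite(locmaps, table, rg)
        pred1 = res.predict_from_locmaps(locmaps)
        path = save_model_bundle(tmp_path / "model.zip", results=res)
        back = load_model_bundle(path).results
        pred2 = back.predict_from_locmaps(locmaps)
        assert (pred1.to_numpy() == pred2.to_numpy()).all()

    def test_summary_mentions_modeled_and_unmodelable(self):
        locmaps, table, rg = self._cohort(2)
        res = fit_composite(locmaps, table, rg)
        text = res.summary()
        assert "planted" in text
        assert "modeled scores" in text
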