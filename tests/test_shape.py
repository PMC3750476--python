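import numpy as np
import pytest

from mamle import (
    FeatureVector,
    ShapeModel,
    fit_shape_model,
    log_likelihood,
    mahalanobis_D,
    region_features,
)


def disk_mask(radius, pad=2):
    ext = radius + pad
    yy, xx = np.mgrid[-ext:ext + 1, -ext:ext + 1]
    return (yy**2 + xx**2 <= radius**2).astype(np.int32)


class TestRegionFeatures:
    def test_disk_closed_form(self):
        mask = disk_mask(10)
        feat = region_features(mask, 1)
        assert feat.area == pytest.approx(np.pi * 100, rel=0.05)
        # equivalent-ellipse axes of a disk: 4*sqrt(r^2/4) = 2r
        assert feat.major == pytest.approx(20.0, rel=0.05)
        assert feat.minor == pytest.approx(20.0, rel=0.05)

    def test_rectangle_second_moments(self):
        mask = np.zeros((20, 40), dtype=np.int32)
        mask[5:15, 5:35] = 1  # 10 x 30 solid rectangle
        feat = region_features(mask, 1)
        assert feat.major == pytest.approx(4 * np.sqrt(30**2 / 12), rel=0.02)
        assert feat.minor == pytest.approx(4 * np.sqrt(10**2 / 12), rel=0.02)
        assert feat.area == 300

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        blob = (rng.random((15, 25)) > 0.4).astype(np.int32)
        blob[7, 12] = 1
        f0 = region_features(blob, 1)
        f90 = region_features(np.rot90(blob).copy(), 1)
        assert f0.area == f90.area
        assert f0.major == pytest.approx(f90.major, abs=1e-9)
        assert f0.minor == pytest.approx(f90.minor, abs=1e-9)

    def test_tiny_region_rejected(self):
        mask = np.zeros((16, 16), dtype=np.int32)
        mask[3, 3:7] = 1  # 4 pixels
        with pytest.raises(ValueError):
            region_features(mask, 1)


class TestFitShapeModel:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        mu_true = np.array([250.0, 30.0, 10.0])
        a = np.array([[30.0, 2.0, 1.0], [2.0, 4.0, 0.5], [1.0, 0.5, 1.0]])
        sigma_true = a @ a.T
        x = rng.multivariate_normal(mu_true, sigma_true, size=1000)
        model = fit_shape_model(x, trim_fraction=0.0)
        assert np.linalg.norm(model.mu - mu_true) / np.linalg.norm(mu_true) < 0.10
        assert (
            np.linalg.norm(model.sigma - sigma_true) / np.linalg.norm(sigma_true) < 0.10
        )

    def test_identical_features_degenerate(self):
        feats = [FeatureVector(100.0, 20.0, 8.0)] * 20
        model = fit_shape_model(feats)
        np.testing.assert_allclose(model.mu, [100.0, 20.0, 8.0])
        # covariance collapses to the ridge floor but stays invertible
        assert np.all(np.linalg.eigvalsh(model.sigma) > 0)

    def test_too_few_objects(self):
        feats = [FeatureVector(100.0, 20.0, 8.0)] * 9
        with pytest.raises(ValueError, match="review"):
            fit_shape_model(feats)

    def test_trimming_excludes_oversized(self):
        rng = np.random.default_rng(1)
        good = rng.multivariate_normal([200, 25, 9], np.diag([100, 4, 1]), size=100)
        contaminated = np.vstack([good, [[900, 60, 15]] * 10])
        model = fit_shape_model(contaminated, max_cell_area=450)
        assert model.mu[0] < 250

    def test_json_roundtrip(self, tmp_path):
        model = fit_shape_model(
            np.random.default_rng(2).normal([200, 25, 9], [10, 2, 1], (50, 3)),
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ShapeModel.from_json(path)
        np.testing.assert_allclose(back.mu, model.mu)
        np.testing.assert_allclose(back.sigma, model.sigma)
        assert back.n == model.n


class TestMahalanobis:
    def test_zero_at_mean(self, rod_model):
        assert mahalanobis_D(rod_model.mu, rod_model) == pytest.approx(0.0, abs=1e-9)

    def test_euclidean_case(self):
        model = ShapeModel(mu=np.zeros(3), sigma=np.eye(3), n=10)
        assert mahalanobis_D(np.array([3.0, 4.0, 0.0]), model) == pytest.approx(25.0)

    def test_matches_solve_and_dot(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(3, 3))
        sigma = a @ a.T + 0.5 * np.eye(3)
        mu = rng.normal(size=3)
        model = ShapeModel(mu=mu, sigma=sigma, n=10)
        for _ in range(20):
            x = rng.normal(size=3)
            expected = (x - mu) @ np.linalg.solve(sigma, x - mu)
            assert mahalanobis_D(x, model) == pytest.approx(expected, rel=1e-9)

    def test_nonnegative_and_affine_invariant(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(3, 3))
        sigma = a @ a.T + 0.5 * np.eye(3)
        mu = rng.normal(size=3)
        model = ShapeModel(mu=mu, sigma=sigma, n=10)
        t = rng.normal(size=(3, 3)) + 2 * np.eye(3)  # invertible reparameterization
        model_t = ShapeModel(mu=t @ mu, sigma=t @ sigma @ t.T, n=10)
        for _ in range(10):
            x = rng.normal(size=3)
            d = mahalanobis_D(x, model)
            assert d >= 0
            assert mahalanobis_D(t @ x, model_t) == pytest.approx(d, rel=1e-6)

    def test_likelihood_ranking_matches_negative_D(self, rod_model):
        rng = np.random.default_rng(5)
        xs = [rod_model.mu + rng.normal(scale=20, size=3) for _ in range(15)]
        by_ll = sorted(range(15), key=lambda i: -log_likelihood(xs[i], rod_model))
        by_d = sorted(range(15), key=lambda i: mahalanobis_D(xs[i], rod_model))
        assert by_ll == by_d

    def test_mean_bias_shrinks_with_n(self):
        mu_true = np.array([250.0, 30.0, 10.0])
        sigma_true = np.diag([400.0, 16.0, 1.0])
        errs = []
        for n in (100, 1000):
            rng = np.random.default_rng(6)
            x = rng.multivariate_normal(mu_true, sigma_true, size=n)
            model = fit_shape_model(x, trim_fraction=0.0)
            errs.append(np.linalg.norm(model.mu - mu_true))
        assert errs[1] < errs[0]
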