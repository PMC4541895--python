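import numpy as np
import pytest

from gaitmon.pca import (
    PCAModel,
    Standardizer,
    fit_pca,
    mean_vector,
    principal_axes,
    projection_matrix,
    scatter_matrix,
)


@pytest.fixture(scope="module")
def random_dataset():
    rng = np.random.default_rng(21)
    # anisotropic Gaussian so the spectrum is well spread
    A = rng.normal(size=(37, 37))
    return rng.normal(size=(400, 37)) @ A + rng.uniform(-5, 5, 37)


class TestMeanAndScatter:
    def test_mean_of_identical_samples(self):
        v = np.arange(37, dtype=float)
        X = np.tile(v, (10, 1))
        np.testing.assert_allclose(mean_vector(X), v)

    def test_mean_of_two_samples(self):
        a, b = np.zeros(5), np.ones(5)
        np.testing.assert_allclose(mean_vector(np.vstack([a, b])), 0.5 * np.ones(5))

    def test_mean_matches_accumulate_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            X = rng.normal(size=(rng.integers(1, 30), 6))
            acc = np.zeros(6)
            for row in X:
                acc += row
            np.testing.assert_allclose(mean_vector(X), acc / len(X), atol=1e-12)

    def test_identical_samples_give_zero_scatter(self):
        X = np.tile(np.arange(5.0), (8, 1))
        np.testing.assert_allclose(scatter_matrix(X), 0.0, atol=1e-12)

    def test_scatter_is_n_times_population_covariance(self, random_dataset):
        X = random_dataset
        S = scatter_matrix(X)
        np.testing.assert_allclose(S, len(X) * np.cov(X.T, ddof=0), rtol=1e-9)

    def test_scatter_symmetry(self, random_dataset):
        S = scatter_matrix(random_dataset)
        np.testing.assert_allclose(S, S.T)

    def test_errors_on_degenerate_inputs(self):
        with pytest.raises(ValueError):
            mean_vector(np.empty((0, 3)))
        with pytest.raises(ValueError):
            scatter_matrix(np.ones((1, 3)))


class TestPrincipalAxes:
    def test_axis_aligned_variance(self):
        X = np.zeros((20, 2))
        X[:, 0] = np.linspace(-3, 3, 20)
        eigvals, eigvecs = principal_axes(scatter_matrix(X))
        np.testing.assert_allclose(np.abs(eigvecs[:, 0]), [1.0, 0.0], atol=1e-12)
        assert eigvals[1] == pytest.approx(0.0, abs=1e-9)

    def test_eigenvalue_sum_equals_trace(self, random_dataset):
        S = scatter_matrix(random_dataset)
        eigvals, _ = principal_axes(S)
        assert eigvals.sum() == pytest.approx(np.trace(S), rel=1e-10)

    def test_eigenpairs_satisfy_defining_property(self, random_dataset):
        S = scatter_matrix(random_dataset)
        eigvals, eigvecs = principal_axes(S)
        for k in range(S.shape[0]):
            np.testing.assert_allclose(
                S @ eigvecs[:, k],
                eigvals[k] * eigvecs[:, k],
                atol=1e-8 * max(1.0, eigvals[0]),
            )

    def test_descending_order_and_orthonormality(self, random_dataset):
        eigvals, eigvecs = principal_axes(scatter_matrix(random_dataset))
        assert np.all(np.diff(eigvals) <= 1e-9)
        np.testing.assert_allclose(eigvecs.T @ eigvecs, np.eye(37), atol=1e-9)

    def test_sign_convention_is_deterministic(self, random_dataset):
        _, v1 = principal_axes(scatter_matrix(random_dataset))
        _, v2 = principal_axes(scatter_matrix(random_dataset))
        np.testing.assert_array_equal(v1, v2)
        for k in range(v1.shape[1]):
            assert v1[np.argmax(np.abs(v1[:, k])), k] > 0

    def test_rejects_non_symmetric_matrix(self):
        with pytest.raises(ValueError):
            principal_axes(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_matches_sklearn_principal_directions(self, random_dataset):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = random_dataset
        _, eigvecs = principal_axes(scatter_matrix(X))
        ref = sklearn.PCA(n_components=10).fit(X)
        for k in range(10):
            dot = abs(ref.components_[k] @ eigvecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-6)


class TestProjection:
    def test_full_basis_is_square_orthonormal(self, random_dataset):
        _, eigvecs = principal_axes(scatter_matrix(random_dataset))
        W = projection_matrix(eigvecs, 37)
        assert W.shape == (37, 37)
        np.testing.assert_allclose(W.T @ W, np.eye(37), atol=1e-9)

    def test_operating_point_shape_and_unit_columns(self, random_dataset):
        model = fit_pca(random_dataset, 22)
        assert model.components.shape == (37, 22)
        np.testing.assert_allclose(
            np.linalg.norm(model.components, axis=0), 1.0, atol=1e-9
        )

    def test_component_count_bounds(self, random_dataset):
        _, eigvecs = principal_axes(scatter_matrix(random_dataset))
        for bad in (0, 38):
            with pytest.raises(ValueError):
                projection_matrix(eigvecs, bad)

    def test_mean_projects_to_zero(self, random_dataset):
        model = fit_pca(random_dataset, 22)
        np.testing.assert_allclose(model.project(model.mean), 0.0, atol=1e-9)

    def test_full_projection_is_isometry(self, random_dataset):
        X = random_dataset[:50]
        model = fit_pca(random_dataset, 37)
        Y = model.project(X)
        for i in range(0, 50, 7):
            for j in range(0, 50, 11):
                dx = np.linalg.norm(X[i] - X[j])
                dy = np.linalg.norm(Y[i] - Y[j])
                assert dy == pytest.approx(dx, rel=1e-8, abs=1e-8)

    def test_reconstruction_error_non_increasing_in_components(self, random_dataset):
        X = random_dataset
        errors = []
        for I in (5, 10, 20, 30, 37):
            model = fit_pca(X, I)
            Y = model.project(X)
            recon = Y @ model.components.T + model.mean
            errors.append(np.sum((X - recon) ** 2))
        assert all(a >= b - 1e-6 for a, b in zip(errors, errors[1:]))

    def test_retained_variance_equals_top_eigenvalues(self, random_dataset):
        X = random_dataset
        for I in (5, 22):
            model = fit_pca(X, I)
            Y = model.project(X)
            S_proj = scatter_matrix(Y)
            assert np.trace(S_proj) == pytest.approx(
                model.eigenvalues[:I].sum(), rel=1e-9
            )

    def test_uncentered_variant_differs_by_constant_shift(self, random_dataset):
        X = random_dataset[:20]
        centered = fit_pca(random_dataset, 10, center=True)
        literal = fit_pca(random_dataset, 10, center=False)
        shift = literal.project(X) - centered.project(X)
        np.testing.assert_allclose(shift - shift[0], 0.0, atol=1e-9)

    def test_dimension_mismatch_raises(self, random_dataset):
        model = fit_pca(random_dataset, 5)
        with pytest.raises(ValueError):
            model.project(np.zeros(12))

    def test_json_round_trip(self, tmp_path, random_dataset):
        model = fit_pca(random_dataset, 8)
        path = tmp_path / "pca.json"
        model.to_json(path)
        back = PCAModel.from_json(path)
        np.testing.assert_allclose(
            back.project(random_dataset[:5]), model.project(random_dataset[:5])
        )


class TestStandardizer:
    def test_zero_mean_unit_scale(self, random_dataset):
        scaler = Standardizer.fit(random_dataset)
        Z = scaler.transform(random_dataset)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        X = np.ones((10, 3))
        X[:, 1] = np.arange(10)
        Z = Standardizer.fit(X).transform(X)
        np.testing.assert_allclose(Z[:, 0], 0.0)
        np.testing.assert_allclose(Z[:, 2], 0.0)
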