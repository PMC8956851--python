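"""Unit and property tests for scatter matrices and the discriminant solve."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdfl import compute_scatter, fit_layer, project, sigmoid_activate
from sdfl.core import auto_ridge
from sdfl.dataset import DegenerateClassError, ValidationError

from conftest import (
    brute_force_scatter,
    random_labeled_dataset,
    rayleigh_quotient,
)


class TestComputeScatter:
    def test_golden_two_class_square(self, toy_two_class):
        """Four points in a square: scatters match hand summation."""
        pair = compute_scatter(toy_two_class.features, toy_two_class.labels)
        np.testing.assert_allclose(pair.class_means, [[1, 0], [1, 2]])
        np.testing.assert_allclose(pair.total_mean, [1, 1])
        np.testing.assert_allclose(pair.sigma_intra, [[4, 0], [0, 0]])
        np.testing.assert_allclose(pair.sigma_inter, [[0, 0], [0, 4]])

    def test_single_class_has_zero_between_scatter(self, rng):
        X = rng.standard_normal((10, 3))
        pair = compute_scatter(X, np.ones(10, dtype=int))
        np.testing.assert_allclose(pair.sigma_inter, 0.0)

    def test_singleton_classes_have_zero_within_scatter(self, rng):
        X = rng.standard_normal((4, 3))
        pair = compute_scatter(X, np.array([1, 2, 3, 4]))
        np.testing.assert_allclose(pair.sigma_intra, 0.0)

    @pytest.mark.parametrize("weighting", ["count", "uniform"])
    def test_matches_per_sample_loop_oracle(self, rng, weighting):
        data = random_labeled_dataset(rng, 4, 5, 12)
        pair = compute_scatter(
            data.features, data.labels, between_class_weighting=weighting
        )
        s_w, s_b = brute_force_scatter(data.features, data.labels)
        np.testing.assert_allclose(pair.sigma_intra, s_w, rtol=1e-10, atol=1e-10)
        if weighting == "count":
            np.testing.assert_allclose(pair.sigma_inter, s_b, rtol=1e-10, atol=1e-10)

    @given(
        seed=st.integers(0, 10_000),
        n_classes=st.integers(2, 6),
        dim=st.integers(2, 10),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_conservation_identity(self, seed, n_classes, dim):
        """Within + between scatter equals the total scatter."""
        data = random_labeled_dataset(
            np.random.default_rng(seed), n_classes, dim, n_per_class=8
        )
        pair = compute_scatter(data.features, data.labels)
        centred = data.features - data.features.mean(axis=0)
        total = centred.T @ centred
        scale = max(np.abs(total).max(), 1.0)
        np.testing.assert_allclose(
            pair.sigma_intra + pair.sigma_inter, total, rtol=0, atol=1e-8 * scale
        )

    def test_scatter_matrices_are_psd(self, gaussian_six_class):
        pair = compute_scatter(gaussian_six_class.features, gaussian_six_class.labels)
        for m in (pair.sigma_intra, pair.sigma_inter):
            smallest = np.linalg.eigvalsh(m).min()
            assert smallest >= -1e-8 * np.trace(m) / m.shape[0]

    def test_missing_class_raises(self, rng):
        X = rng.standard_normal((6, 2))
        with pytest.raises(DegenerateClassError, match="degenerate class"):
            compute_scatter(X, np.array([1, 1, 3, 3, 3, 1]))

    def test_non_finite_input_raises(self):
        X = np.array([[0.0, np.nan], [1.0, 2.0]])
        with pytest.raises(ValidationError):
            compute_scatter(X, np.array([1, 2]))


class TestFitLayer:
    def test_output_shape_is_input_dim_by_c_minus_1(self, rng):
        data = random_labeled_dataset(rng, 6, 12, 10)
        layer = fit_layer(data.features, data.labels)
        assert layer.mapping.shape == (12, 5)
        assert layer.eigenvalues.shape == (5,)

    def test_identical_classes_give_zero_eigenvalues(self, rng):
        X = rng.standard_normal((10, 4))
        stacked = np.vstack([X, X])
        labels = np.concatenate([np.ones(10), np.full(10, 2)]).astype(int)
        layer = fit_layer(stacked, labels, n_components=1)
        assert abs(layer.eigenvalues[0]) < 1e-10

    def test_two_class_direction_matches_closed_form(self, rng):
        """Leading direction parallel to S_w^-1 (mu1 - mu2)."""
        mu1, mu2 = np.array([0.0, 0.0]), np.array([5.0, 1.0])
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        chol = np.linalg.cholesky(cov)
        n = 300
        X = np.vstack(
            [mu1 + rng.standard_normal((n, 2)) @ chol.T,
             mu2 + rng.standard_normal((n, 2)) @ chol.T]
        )
        y = np.concatenate([np.ones(n), np.full(n, 2)]).astype(int)
        layer = fit_layer(X, y, ridge=0.0)
        s_w, _ = brute_force_scatter(X, y)
        closed = np.linalg.solve(s_w, X[y == 1].mean(0) - X[y == 2].mean(0))
        closed /= np.linalg.norm(closed)
        cosine = abs(closed @ layer.mapping[:, 0])
        assert cosine >= 0.999

    def test_two_class_direction_beats_fine_grid(self, rng):
        """No unit direction on a 0.1-degree grid has a larger Rayleigh quotient."""
        data = random_labeled_dataset(rng, 2, 2, 40, separation=4.0)
        layer = fit_layer(data.features, data.labels, ridge=0.0)
        s_w, s_b = brute_force_scatter(data.features, data.labels)
        angles = np.deg2rad(np.arange(0.0, 180.0, 0.1))
        grid_best = max(
            rayleigh_quotient(np.array([np.cos(a), np.sin(a)]), s_b, s_w)
            for a in angles
        )
        fitted = rayleigh_quotient(layer.mapping[:, 0], s_b, s_w)
        assert fitted >= grid_best - 1e-6 * abs(grid_best)

    def test_rayleigh_optimality_over_random_directions(self, rng):
        data = random_labeled_dataset(rng, 3, 6, 15)
        layer = fit_layer(data.features, data.labels, ridge=0.0)
        s_w, s_b = brute_force_scatter(data.features, data.labels)
        best = rayleigh_quotient(layer.mapping[:, 0], s_b, s_w)
        directions = rng.standard_normal((1000, 6))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        quotients = [rayleigh_quotient(v, s_b, s_w) for v in directions]
        assert best >= max(quotients)

    def test_eigen_identity_residual(self, gaussian_six_class):
        """Each column solves the generalized eigenproblem to tight residual."""
        data = gaussian_six_class
        layer = fit_layer(data.features, data.labels)
        pair = compute_scatter(data.features, data.labels)
        lhs = pair.sigma_inter @ layer.mapping
        regularized = pair.sigma_intra + layer.ridge * np.eye(layer.input_dim)
        rhs = regularized @ layer.mapping * layer.eigenvalues
        for col in range(layer.n_components):
            residual = np.linalg.norm(lhs[:, col] - rhs[:, col])
            assert residual <= 1e-6 * np.linalg.norm(lhs[:, col])

    def test_column_norms_order_and_sign(self, gaussian_six_class):
        layer = fit_layer(gaussian_six_class.features, gaussian_six_class.labels)
        np.testing.assert_allclose(np.linalg.norm(layer.mapping, axis=0), 1.0)
        assert np.all(np.diff(layer.eigenvalues) <= 1e-12)
        assert np.all(layer.eigenvalues >= -1e-8)
        peaks = np.argmax(np.abs(layer.mapping), axis=0)
        assert np.all(layer.mapping[peaks, np.arange(layer.n_components)] > 0)

    def test_permutation_invariance(self, rng, gaussian_six_class):
        data = gaussian_six_class
        layer = fit_layer(data.features, data.labels)
        perm = rng.permutation(data.n_samples)
        shuffled = fit_layer(data.features[perm], data.labels[perm])
        # summation order changes round-off, not the learned subspace
        np.testing.assert_allclose(
            shuffled.mapping, layer.mapping, rtol=0, atol=1e-8
        )

    def test_scale_equivariance_of_separability(self, gaussian_six_class):
        """Scaling all features by c leaves the Rayleigh spectrum unchanged."""
        data = gaussian_six_class
        base = fit_layer(data.features, data.labels)
        scaled = fit_layer(7.5 * data.features, data.labels)
        np.testing.assert_allclose(
            scaled.eigenvalues, base.eigenvalues, rtol=1e-8
        )

    def test_too_many_components_rejected(self, gaussian_six_class):
        with pytest.raises(ValidationError, match="n_components"):
            fit_layer(gaussian_six_class.features, gaussian_six_class.labels,
                      n_components=6)

    def test_negative_ridge_rejected(self, gaussian_six_class):
        with pytest.raises(ValidationError, match="ridge"):
            fit_layer(gaussian_six_class.features, gaussian_six_class.labels,
                      ridge=-1.0)

    def test_singular_within_scatter_suggests_ridge(self, rng):
        X = rng.standard_normal((4, 3))  # singleton classes: S_w = 0
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_layer(X, np.array([1, 2, 3, 4]), ridge=0.0)

    def test_auto_ridge_rescues_singular_case(self, rng):
        X = rng.standard_normal((40, 30))  # n_per_class < d: rank-deficient S_w
        y = np.repeat([1, 2], 20)
        layer = fit_layer(X, y)  # auto ridge
        assert layer.ridge > 0
        assert np.all(np.isfinite(layer.mapping))

    def test_auto_ridge_scales_with_trace(self, rng):
        pair = compute_scatter(rng.standard_normal((20, 4)), np.repeat([1, 2], 10))
        expected = 1e-6 * np.trace(pair.sigma_intra) / 4
        assert auto_ridge(pair.sigma_intra) == pytest.approx(expected)


class TestProjectAndSigmoid:
    def test_zero_vector_projects_to_zero(self, gaussian_six_class):
        layer = fit_layer(gaussian_six_class.features, gaussian_six_class.labels)
        np.testing.assert_allclose(project(layer, np.zeros(layer.input_dim)), 0.0)

    def test_identity_mapping_on_1d_data(self, rng):
        X = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20)])[:, None]
        y = np.repeat([1, 2], 20)
        layer = fit_layer(X, y, ridge=0.0)
        np.testing.assert_allclose(layer.mapping, [[1.0]])
        np.testing.assert_allclose(project(layer, X), X)

    def test_midpoint_threshold_separates_well_separated_classes(self, rng):
        """10-sigma mean separation projects to two cleanly split clusters."""
        X = np.vstack(
            [rng.standard_normal((50, 3)),
             np.array([10.0, 0.0, 0.0]) + rng.standard_normal((50, 3))]
        )
        y = np.repeat([1, 2], 50)
        layer = fit_layer(X, y, n_components=1)
        proj = project(layer, X).ravel()
        midpoint = 0.5 * (proj[y == 1].mean() + proj[y == 2].mean())
        side = np.where(proj > midpoint, 1, 2)
        accuracy = max(np.mean(side == y), np.mean(side != y))
        assert accuracy == 1.0

    def test_dimension_mismatch_raises(self, gaussian_six_class):
        layer = fit_layer(gaussian_six_class.features, gaussian_six_class.labels)
        with pytest.raises(ValidationError, match="columns"):
            project(layer, np.zeros(layer.input_dim + 1))

    def test_sigmoid_fixed_points_and_symmetry(self, rng):
        assert sigmoid_activate(0.0) == 0.5
        x = rng.standard_normal(100)
        np.testing.assert_allclose(
            sigmoid_activate(x) + sigmoid_activate(-x), 1.0, rtol=0, atol=1e-15
        )

    def test_sigmoid_saturates_gracefully(self):
        out = sigmoid_activate(np.array([-50.0, 0.0, 50.0]))
        assert np.all(np.isfinite(out))
        np.testing.assert_allclose(out, [0.0, 0.5, 1.0], rtol=0, atol=1e-15)
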