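"""TV functional/gradient, weighted LS gradient, line search, image update."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from ctfr.geometry import AttenuationImage, Sinogram, default_grid, \
    make_geometry
from ctfr.projector import forward_project
from ctfr.pwls_tv import (
    TvConfig,
    pwls_tv_step,
    pwls_tv_update,
    step_size,
    tv_coefficient,
    tv_gradient,
    tv_value,
    wls_gradient,
)
from ctfr.simulate import StatisticalWeights, identity_weights

from conftest import dense_matrix


class TestTvValue:
    def test_constant_image(self):
        """All differences vanish: 81 interior terms of sqrt(alpha)."""
        img = np.full((10, 10), 3.7)
        assert tv_value(img, 1e-8) == pytest.approx(81e-4, rel=1e-12)

    def test_hand_evaluated_2x2(self):
        """[[0,1],[0,1]]: one term, vertical diff 0, horizontal diff 1."""
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert tv_value(img, 0.0) == pytest.approx(1.0, abs=1e-15)

    def test_shift_invariance(self, rng):
        img = rng.standard_normal((12, 9))
        assert tv_value(img + 5.3, 1e-8) == pytest.approx(
            tv_value(img, 1e-8), rel=1e-12)

    def test_lower_bound_attained_only_by_constants(self, rng):
        alpha = 1e-8
        n_terms = 9 * 9
        flat = np.full((10, 10), 0.5)
        assert tv_value(flat, alpha) == pytest.approx(
            n_terms * math.sqrt(alpha))
        bumpy = flat.copy()
        bumpy[4, 4] += 1e-3
        assert tv_value(bumpy, alpha) > n_terms * math.sqrt(alpha)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            tv_value(np.zeros((1, 5)), 1e-8)


class TestTvGradient:
    def test_constant_image_zero_gradient(self):
        g = tv_gradient(np.full((8, 8), 1.0), 1e-8)
        assert np.max(np.abs(g)) <= 1e-12

    @pytest.mark.parametrize("boundary", ["crop", "neumann"])
    def test_matches_finite_differences(self, rng, boundary):
        """Analytic gradient vs central differences on 50 random 8x8
        images, max abs error <= 1e-5."""
        h = 1e-7
        for _ in range(50):
            img = rng.standard_normal((8, 8))
            grad = tv_gradient(img, 1e-8, boundary)
            fd = np.zeros_like(img)
            for i in range(8):
                for j in range(8):
                    up = img.copy(); up[i, j] += h
                    dn = img.copy(); dn[i, j] -= h
                    fd[i, j] = (tv_value(up, 1e-8, boundary)
                                - tv_value(dn, 1e-8, boundary)) / (2 * h)
            assert np.max(np.abs(grad - fd)) <= 1e-5

    def test_zero_homogeneous_at_alpha_zero(self):
        """For alpha=0 and a strictly monotone image the gradient is
        invariant under positive scaling."""
        img = np.add.outer(np.arange(6.0), 2 * np.arange(6.0)) + 1.0
        g1 = tv_gradient(img, 0.0)
        g2 = tv_gradient(4.2 * img, 0.0)
        np.testing.assert_allclose(g1, g2, atol=1e-14)


class TestWlsGradient:
    def test_zero_residual_gives_zero_gradient(self, tiny_geometry,
                                               tiny_grid, rng):
        mu = AttenuationImage(tiny_grid, rng.random(tiny_grid.shape))
        y = forward_project(mu, tiny_geometry)
        H = wls_gradient(mu, y, identity_weights(tiny_geometry),
                         tiny_geometry)
        assert np.max(np.abs(H.values)) <= 1e-12

    def test_matches_dense_matrix_algebra(self, tiny_geometry, tiny_grid,
                                          rng):
        """H equals Gᵀ Σ⁻¹ (Gμ − y) computed with the explicit matrix."""
        G = dense_matrix(tiny_geometry, tiny_grid)
        mu_v = rng.random(tiny_grid.shape)
        y_v = rng.random((tiny_geometry.n_views, tiny_geometry.n_bins))
        var = rng.uniform(0.5, 2.0, y_v.shape)
        mu = AttenuationImage(tiny_grid, mu_v)
        H = wls_gradient(mu, Sinogram(tiny_geometry, y_v),
                         StatisticalWeights(var), tiny_geometry)
        expected = G.T @ ((G @ mu_v.ravel() - y_v.ravel()) / var.ravel())
        np.testing.assert_allclose(H.values.ravel(), expected,
                                   rtol=1e-10, atol=1e-12)

    def test_doubling_variances_halves_gradient(self, tiny_geometry,
                                                tiny_grid, rng):
        mu = AttenuationImage(tiny_grid, rng.random(tiny_grid.shape))
        y = Sinogram(tiny_geometry,
                     rng.random((tiny_geometry.n_views,
                                 tiny_geometry.n_bins)))
        var = np.ones(y.values.shape)
        h1 = wls_gradient(mu, y, StatisticalWeights(var), tiny_geometry)
        h2 = wls_gradient(mu, y, StatisticalWeights(2 * var), tiny_geometry)
        np.testing.assert_allclose(h2.values, 0.5 * h1.values, atol=1e-14)


class TestStepSize:
    def test_exact_line_search_against_scalar_minimizer(self, tiny_geometry,
                                                        tiny_grid, rng):
        """tau matches the 1-D minimizer of the weighted quadratic found
        by bounded scalar search, for identity and random diagonal Σ."""
        for trial in range(6):
            mu_v = rng.random(tiny_grid.shape)
            y_v = rng.random((tiny_geometry.n_views, tiny_geometry.n_bins))
            if trial % 2 == 0:
                var = np.ones(y_v.shape)
            else:
                var = rng.uniform(0.2, 5.0, y_v.shape)
            weights = StatisticalWeights(var)
            mu = AttenuationImage(tiny_grid, mu_v)
            y = Sinogram(tiny_geometry, y_v)
            H = wls_gradient(mu, y, weights, tiny_geometry)
            tau, converged = step_size(H, tiny_geometry, weights)
            assert not converged

            def cost(t):
                img = AttenuationImage(tiny_grid, mu_v - t * H.values)
                res = forward_project(img, tiny_geometry).values - y_v
                return 0.5 * np.sum(res * res / var)

            opt = minimize_scalar(cost, bounds=(0.0, 10 * tau),
                                  method="bounded",
                                  options={"xatol": tau * 1e-9})
            assert tau == pytest.approx(opt.x, rel=1e-6)

    def test_zero_gradient_flags_convergence(self, tiny_geometry, tiny_grid):
        H = AttenuationImage(tiny_grid, np.zeros(tiny_grid.shape))
        tau, converged = step_size(H, tiny_geometry,
                                   identity_weights(tiny_geometry))
        assert tau == 0.0
        assert converged

    def test_identity_like_problem_gives_unit_step(self):
        """When G acts as a scalar multiple of the identity along H, the
        exact step is 1/scale²·...: with unit weights and GH = H the step
        is exactly 1.  Emulated with a one-pixel grid and a single ray
        normalized to unit weight."""
        geom = make_geometry(
            n_views=1, angular_range=360.0, n_bins=1,
            source_to_detector=100.0, center_to_detector=40.0,
            detector_extent=2.0)
        # single pixel whose side equals 1 mm: the central ray crosses
        # exactly the pixel diameter -> G = [chord]; tau = 1/chord²
        from ctfr.geometry import ImageGrid
        grid = ImageGrid(1, 1, 1.0)
        H = AttenuationImage(grid, np.ones((1, 1)))
        gh = forward_project(H, geom).values[0, 0]
        tau, _ = step_size(H, geom, identity_weights(geom))
        assert tau == pytest.approx(1.0 / gh ** 2, rel=1e-12)


class TestUpdate:
    def test_fixed_point_at_zero_residual(self, tiny_geometry, tiny_grid,
                                          rng):
        mu = AttenuationImage(tiny_grid, rng.random(tiny_grid.shape))
        y = forward_project(mu, tiny_geometry)
        cfg = TvConfig(beta=0.0)
        out = pwls_tv_update(mu, y, identity_weights(tiny_geometry),
                             tiny_geometry, cfg)
        np.testing.assert_allclose(out.values, mu.values, atol=1e-12)

    def test_wls_cost_strictly_decreases(self, tiny_geometry, tiny_grid,
                                         rng):
        """beta=0 exact line search: the weighted data cost strictly
        decreases across 10 consecutive updates on a noisy problem."""
        truth = rng.random(tiny_grid.shape) * 0.02
        clean = forward_project(AttenuationImage(tiny_grid, truth),
                                tiny_geometry).values
        noisy = clean + rng.normal(0, 0.01, clean.shape)
        y = Sinogram(tiny_geometry, noisy)
        weights = identity_weights(tiny_geometry)
        cfg = TvConfig(beta=0.0)
        mu = AttenuationImage(tiny_grid, np.zeros(tiny_grid.shape))
        costs = []
        for n in range(11):
            mu, state = pwls_tv_step(mu, y, weights, tiny_geometry, cfg, n)
            costs.append(state.wls_cost)
        for prev, cur in zip(costs, costs[1:]):
            assert cur < prev

    def test_composition_consistency(self, tiny_geometry, tiny_grid, rng):
        """The update equals the hand-composition of its parts."""
        cfg = TvConfig()
        mu_v = rng.random(tiny_grid.shape)
        y = Sinogram(tiny_geometry,
                     rng.random((tiny_geometry.n_views,
                                 tiny_geometry.n_bins)))
        var = rng.uniform(0.5, 2.0, y.values.shape)
        weights = StatisticalWeights(var)
        mu = AttenuationImage(tiny_grid, mu_v)
        out = pwls_tv_update(mu, y, weights, tiny_geometry, cfg)
        H = wls_gradient(mu, y, weights, tiny_geometry)
        tau, _ = step_size(H, tiny_geometry, weights)
        g = tv_gradient(mu_v, cfg.alpha, cfg.boundary)
        coeff = tv_coefficient(cfg, tau, H.values, g)
        expected = mu_v - tau * H.values - coeff * g
        np.testing.assert_allclose(out.values, expected, atol=1e-14)

    def test_absolute_mode_uses_beta_verbatim(self, tiny_geometry,
                                              tiny_grid, rng):
        cfg = TvConfig(beta=0.25, tv_step_mode="absolute")
        mu_v = rng.random(tiny_grid.shape)
        y = Sinogram(tiny_geometry,
                     rng.random((tiny_geometry.n_views,
                                 tiny_geometry.n_bins)))
        weights = identity_weights(tiny_geometry)
        mu = AttenuationImage(tiny_grid, mu_v)
        out = pwls_tv_update(mu, y, weights, tiny_geometry, cfg)
        H = wls_gradient(mu, y, weights, tiny_geometry)
        tau, _ = step_size(H, tiny_geometry, weights)
        g = tv_gradient(mu_v, cfg.alpha, cfg.boundary)
        np.testing.assert_allclose(
            out.values, mu_v - tau * H.values - 0.25 * g, atol=1e-14)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TvConfig(alpha=0.0)
        with pytest.raises(ValueError):
            TvConfig(beta=-1.0)
        with pytest.raises(ValueError):
            TvConfig(tv_step_mode="adaptive")


class TestConvergenceOnDenseScan:
    def test_beats_fbp_dense_baseline(self):
        """Noise-free fully sampled scan, tiny TV weight: iterating from
        the FBP image reduces RMSE below the FBP baseline."""
        from ctfr.fbp import fbp_reconstruct
        from ctfr.pipeline import rmse
        from ctfr.simulate import analytic_sinogram, make_head_phantom

        geom = make_geometry(
            n_views=120, angular_range=360.0, n_bins=96,
            source_to_detector=100.0, center_to_detector=40.0,
            detector_extent=60.0)
        grid = default_grid(geom, 48)
        truth, phantom = make_head_phantom(grid)
        y = analytic_sinogram(phantom, geom)
        weights = identity_weights(geom)
        mu = fbp_reconstruct(y, geom, grid)
        fbp_err = rmse(mu, truth)
        cfg = TvConfig(beta=1e-6)
        for n in range(60):
            mu, _ = pwls_tv_step(mu, y, weights, geom, cfg, n)
        assert rmse(mu, truth) < fbp_err
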