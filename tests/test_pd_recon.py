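"""Operators, proximal maps, and the primal-dual solver."""

import numpy as np
import pytest

from perfct.pd_recon import (
    SYM_WEIGHTS,
    RegularizerConfig,
    _l1_iso,
    div3,
    grad3,
    objective_value,
    reconstruct,
    soft_threshold,
    svt,
    sym_grad,
    sym_grad_adjoint,
)
from perfct.projector import SinogramSeries, forward_project, system_matrix


class TestGradientOperators:
    def test_constant_series_has_zero_gradient(self):
        g = grad3(np.full((6, 6, 4), 3.7))
        np.testing.assert_array_equal(g, 0.0)

    def test_temporal_ramp(self):
        x = np.broadcast_to(np.arange(5.0), (6, 6, 5)).copy()
        g = grad3(x)
        np.testing.assert_array_equal(g[0], 0.0)
        np.testing.assert_array_equal(g[1], 0.0)
        np.testing.assert_array_equal(g[2][:, :, :-1], 1.0)
        np.testing.assert_array_equal(g[2][:, :, -1], 0.0)  # Neumann boundary

    def test_grad_div_adjoint_identity(self, rng):
        x = rng.standard_normal((8, 8, 3))
        p = rng.standard_normal((3, 8, 8, 3))
        for tw in (1.0, 0.5):
            lhs = np.sum(grad3(x, tw) * p)
            rhs = -np.sum(x * div3(p, tw))
            assert abs(lhs - rhs) <= 1e-9 * abs(lhs)

    def test_single_frame_warns_and_zeroes_temporal(self):
        with pytest.warns(UserWarning, match="single-frame"):
            g = grad3(np.random.default_rng(0).random((5, 5, 1)))
        np.testing.assert_array_equal(g[2], 0.0)


class TestSymmetricGradient:
    def test_constant_field_maps_to_zero(self):
        v = np.ones((3, 6, 6, 4))
        np.testing.assert_array_equal(sym_grad(v), 0.0)

    def test_weighted_adjoint_identity(self, rng):
        v = rng.standard_normal((3, 7, 7, 3))
        r = rng.standard_normal((6, 7, 7, 3))
        w = SYM_WEIGHTS.reshape(6, 1, 1, 1)
        lhs = np.sum(w * sym_grad(v) * r)
        rhs = np.sum(v * sym_grad_adjoint(r))
        assert abs(lhs - rhs) <= 1e-9 * abs(lhs)

    def test_affine_series_has_zero_tgv_cost(self):
        """E(grad3 of an affine-in-space, linear-in-time series) vanishes."""
        yy, xx = np.mgrid[0:8, 0:8].astype(float)
        t = np.arange(4.0)
        x = 1.0 + 2 * xx[:, :, None] - 3 * yy[:, :, None] + 0.5 * t
        v = grad3(x)
        # interior only: forward differences break affinity at the boundary
        ev = sym_grad(v)[:, 1:-2, 1:-2, 1:-2]
        np.testing.assert_allclose(ev, 0.0, atol=1e-12)


class TestProximalOperators:
    @pytest.mark.parametrize("z,t,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0)])
    def test_scalar_shrinkage(self, z, t, expected):
        assert soft_threshold(np.array(z), t) == pytest.approx(expected)

    def test_vector_magnitude_shrinkage(self):
        z = np.array([3.0, 4.0])
        np.testing.assert_allclose(soft_threshold(z, 5.0, axis=0), 0.0)
        out = soft_threshold(z, 2.5, axis=0)
        assert np.hypot(*out) == pytest.approx(2.5)
        np.testing.assert_allclose(out / np.hypot(*out), z / 5.0)

    def test_svt_diagonal_case(self):
        M = np.diag([3.0, 1.0])
        np.testing.assert_allclose(svt(M, 2.0), np.diag([1.0, 0.0]), atol=1e-12)

    def test_svt_zero_threshold_is_identity(self, rng):
        M = rng.standard_normal((6, 4))
        np.testing.assert_array_equal(svt(M, 0.0), M)

    def test_svt_nuclear_norm_matches_svd_oracle(self, rng):
        M = rng.standard_normal((6, 4))
        t = 0.7
        s = np.linalg.svd(M, compute_uv=False)
        expected = np.maximum(s - t, 0.0).sum()
        out_nn = np.linalg.svd(svt(M, t), compute_uv=False).sum()
        assert out_nn == pytest.approx(expected, abs=1e-10)

    def test_svt_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            svt(np.array([[np.inf, 0.0]]), 1.0)


class TestObjectiveValue:
    def test_zero_data_zero_objective(self, small_geometry):
        x = np.zeros((16, 16, 2))
        b = np.zeros((48, 32, 2))
        cfg = RegularizerConfig(method="tv", alpha=0.01)
        assert objective_value(x, b, small_geometry, cfg) == 0.0

    def test_constant_consistent_series_has_zero_tv_objective(self, small_geometry):
        x = np.full((16, 16, 2), 0.2)
        b = np.stack([forward_project(x[:, :, i], small_geometry) for i in range(2)], axis=2)
        cfg = RegularizerConfig(method="tv", alpha=0.01)
        val = objective_value(x, b, small_geometry, cfg)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_norm_evaluation(self, small_geometry, rng):
        """Brute-force data term + isotropic TV, coded separately."""
        x = rng.random((16, 16, 2)) * 0.1
        b = rng.random((48, 32, 2))
        cfg = RegularizerConfig(method="tv", alpha=0.004)
        A = system_matrix(small_geometry).toarray()
        An = np.linalg.norm(A, 2)
        resid = (A / An) @ x.reshape(-1, 2) - b.reshape(-1, 2) / An
        data = 0.5 * np.sum(resid**2)
        dx = np.diff(x, axis=1, append=x[:, -1:, :])
        dy = np.diff(x, axis=0, append=x[-1:, :, :])
        dt = np.diff(x, axis=2, append=x[:, :, -1:])
        tv = np.sqrt(dx**2 + dy**2 + dt**2).sum()
        expected = data + cfg.alpha * tv
        val = objective_value(x, b, small_geometry, cfg)
        assert val == pytest.approx(expected, rel=1e-6)


class TestReconstruct:
    def test_deterministic(self, small_geometry, rng):
        mu = rng.random((16, 16, 2)) * 0.2
        b = np.stack(
            [forward_project(mu[:, :, i], small_geometry) for i in range(2)],
            axis=2,
        )
        sino = SinogramSeries(data=b, geometry=small_geometry)
        cfg = RegularizerConfig(method="ltv", alpha=0.002, n_max=20)
        s1, _, _ = reconstruct(sino, small_geometry, cfg)
        s2, _, _ = reconstruct(sino, small_geometry, cfg)
        np.testing.assert_array_equal(s1.data, s2.data)

    def test_converged_flag_reflects_stopping_rule(self, small_geometry, rng):
        mu = rng.random((16, 16, 2)) * 0.2
        b = np.stack(
            [forward_project(mu[:, :, i], small_geometry) for i in range(2)],
            axis=2,
        )
        sino = SinogramSeries(data=b, geometry=small_geometry)
        cfg = RegularizerConfig(method="tv", alpha=1e-6, eps_tol=1e-3, n_max=500)
        _, _, report = reconstruct(sino, small_geometry, cfg)
        assert report.converged
        assert report.n_iters < 500
        assert report.relative_change_history[-1] < 1e-3
        # a cap of one iteration cannot satisfy the tolerance here
        cfg2 = RegularizerConfig(method="tv", alpha=1e-6, eps_tol=1e-12, n_max=1)
        _, _, r2 = reconstruct(sino, small_geometry, cfg2)
        assert not r2.converged and r2.n_iters == 1

    def test_unstable_steps_are_rescaled(self, small_geometry, rng):
        mu = rng.random((16, 16, 2)) * 0.2
        b = np.stack(
            [forward_project(mu[:, :, i], small_geometry) for i in range(2)],
            axis=2,
        )
        sino = SinogramSeries(data=b, geometry=small_geometry)
        cfg = RegularizerConfig(
            method="tgv", alpha1=0.002, sigma=5.0, tau=5.0, n_max=5
        )
        _, _, report = reconstruct(sino, small_geometry, cfg)
        assert report.sigma_eff < 5.0 and report.tau_eff < 5.0
        assert (
            report.sigma_eff * report.tau_eff * report.composite_norm**2
            <= 1.0
        )

    def test_ls_methods_return_decomposition(self, small_geometry, rng):
        mu = rng.random((16, 16, 2)) * 0.2
        b = np.stack(
            [forward_project(mu[:, :, i], small_geometry) for i in range(2)],
            axis=2,
        )
        sino = SinogramSeries(data=b, geometry=small_geometry)
        series, ls, _ = reconstruct(
            sino, small_geometry,
            RegularizerConfig(method="ltgv", alpha1=0.002, n_max=30),
        )
        assert ls is not None
        # L is an image (affine HU map), S a difference image (linear map),
        # so the HU-domain sum reproduces the reconstruction exactly
        np.testing.assert_allclose(
            ls.L.data + ls.S.data, series.data, atol=1e-9
        )

    def test_invalid_method_rejected(self):
        with pytest.raises(ValueError):
            RegularizerConfig(method="ridge")
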