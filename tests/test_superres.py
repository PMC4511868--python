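"""Forward/adjoint operators, BTV prior, and the MAP super-resolution solver."""

import numpy as np
import pytest

from hypersr import (MapImage, PSFModel, SRConfig, ShiftedMapSeries,
                     SuperResolution, apply_adjoint, apply_forward,
                     btv_penalty_gradient, choose_decimation, initial_estimate,
                     make_bar_target, raster_shift_grid, simulate_map_series,
                     solve_super_resolution)


def mirror_index(i, n):
    """Independent symmetric-boundary fold (explicit walk, no modular trick)."""
    while i < 0 or i >= n:
        if i < 0:
            i = -1 - i
        else:
            i = 2 * n - 1 - i
    return i


def dense_forward_matrix(ny, nx, k, kernel, sx, sy):
    """Materialized X @ H @ T for the oracle comparison, built row by row."""
    n = ny * nx
    T = np.zeros((n, n))
    for y in range(ny):
        for x in range(nx):
            T[y * nx + x, ((y + sy) % ny) * nx + (x + sx) % nx] = 1.0
    H = np.zeros((n, n))
    ky, kx = kernel.shape
    ry, rx = ky // 2, kx // 2
    for y in range(ny):
        for x in range(nx):
            for a in range(ky):
                for b in range(kx):
                    yy = mirror_index(y + a - ry, ny)
                    xx = mirror_index(x + b - rx, nx)
                    H[y * nx + x, yy * nx + xx] += kernel[a, b]
    X = np.zeros(((ny // k) * (nx // k), n))
    for yl in range(ny // k):
        for xl in range(nx // k):
            X[yl * (nx // k) + xl, (yl * k) * nx + xl * k] = 1.0
    return X @ H @ T


class TestChooseDecimation:
    @pytest.mark.parametrize("N,expected", [(100, 10), (25, 5), (1, 1),
                                            (2, 1), (99, 9), (101, 10)])
    def test_printed_and_boundary_cases(self, N, expected):
        assert choose_decimation(N) == expected

    def test_rule_property(self):
        for N in range(1, 200):
            k = choose_decimation(N)
            assert k * k <= N < (k + 1) * (k + 1)

    def test_invalid(self):
        with pytest.raises(ValueError):
            choose_decimation(0)


class TestForwardAdjoint:
    def test_identity_problem(self, rng):
        m = MapImage(rng.random((6, 6)), 1.0)
        out = apply_forward(m, (0.0, 0.0), PSFModel(kernel=np.ones((1, 1))), 1)
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_map_preserved(self, rng):
        m = MapImage(np.full((12, 12), 3.7), 0.5)
        out = apply_forward(m, (1.0, 0.5), PSFModel(fwhm=1.2), 3)
        np.testing.assert_allclose(out.values, 3.7, rtol=1e-12)
        assert out.values.shape == (4, 4)

    @pytest.mark.parametrize("shape,k,shift", [
        ((12, 12), 3, (2, 1)), ((20, 16), 4, (0, 3)), ((40, 40), 5, (3, 2)),
    ])
    def test_forward_matches_dense_operator(self, rng, shape, k, shift):
        psf = PSFModel(fwhm=0.9)
        pitch = 0.3
        kernel = psf.kernel_at(pitch)
        A = dense_forward_matrix(*shape, k, kernel, *shift)
        x = rng.standard_normal(shape)
        got = apply_forward(MapImage(x, pitch),
                            (shift[0] * pitch, shift[1] * pitch), psf, k)
        np.testing.assert_allclose(got.values.ravel(), A @ x.ravel(),
                                   atol=1e-12)

    @pytest.mark.parametrize("shape,k,shift", [
        ((12, 12), 3, (2, 1)), ((40, 40), 5, (3, 2)),
    ])
    def test_adjoint_matches_dense_transpose(self, rng, shape, k, shift):
        psf = PSFModel(fwhm=0.9)
        pitch = 0.3
        A = dense_forward_matrix(*shape, k, psf.kernel_at(pitch), *shift)
        y = rng.standard_normal((shape[0] // k, shape[1] // k))
        got = apply_adjoint(MapImage(y, pitch * k),
                            (shift[0] * pitch, shift[1] * pitch), psf, k)
        np.testing.assert_allclose(got.values.ravel(), A.T @ y.ravel(),
                                   atol=1e-12)

    def test_inner_product_adjoint_identity(self, rng):
        psf = PSFModel(fwhm=0.8)
        k, pitch = 3, 0.25
        for _ in range(20):
            x = rng.standard_normal((12, 9))
            y = rng.standard_normal((4, 3))
            fx = apply_forward(MapImage(x, pitch), (pitch, 2 * pitch), psf, k)
            ax = apply_adjoint(MapImage(y, pitch * k), (pitch, 2 * pitch), psf, k)
            assert abs(np.vdot(fx.values, y) - np.vdot(x, ax.values)) < 1e-10

    def test_decimation_adjoint_of_delta(self):
        lr = np.zeros((3, 3))
        lr[1, 2] = 1.0
        got = apply_adjoint(MapImage(lr, 2.0), (0.0, 0.0),
                            PSFModel(kernel=np.ones((1, 1))), 2)
        expected = np.zeros((6, 6))
        expected[2, 4] = 1.0
        np.testing.assert_array_equal(got.values, expected)

    def test_non_integer_shift_rejected(self, rng):
        m = MapImage(rng.random((6, 6)), 1.0)
        with pytest.raises(ValueError, match="integer"):
            apply_forward(m, (0.37, 0.0), PSFModel(fwhm=0.5), 2)

    def test_indivisible_dimensions_rejected(self, rng):
        m = MapImage(rng.random((7, 6)), 1.0)
        with pytest.raises(ValueError, match="divisible"):
            apply_forward(m, (0.0, 0.0), PSFModel(fwhm=0.5), 2)


class TestInitialEstimate:
    def test_single_frame_identity(self, rng):
        m = MapImage(rng.random((5, 5)), 1.0)
        s = ShiftedMapSeries([m], [(0.0, 0.0)], 1.0)
        np.testing.assert_array_equal(initial_estimate(s, 1).values, m.values)

    def test_constant_frames(self):
        maps = [MapImage(np.full((4, 4), 2.0), 1.0) for _ in range(4)]
        shifts = raster_shift_grid(2, 0.5)
        s = ShiftedMapSeries(maps, shifts, 1.0)
        np.testing.assert_allclose(initial_estimate(s, 2).values, 2.0)

    def test_matches_brute_force_accumulation(self, rng):
        k = 2
        maps = [MapImage(rng.random((3, 3)), 1.0) for _ in range(4)]
        shifts = raster_shift_grid(2, 0.5)
        s = ShiftedMapSeries(maps, shifts, 1.0)
        got = initial_estimate(s, k).values
        acc = np.zeros((6, 6))
        for m, (dx, dy) in zip(maps, shifts):
            up = np.zeros((6, 6))
            for y in range(6):
                for x in range(6):
                    up[y, x] = m.values[y // k, x // k]
            sy, sx = int(round(dy / 0.5)), int(round(dx / 0.5))
            rolled = np.zeros((6, 6))
            for y in range(6):
                for x in range(6):
                    rolled[(y + sy) % 6, (x + sx) % 6] = up[y, x]
            acc += rolled
        np.testing.assert_allclose(got, acc / 4.0, atol=1e-12)


class TestBTV:
    def test_constant_image_zero(self):
        pen, grad = btv_penalty_gradient(np.full((6, 6), 4.0), 0.7, 2)
        assert pen == 0.0
        np.testing.assert_array_equal(grad, 0.0)

    def test_radius_zero_empty_sum(self, rng):
        pen, grad = btv_penalty_gradient(rng.random((5, 5)), 0.7, 0)
        assert pen == 0.0
        np.testing.assert_array_equal(grad, 0.0)

    def test_gradient_matches_finite_differences(self, rng):
        vals = rng.random((8, 8))
        alpha, P = 0.7, 2
        _, grad = btv_penalty_gradient(vals, alpha, P)
        eps = 1e-6
        for i in range(8):
            for j in range(8):
                a = vals.copy()
                a[i, j] += eps
                b = vals.copy()
                b[i, j] -= eps
                num = (btv_penalty_gradient(a, alpha, P)[0]
                       - btv_penalty_gradient(b, alpha, P)[0]) / (2 * eps)
                assert abs(num - grad[i, j]) < 1e-5


class TestSeriesInvariants:
    def test_shift_must_be_sub_pixel(self, rng):
        maps = [MapImage(rng.random((4, 4)), 1.0) for _ in range(2)]
        with pytest.raises(ValueError, match="sub-pixel"):
            ShiftedMapSeries(maps, [(0.0, 0.0), (1.5, 0.0)], 1.0)

    def test_shift_must_sit_on_hr_grid(self, rng):
        maps = [MapImage(rng.random((4, 4)), 1.0) for _ in range(2)]
        s = ShiftedMapSeries(maps, [(0.0, 0.0), (0.3, 0.0)], 1.0)
        with pytest.raises(ValueError, match="integer multiple"):
            s.hr_shifts(k=2)
        assert tuple(s.hr_shifts(k=10)[1]) == (3, 0)

    def test_psf_validation(self):
        with pytest.raises(ValueError, match="exactly one"):
            PSFModel()
        with pytest.raises(ValueError, match="non-negative"):
            PSFModel(kernel=np.array([[1.0, -0.5]]))
        k = PSFModel(kernel=np.ones((3, 3))).kernel
        assert abs(k.sum() - 1.0) < 1e-15

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SRConfig(k=0)
        with pytest.raises(ValueError):
            SRConfig(alpha=1.5)


class TestSolver:
    def test_single_frame_identity_problem(self, rng):
        m = MapImage(rng.random((6, 6)), 1.0)
        s = ShiftedMapSeries([m], [(0.0, 0.0)], 1.0)
        res = solve_super_resolution(s, PSFModel(kernel=np.ones((1, 1))),
                                     SRConfig(k=1, lambda_reg=0.0))
        np.testing.assert_allclose(res.map.values, m.values, atol=1e-6)
        assert res.converged

    def test_output_geometry_at_paper_factors(self, rng):
        hr = MapImage(rng.random((16, 16)), 0.5)
        shifts = raster_shift_grid(2, 0.5)
        series = simulate_map_series(hr, shifts, PSFModel(fwhm=1.0), 2, 0.0, 0)
        res = solve_super_resolution(series, PSFModel(fwhm=1.0),
                                     SRConfig(k=2, n_iter=2))
        assert res.map.values.shape == (16, 16)
        assert abs(res.map.pixel_size - 0.5) < 1e-12

    def test_noiseless_bar_recovery_beats_initial_estimate(self):
        truth = make_bar_target(bar_width=3, n_bars=5, canvas=40, pixel_size=0.2)
        shifts = raster_shift_grid(5, 0.2)
        psf = PSFModel(fwhm=0.5)
        series = simulate_map_series(truth, shifts, psf, 5, 0.0, seed=3)
        res = solve_super_resolution(series, psf,
                                     SRConfig(k=5, lambda_reg=0.002, n_iter=80))
        init = initial_estimate(series, 5)

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        c_sr = corr(res.map.values, truth.values)
        c_init = corr(init.values, truth.values)
        assert c_sr >= 0.95
        assert c_sr > c_init

    def test_objective_trace_non_increasing(self):
        truth = make_bar_target(bar_width=2, n_bars=3, canvas=20, pixel_size=0.5)
        shifts = raster_shift_grid(2, 0.5)
        psf = PSFModel(fwhm=1.0)
        series = simulate_map_series(truth, shifts, psf, 2, 0.0, seed=0)
        res = solve_super_resolution(series, psf, SRConfig(k=2, n_iter=30))
        assert np.all(np.diff(res.objective_trace) <= 1e-12)

    def test_translation_equivariance_full_pixel_offset(self, rng):
        hr = MapImage(rng.random((12, 12)), 0.5)
        psf = PSFModel(fwhm=0.8)
        shifts = raster_shift_grid(2, 0.5)
        series = simulate_map_series(hr, shifts, psf, 2, 0.0, 0)
        res_a = solve_super_resolution(series, psf,
                                       SRConfig(k=2, lambda_reg=0.0, n_iter=15))
        offset = shifts + 1.0  # one full LR pixel
        series_b = ShiftedMapSeries(series.maps, offset, 1.0, strict=False)
        res_b = solve_super_resolution(series_b, psf,
                                       SRConfig(k=2, lambda_reg=0.0, n_iter=15))
        np.testing.assert_allclose(res_b.map.values,
                                   np.roll(res_a.map.values, (2, 2), (0, 1)),
                                   atol=1e-9)


class TestSuperResolutionEstimator:
    def test_auto_factor_and_attributes(self):
        truth = make_bar_target(bar_width=2, n_bars=3, canvas=20, pixel_size=0.5)
        shifts = raster_shift_grid(2, 0.5)
        psf = PSFModel(fwhm=1.0)
        series = simulate_map_series(truth, shifts, psf, 2, 0.0, seed=0)
        est = SuperResolution(psf_fwhm=1.0, n_iter=5).fit(series)
        assert est.k_ == 2  # floor(sqrt(4))
        assert est.map_.values.shape == (20, 20)
        assert len(est.objective_trace_) >= 1
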