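import numpy as np
import pytest

from flockmetrics.correlation import (
    correct_and_normalize,
    correlation_over_window,
    fit_correlation_length,
    inpaint_invalid,
    lag_grid_um,
    radial_average,
    spatial_correlation_2d,
)

from conftest import make_field


def direct_circular_correlation(vx, vy):
    """O(N²) oracle: average of v(x)·v(x+r) over all circular shifts."""
    ny, nx = vx.shape
    out = np.empty((ny, nx))
    for dy in range(ny):
        for dx in range(nx):
            sx = np.roll(np.roll(vx, -dy, axis=0), -dx, axis=1)
            sy = np.roll(np.roll(vy, -dy, axis=0), -dx, axis=1)
            out[dy, dx] = np.mean(vx * sx + vy * sy)
    return out


def spectral_synthesis_field(n, L_um, spacing_um, seed):
    """Gaussian random field with isotropic exponential correlation
    exp(−r/L): white noise filtered to the 2D spectrum
    S(k) ∝ (1 + (kL)²)^(−3/2)."""
    rng = np.random.default_rng(seed)
    k = 2 * np.pi * np.fft.fftfreq(n, d=spacing_um)
    kk = np.hypot(k[:, None], k[None, :])
    amp = (1.0 + (kk * L_um) ** 2) ** (-0.75)
    out = []
    for _ in range(2):
        white = np.fft.fft2(rng.standard_normal((n, n)))
        f = np.fft.ifft2(white * amp).real
        out.append(f / f.std())
    return out


class TestFftVsOracle:
    @pytest.mark.parametrize("shape", [(4, 4), (5, 7), (8, 8), (16, 16)])
    def test_matches_direct_shift_average(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        vx = rng.normal(size=shape)
        vy = rng.normal(size=shape)
        fft_map = spatial_correlation_2d(vx, vy, drift_correct=False)
        oracle = direct_circular_correlation(vx, vy)
        assert np.allclose(fft_map, oracle, rtol=1e-10, atol=1e-12)

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        acc = np.zeros((64, 64))
        n_frames = 50
        for _ in range(n_frames):
            acc += spatial_correlation_2d(
                rng.normal(size=(64, 64)), rng.normal(size=(64, 64))
            )
        acc /= n_frames
        c_norm = acc / acc[0, 0]
        off_lag = c_norm.ravel()[1:]
        assert np.abs(off_lag).max() < 5.0 / np.sqrt(n_frames * 64 * 64) * 10

    def test_uniform_field_degenerate_after_drift_correction(self):
        f = make_field(np.full((6, 6), 3.0), np.full((6, 6), 1.0))
        curve = correlation_over_window(f, drift_correct=True)
        assert not curve.fit["converged"]

    def test_too_many_invalid_vectors_rejected(self):
        vx = np.ones((6, 6))
        valid = np.zeros((6, 6), bool)
        valid[:2] = True
        with pytest.raises(ValueError, match="invalid"):
            spatial_correlation_2d(vx, vx, valid)

    def test_inpainting_uses_neighbor_median(self):
        vx = np.ones((5, 5))
        valid = np.ones((5, 5), bool)
        vx[2, 2] = 999.0
        valid[2, 2] = False
        filled = inpaint_invalid(vx, valid)
        assert filled[2, 2] == 1.0


class TestRadialAverage:
    def test_zero_lag_bin_is_exact(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(8, 8))
        r, c, n = radial_average(m, spacing_um=25.0)
        assert r[0] == 0.0
        assert c[0] == pytest.approx(m[0, 0])
        assert n[0] == 1

    def test_isotropic_gaussian_profile_recovered(self):
        spacing = 1.0
        lags = lag_grid_um((64, 64), spacing)
        sigma = 6.0
        m = np.exp(-(lags**2) / (2 * sigma**2))
        r, c, _ = radial_average(m, spacing, bin_width_um=1.0)
        sel = (r > 0) & (r < 20)
        # bin-center vs mean-lag-in-annulus discretization allows ~0.03
        assert np.allclose(c[sel], np.exp(-(r[sel] ** 2) / (2 * sigma**2)), atol=0.04)

    def test_pure_x_sinusoid_angular_mean(self):
        """cos(k·x) correlates only along x; the radial average equals
        the angular mean J0-like integral — check against direct
        numerical angular averaging."""
        n, spacing = 128, 1.0
        x = np.arange(n) * spacing
        kx = 2 * np.pi * 4 / (n * spacing)
        field = np.cos(kx * x)[None, :].repeat(n, axis=0)
        m = spatial_correlation_2d(field, np.zeros_like(field), drift_correct=False)
        r, c, _ = radial_average(m, spacing, bin_width_um=2.0)
        from scipy.special import j0

        sel = (r > 0) & (r < 40)
        expected = 0.5 * j0(kx * r[sel])
        assert np.allclose(c[sel], expected, atol=0.05)


class TestCorrectionAndNormalization:
    def test_drift_corrected_field_needs_no_correction(self):
        rng = np.random.default_rng(2)
        vx = rng.normal(size=(16, 16))
        vx -= vx.mean()
        m = spatial_correlation_2d(vx, np.zeros_like(vx), drift_correct=False)
        r, c, _ = radial_average(m, 25.0)
        c_corr, c_norm, ok = correct_and_normalize(r, c, 0.0)
        assert ok and np.array_equal(c_corr, c)
        assert c_norm[0] == pytest.approx(1.0)

    def test_constant_drift_subtraction_recovers_fluctuations(self):
        rng = np.random.default_rng(3)
        fx = rng.normal(size=(16, 16))
        fx -= fx.mean()
        drift = 5.0
        m_f = spatial_correlation_2d(fx, np.zeros_like(fx), drift_correct=False)
        m_t = spatial_correlation_2d(fx + drift, np.zeros_like(fx), drift_correct=False)
        r, c_f, _ = radial_average(m_f, 25.0)
        _, c_t, _ = radial_average(m_t, 25.0)
        c_corr, _, _ = correct_and_normalize(r, c_t, drift**2)
        assert np.allclose(c_corr, c_f, atol=1e-8)

    def test_degenerate_denominator_flags_not_converged(self):
        r = np.arange(5.0)
        c = np.full(5, 4.0)
        _, _, ok = correct_and_normalize(r, c, 4.0)
        assert not ok


class TestCorrelationFit:
    def test_exact_exponential_self_consistency(self):
        r = np.linspace(0, 200, 60)
        c = np.exp(-r / 20.0)
        fit = fit_correlation_length(r, c)
        assert fit["converged"]
        assert fit["l_corr_um"] == pytest.approx(20.0, abs=1e-5)
        assert fit["gamma"] == pytest.approx(1.0, abs=1e-6)

    def test_noisy_stretched_exponential_recovery(self):
        r = np.linspace(0, 150, 50)
        rng = np.random.default_rng(4)
        Ls, gammas = [], []
        for _ in range(50):
            c = np.exp(-((r / 35.0) ** 0.7)) + rng.normal(0, 0.01, r.size)
            fit = fit_correlation_length(r, c)
            assert fit["converged"]
            Ls.append(fit["l_corr_um"])
            gammas.append(fit["gamma"])
        assert abs(np.median(Ls) - 35.0) / 35.0 < 0.15
        assert abs(np.median(gammas) - 0.7) < 0.15

    def test_too_few_bins_not_converged(self):
        fit = fit_correlation_length(np.arange(4.0), np.exp(-np.arange(4.0)))
        assert not fit["converged"] and "bins" in fit["message"]

    def test_spectral_synthesis_pipeline_recovers_length(self):
        """Full route (FFT → radial average → normalize → fit) on one
        Gaussian field with prescribed exponential correlation."""
        spacing, L = 4.0, 50.0
        vx, vy = spectral_synthesis_field(256, L, spacing, seed=7)
        m = spatial_correlation_2d(vx, vy, drift_correct=True)
        r, c, _ = radial_average(m, spacing)
        _, c_norm, ok = correct_and_normalize(r, c, 0.0)
        assert ok
        fit = fit_correlation_length(r, c_norm, r_max_um=256 * spacing / 2)
        assert fit["converged"]
        assert fit["l_corr_um"] == pytest.approx(L, rel=0.2)


class TestCurveInvariances:
    def _curve(self, vx, vy, **kw):
        f = make_field(vx, vy)
        return correlation_over_window(f, drift_correct=True, **kw)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        vx, vy = rng.normal(size=(2, 24, 24))
        a = self._curve(vx, vy)
        b = self._curve(7.5 * vx, 7.5 * vy)
        assert np.allclose(a.C_normalized, b.C_normalized, atol=1e-12)
        assert a.fit["l_corr_um"] == pytest.approx(b.fit["l_corr_um"], rel=1e-6)
        assert a.fit["gamma"] == pytest.approx(b.fit["gamma"], rel=1e-6)

    def test_rotation_invariance_of_radial_curve(self):
        rng = np.random.default_rng(6)
        vx, vy = rng.normal(size=(2, 24, 24))
        a = self._curve(vx, vy)
        b = self._curve(np.rot90(-vy), np.rot90(vx))  # rotate field + vectors
        assert np.allclose(a.C_normalized, b.C_normalized, atol=1e-10)

    def test_identical_frames_equal_single_frame(self):
        rng = np.random.default_rng(7)
        vx1, vy1 = rng.normal(size=(2, 12, 12))
        single = self._curve(vx1, vy1)
        double = correlation_over_window(
            make_field(np.stack([vx1, vx1]), np.stack([vy1, vy1])),
            drift_correct=True,
        )
        assert np.allclose(single.C_normalized, double.C_normalized, atol=1e-12)

    def test_frame_averaging_tightens_white_noise_band(self):
        rng = np.random.default_rng(8)

        def band(T):
            vx = rng.normal(size=(T, 32, 32))
            vy = rng.normal(size=(T, 32, 32))
            curve = correlation_over_window(make_field(vx, vy), drift_correct=True)
            return np.abs(curve.C_normalized[1:]).mean()

        assert np.mean([band(16) for _ in range(3)]) < np.mean(
            [band(1) for _ in range(3)]
        )
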