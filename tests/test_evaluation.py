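import numpy as np
import pytest

import zsdeconv as z
from zsdeconv.evaluation import LinearMatch
from zsdeconv.losses import convolve_psf, downsample
from zsdeconv.simulator import PSFKernel


def small_psf():
    k = np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25])
    return PSFKernel(kernel=k, pixel_size=(50.0, 50.0))


class TestDegradationMatchedPSNR:
    def test_perfect_match_capped(self, rng):
        gt = rng.uniform(0, 1, (16, 16))
        psf = small_psf()
        # any SR image whose degradation equals normalized gt scores the cap;
        # build one by taking gt itself with a delta PSF and factor 1
        delta = PSFKernel(np.array([[1.0]]), (50.0, 50.0))
        assert z.psnr_degradation_matched(gt, gt, delta, 1) == 100.0

    def test_affine_invariance(self, rng):
        gt = rng.uniform(0, 1, (16, 16))
        sr = rng.uniform(0, 1, (32, 32))
        psf = small_psf()
        base = z.psnr_degradation_matched(sr, gt, psf, 2)
        for a, c in [(2.0, 5.0), (0.3, -1.0), (10.0, 0.0)]:
            assert z.psnr_degradation_matched(a * sr + c, gt, psf, 2) == pytest.approx(
                base, rel=1e-9
            )

    def test_linear_match_closed_form(self, rng):
        # I = 2x + 5 -> fitted a = 0.5, c = -2.5 (inverse mapping)
        x = rng.uniform(0, 1, (16, 16))
        i = 2.0 * x + 5.0
        m = LinearMatch.fit(i, x)
        assert m.slope_a == pytest.approx(0.5)
        assert m.intercept_c == pytest.approx(-2.5)

    def test_matches_normal_equations_oracle(self, rng):
        gt = rng.uniform(0, 1, (16, 16))
        sr = rng.uniform(0, 1, (32, 32))
        psf = small_psf()
        got = z.psnr_degradation_matched(sr, gt, psf, 2)
        # independent oracle via lstsq
        i = downsample(convolve_psf(sr, psf, "reflect"), 2).ravel()
        x = ((gt - gt.min()) / (gt.max() - gt.min())).ravel()
        A = np.stack([i, np.ones_like(i)], axis=1)
        coef, *_ = np.linalg.lstsq(A, x, rcond=None)
        mse = np.mean((A @ coef - x) ** 2)
        assert got == pytest.approx(10 * np.log10(1 / mse), rel=1e-9)

    def test_constant_gt_rejected(self, rng):
        with pytest.raises(ValueError):
            z.psnr_degradation_matched(rng.uniform(0, 1, (8, 8)), np.ones((8, 8)),
                                       small_psf(), 1)


class TestFeatureMaskedPSNR:
    def test_threshold_zero_equals_unmasked(self, rng):
        ref = rng.uniform(0.01, 1, (4, 8, 8))
        sr = rng.uniform(0, 1, (4, 8, 8))
        masked = z.psnr3d_feature_masked(sr, ref, threshold=0.0)
        x = (ref - ref.min()) / (ref.max() - ref.min())
        m = LinearMatch.fit(sr, x)
        mse = np.mean((m.apply(sr) - x) ** 2)
        assert masked == pytest.approx(10 * np.log10(1 / mse), rel=1e-6)

    def test_all_background_rejected(self):
        ref = np.zeros((4, 8, 8))
        ref[0, 0, 0] = 1.0  # normalization needs range, but nothing above thr
        with pytest.raises(ValueError):
            z.psnr3d_feature_masked(np.ones((4, 8, 8)), ref, threshold=2.0)

    def test_masking_ignores_background_error(self, rng):
        # feature voxels match exactly; background carries large error
        ref = np.zeros((4, 16, 16))
        ref[:, 4:12, 4:12] = rng.uniform(0.5, 1.0, (4, 8, 8))
        sr = ref.copy()
        bg = ref <= 0.02
        sr[bg] += rng.uniform(0.3, 0.5, bg.sum())
        masked = z.psnr3d_feature_masked(sr, ref, threshold=0.02)
        unmasked = z.psnr3d_feature_masked(sr, ref, threshold=0.0)
        assert masked > unmasked + 20.0
        # brute-force mask oracle
        x = (ref - ref.min()) / (ref.max() - ref.min())
        mask = x > 0.02
        m = LinearMatch.fit(sr[mask], x[mask])
        mse = np.mean((m.apply(sr[mask]) - x[mask]) ** 2)
        expect = 100.0 if mse < 1e-10 else 10 * np.log10(1 / mse)
        assert masked == pytest.approx(expect, rel=1e-6)


class TestFWHM:
    def test_gaussian_closed_form(self):
        x = np.arange(41)
        sigma = 2.0
        prof = np.exp(-0.5 * ((x - 20) / sigma) ** 2)
        expect = 2 * np.sqrt(2 * np.log(2)) * sigma * 50.0  # = 235.5 nm
        assert z.fwhm(prof, 50.0) == pytest.approx(expect, rel=0.02)

    def test_top_hat(self):
        prof = np.zeros(21)
        prof[8:13] = 1.0
        assert z.fwhm(prof) == pytest.approx(5.0, abs=0.1)

    def test_asymmetric_profile_matches_crossing_search(self):
        x = np.arange(61, dtype=float)
        prof = np.exp(-0.5 * ((x - 30) / 3.0) ** 2) + 0.3 * np.exp(
            -0.5 * ((x - 36) / 6.0) ** 2
        )
        got = z.fwhm(prof)
        # brute-force crossing search at 0.1-px resolution
        fine = np.arange(0, 60, 0.1)
        pf = np.interp(fine, x, prof)
        level = prof.min() + 0.5 * (prof.max() - prof.min())
        above = np.where(pf >= level)[0]
        brute = (above[-1] - above[0]) * 0.1
        assert got == pytest.approx(brute, abs=0.15)

    def test_no_crossing_rejected(self):
        with pytest.raises(ValueError):
            z.fwhm(np.linspace(0, 1, 10))


class TestFRC:
    def test_identical_images_flagged(self, rng):
        img = rng.uniform(0, 1, (64, 64))
        res = z.frc_resolution(img, img)
        assert not res.crossed
        assert np.all(res.frc[1:] > 0.99)

    def test_independent_noise_decorrelated(self, rng):
        n = 256
        a = rng.standard_normal((n, n))
        b = rng.standard_normal((n, n))
        res = z.frc_resolution(a, b)
        ky = np.fft.fftfreq(n)[:, None]
        kx = np.fft.fftfreq(n)[None, :]
        bins = (np.sqrt(ky**2 + kx**2) * n).astype(int)
        counts = np.bincount(bins[bins < n // 2].ravel(), minlength=n // 2)[: n // 2]
        good = counts >= 100
        # each ring is a correlation of ~count/2 independent Fourier pairs:
        # 3.5-sigma bound per ring, and the ensemble hovers near zero
        bound = 3.5 / np.sqrt(np.maximum(counts, 1) / 2)
        assert np.all(np.abs(res.frc[good]) < bound[good])
        assert np.mean(np.abs(res.frc[good])) < 0.05

    def test_band_limited_cutoff_recovered(self, rng):
        # common band-limited signal + independent noise in two realizations
        n = 128
        ky = np.fft.fftfreq(n)[:, None]
        kx = np.fft.fftfreq(n)[None, :]
        r = np.sqrt(ky**2 + kx**2)
        cutoff = 0.25  # cycles/px
        spec = (r < cutoff) * np.exp(1j * rng.uniform(0, 2 * np.pi, (n, n)))
        signal = np.real(np.fft.ifft2(spec))
        signal /= signal.std()
        a = signal + 0.05 * rng.standard_normal((n, n))
        b = signal + 0.05 * rng.standard_normal((n, n))
        res = z.frc_resolution(a, b, pixel_size=1.0)
        assert res.crossed
        assert res.resolution == pytest.approx(1.0 / cutoff, rel=0.10)

    def test_agrees_with_psf_fwhm_at_high_snr(self, psf_cam):
        # two high-SNR noise realizations of a blur-limited punctate scene:
        # FRC resolution within 25% of the PSF FWHM
        ph = z.generate_puncta((256, 256), 150, seed=2, pixel_size=62.5)
        cam = z.CameraModel(background_offset_b=100.0, gaussian_variance_beta2=4.0)
        a = z.render_noisy(ph, psf_cam, cam, 100.0, seed=1).counts
        b = z.render_noisy(ph, psf_cam, cam, 100.0, seed=2).counts
        res = z.frc_resolution(a, b, pixel_size=62.5)
        assert res.crossed
        psf_profile = psf_cam.kernel[psf_cam.kernel.shape[0] // 2]
        psf_fwhm_nm = z.fwhm(psf_profile, 62.5)
        assert res.resolution == pytest.approx(psf_fwhm_nm, rel=0.25)


class TestRichardsonLucy:
    def test_flux_conservation_per_iteration(self, rng):
        img = rng.uniform(1, 5, (32, 32))
        psf = small_psf()
        prev = None
        for it in (1, 2, 5, 10):
            out = z.richardson_lucy(img, psf, it, background=0.0, boundary="periodic")
            assert out.sum() == pytest.approx(img.sum(), rel=1e-3)

    def test_delta_psf_identity(self, rng):
        img = rng.uniform(0, 5, (16, 16)) + 100.0
        delta = PSFKernel(np.array([[1.0]]), (50.0, 50.0))
        out = z.richardson_lucy(img, delta, 7, background=100.0)
        assert np.allclose(out, img - 100.0, atol=1e-9)

    def test_matches_recursion_oracle_and_resolves_two_points(self):
        # 1D two-point signal blurred; compare against a literal RL loop
        n = 64
        sig = np.zeros((1, n))
        sig[0, 28] = 1.0
        sig[0, 36] = 1.0
        k1d = np.exp(-0.5 * ((np.arange(9) - 4) / 2.0) ** 2)
        k = (k1d / k1d.sum())[None, :]
        psf = PSFKernel(k, (50.0, 50.0))
        blurred = z.convolve_psf(sig, psf, "periodic")
        out = z.richardson_lucy(blurred, psf, 50, boundary="periodic")
        # brute-force recursion
        u = np.full_like(blurred, blurred.mean())
        kf = k[:, ::-1]
        psf_f = PSFKernel(kf, (50.0, 50.0))
        for _ in range(50):
            u = u * z.convolve_psf(blurred / (z.convolve_psf(u, psf, "periodic") + 1e-12),
                                   psf_f, "periodic")
        assert np.allclose(out, u, atol=1e-8)
        # peaks separated again
        prof = out[0]
        assert prof[28] > prof[32] * 2 and prof[36] > prof[32] * 2

    def test_zero_iterations_rejected(self):
        with pytest.raises(ValueError):
            z.richardson_lucy(np.ones((8, 8)), small_psf(), 0)
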