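import numpy as np
import pytest
from scipy import ndimage

from semrestore import (
    DeconvolutionParams,
    DegradationSpec,
    PSFModel,
    StripeFilterSpec,
    align_stack,
    degrade,
    estimate_drift,
    estimate_psf,
    make_phantom,
    make_textured_stack,
    remove_stripes,
    richardson_lucy,
    rolling_ball,
    sharpness,
)
from semrestore.corrections import _stripe_wedge


def _brute_force_opening(img, radius):
    """Direct double-loop grayscale opening with a ball structuring element
    on the 255-gray-level scale (the oracle for rolling_ball)."""
    lo, ptp = img.min(), np.ptp(img)
    scale = 255.0 / ptp if ptp > 0 else 1.0
    work = (img - lo) * scale
    r = int(radius)
    ax = np.arange(-r, r + 1)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    inside = yy**2 + xx**2 <= r**2
    h = np.zeros_like(yy, dtype=float)
    h[inside] = np.sqrt(r**2 - (yy**2 + xx**2)[inside])
    n_y, n_x = work.shape
    pad = np.pad(work, r, mode="reflect")
    ero = np.zeros_like(work)
    for y in range(n_y):
        for x in range(n_x):
            win = pad[y : y + 2 * r + 1, x : x + 2 * r + 1]
            ero[y, x] = np.min(win[inside] - h[inside])
    pad = np.pad(ero, r, mode="reflect")
    dil = np.zeros_like(work)
    for y in range(n_y):
        for x in range(n_x):
            win = pad[y : y + 2 * r + 1, x : x + 2 * r + 1]
            dil[y, x] = np.max(win[inside] + h[inside])
    return np.minimum(dil, work) / scale + lo


class TestRollingBall:
    def test_constant_image(self):
        corrected, background = rolling_ball(np.full((32, 32), 5.0), 5)
        np.testing.assert_allclose(background, 5.0)
        np.testing.assert_allclose(corrected, 0.0)

    def test_small_bright_spot_preserved(self):
        img = np.zeros((64, 64))
        img[30:33, 30:33] = 100.0
        corrected, background = rolling_ball(img, 25)
        assert corrected[31, 31] >= 99.0  # preserved within 1%
        assert background.max() <= 1.0

    def test_planar_ramp_removed(self):
        img = np.zeros((64, 64))
        img[30:33, 30:33] = 100.0
        x = np.arange(64)[None, :] * np.ones((64, 1))
        ramp = 50.0 * x / 63.0  # charge-gradient mimic
        corrected, _ = rolling_ball(img + ramp, 25)
        # away from borders (reflection distorts the ramp within ~a radius)
        interior = corrected[20:44, 20:44] - img[20:44, 20:44]
        assert np.abs(interior).max() < 0.1 * 50.0

    def test_matches_brute_force_opening_oracle(self, rng):
        img = ndimage.gaussian_filter(rng.normal(size=(24, 24)), 2.0)
        _, background = rolling_ball(img, 4)
        oracle = _brute_force_opening(img, 4)
        np.testing.assert_allclose(background, oracle, atol=1e-9)

    def test_background_at_most_image_and_corrected_nonnegative(self, rng):
        img = rng.random((32, 32)) * 100
        corrected, background = rolling_ball(img, 8)
        assert np.all(background <= img + 1e-9)
        assert corrected.min() >= 0.0

    def test_opening_is_idempotent(self, rng):
        # at a fixed intensity scale the opening is exactly idempotent
        img = ndimage.gaussian_filter(rng.normal(size=(48, 48)), 3.0) * 50
        _, bg1 = rolling_ball(img, 10, intensity_range=None)
        _, bg2 = rolling_ball(bg1, 10, intensity_range=None)
        np.testing.assert_allclose(bg2, bg1, atol=1e-9)

    def test_radius_validation(self):
        with pytest.raises(ValueError, match="radius"):
            rolling_ball(np.zeros((16, 16)), 17)
        with pytest.raises(ValueError, match="radius"):
            rolling_ball(np.zeros((16, 16)), 0)


@pytest.fixture(scope="module")
def striped_pair():
    ph = make_phantom((10, 128, 128), seed=3)
    deg, _ = degrade(ph, DegradationSpec(stripe_amplitude=0.2, seed=3))
    return ph.data[4], deg.data[4]


class TestRemoveStripes:
    def test_stage2_bypass_equals_plain_fourier_mask(self, striped_pair):
        _, striped = striped_pair
        from scipy.fft import fft2, ifft2

        spec = StripeFilterSpec(cs_iterations=0)
        out = remove_stripes(striped, spec)
        f = fft2(striped)
        f[_stripe_wedge(striped.shape, spec)] = 0.0
        np.testing.assert_allclose(out, np.real(ifft2(f)), atol=1e-10)

    def test_stripe_free_input_high_fidelity(self, striped_pair):
        clean, _ = striped_pair
        out = remove_stripes(clean)
        mse = np.mean((out - clean) ** 2)
        psnr = 10 * np.log10(np.ptp(clean) ** 2 / mse)
        assert psnr > 40.0

    def test_planted_stripes_removed(self, striped_pair):
        clean, striped = striped_pair
        from scipy.fft import fft2

        spec = StripeFilterSpec()
        out = remove_stripes(striped, spec)
        wedge = _stripe_wedge(clean.shape, spec)
        e_in = np.sum(np.abs(fft2(striped))[wedge] ** 2)
        e_out = np.sum(np.abs(fft2(out))[wedge] ** 2)
        assert e_out <= 0.10 * e_in  # >= 90 % wedge energy removed
        rmse_in = np.sqrt(np.mean((striped - clean) ** 2))
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse_out < rmse_in

    def test_kept_coefficients_reinjected(self, striped_pair):
        _, striped = striped_pair
        from scipy.fft import fft2

        spec = StripeFilterSpec(cs_iterations=5)
        out = remove_stripes(striped, spec)
        wedge = _stripe_wedge(striped.shape, spec)
        f_in = fft2(striped)
        f_out = fft2(out)
        np.testing.assert_allclose(
            f_out[~wedge], f_in[~wedge], atol=1e-8 * np.abs(f_in).max()
        )

    def test_horizontal_orientation(self, striped_pair):
        clean, _ = striped_pair
        deg, _ = degrade(
            make_phantom((10, 128, 128), seed=3),
            DegradationSpec(stripe_amplitude=0.2,
                            stripe_orientation="horizontal", seed=3),
        )
        spec = StripeFilterSpec(orientation="horizontal")
        out = remove_stripes(deg.data[4], spec)
        rmse_in = np.sqrt(np.mean((deg.data[4] - clean) ** 2))
        rmse_out = np.sqrt(np.mean((out - clean) ** 2))
        assert rmse_out < rmse_in

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            remove_stripes(np.zeros((8, 8)))


class TestEstimatePSF:
    def test_forward_blur_recovery(self, textured_slice):
        blurred = ndimage.gaussian_filter(textured_slice, 2.0, mode="mirror")
        est = estimate_psf(blurred)
        assert 1.5 <= est.sigma <= 2.5

    def test_monotone_in_true_blur(self, textured_slice):
        s2 = estimate_psf(
            ndimage.gaussian_filter(textured_slice, 2.0, mode="mirror")
        ).sigma
        s4 = estimate_psf(
            ndimage.gaussian_filter(textured_slice, 4.0, mode="mirror")
        ).sigma
        assert s4 > s2

    @pytest.mark.parametrize("seed", range(5))
    def test_strictly_increasing_over_sigma_grid(self, seed):
        img = make_textured_stack(1, (128, 128), seed=seed,
                                  texture_sigma=0.5).data[0]
        estimates = [
            estimate_psf(
                ndimage.gaussian_filter(img, s, mode="mirror")
            ).sigma
            for s in (1.0, 2.0, 3.0, 4.0)
        ]
        assert np.all(np.diff(estimates) > 0)

    def test_white_noise_hits_grid_floor(self):
        img = np.random.default_rng(0).normal(size=(128, 128))
        grid = np.linspace(0.5, 5.0, 10)
        est = estimate_psf(img, sigma_grid=grid)
        assert est.sigma <= grid[0] + 1e-9

    def test_flat_image_degenerate_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est = estimate_psf(np.zeros((64, 64)), sigma_grid=[1.0, 2.0])
        assert est.sigma == 1.0

    def test_kernel_normalized(self, textured_slice):
        est = estimate_psf(textured_slice)
        assert est.kernel.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(est.kernel >= 0)


class TestRichardsonLucy:
    def test_identity_psf_fixed_point(self, rng):
        img = rng.random((32, 32)) + 0.1
        out = richardson_lucy(img, PSFModel.delta(),
                              DeconvolutionParams(n_iter=30))
        np.testing.assert_allclose(out, img, atol=1e-6)

    def test_flux_conserved(self, rng):
        img = rng.random((64, 64))
        out = richardson_lucy(img, PSFModel(sigma=1.5),
                              DeconvolutionParams(n_iter=25))
        assert out.sum() / img.sum() == pytest.approx(1.0, abs=1e-3)

    def test_sharpness_increases_on_blurred_phantom(self, phantom_small):
        clean = phantom_small.data[8]
        blurred = ndimage.gaussian_filter(clean, 2.0, mode="mirror")
        blurred = blurred + np.random.default_rng(1).normal(
            0, 0.002, blurred.shape
        )
        out = richardson_lucy(blurred, PSFModel(sigma=2.0),
                              DeconvolutionParams(n_iter=50))
        assert sharpness(out) > sharpness(blurred)

    def test_poisson_likelihood_monotone_on_noiseless_input(self, phantom_small):
        # RL is an EM algorithm for the Poisson model: on noiseless blurred
        # input the likelihood must never decrease across all 50 iterations
        from semrestore.corrections import _psf_otf
        from scipy.fft import irfft2, rfft2

        psf = PSFModel(sigma=2.0)
        clean = phantom_small.data[5] + 0.05
        otf = _psf_otf(psf.kernel, clean.shape)
        y = np.maximum(irfft2(otf * rfft2(clean), s=clean.shape), 1e-12)

        def loglik(u):
            hu = np.maximum(irfft2(otf * rfft2(u), s=u.shape), 1e-300)
            return float(np.sum(y * np.log(hu) - hu))

        lls = [loglik(y)]
        for k in range(1, 51):
            u_k = richardson_lucy(y, psf, DeconvolutionParams(n_iter=k))
            lls.append(loglik(u_k))
        assert np.all(np.diff(lls) >= -1e-7 * np.abs(lls[0]))

    def test_negative_input_shift_undone(self, rng):
        img = rng.normal(size=(32, 32))  # has negatives
        out = richardson_lucy(img, PSFModel(sigma=1.0),
                              DeconvolutionParams(n_iter=5))
        assert np.isfinite(out).all()
        # flux of the shifted problem is conserved, so means stay close
        assert out.mean() == pytest.approx(img.mean(), abs=0.05)

    def test_tv_regularized_variant_runs_and_conserves_shape(self, phantom_small):
        blurred = ndimage.gaussian_filter(phantom_small.data[4], 2.0)
        out = richardson_lucy(
            blurred, PSFModel(sigma=2.0),
            DeconvolutionParams(n_iter=20, tv_weight=0.002),
        )
        assert out.shape == blurred.shape and np.isfinite(out).all()
        assert sharpness(out) > sharpness(blurred)


class TestDrift:
    def test_identical_images_zero_shift(self, phantom_small):
        dy, dx = estimate_drift(phantom_small.data[5], phantom_small.data[5])
        assert abs(dy) < 1e-6 and abs(dx) < 1e-6

    def test_circular_shift_recovered(self, phantom_small):
        a = phantom_small.data[5]
        b = np.roll(a, (7, -3), axis=(0, 1))
        dy, dx = estimate_drift(a, b)
        assert abs(dy - 7) <= 0.25 and abs(dx + 3) <= 0.25

    def test_subpixel_noncircular_shift(self, phantom_small):
        a = phantom_small.data[5]
        b = ndimage.shift(a, (5.5, 2.5), order=3, mode="nearest")
        dy, dx = estimate_drift(a, b, levels=3)
        assert abs(dy - 5.5) <= 0.5 and abs(dx - 2.5) <= 0.5

    def test_antisymmetry(self, phantom_small, rng):
        a = phantom_small.data[3]
        for _ in range(3):
            shift = rng.uniform(-4, 4, size=2)
            b = ndimage.shift(a, shift, order=3, mode="nearest")
            fwd = np.array(estimate_drift(a, b))
            rev = np.array(estimate_drift(b, a))
            assert np.abs(fwd + rev).max() <= 0.25

    def test_flat_image_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            estimate_drift(np.zeros((32, 32)), np.zeros((32, 32)))

    def test_too_many_levels_rejected(self, phantom_small):
        with pytest.raises(ValueError, match="levels"):
            estimate_drift(phantom_small.data[0], phantom_small.data[0],
                           levels=5)


class TestAlignStack:
    def test_already_aligned_stack_is_noop(self):
        # static content (one slice repeated with fresh noise): recovered
        # shifts are exactly zero
        from semrestore import ImageStack

        base = make_phantom((8, 64, 64), seed=2).data[4]
        r = np.random.default_rng(0)
        stack = ImageStack(np.stack(
            [base + r.normal(0, 0.002, base.shape) for _ in range(10)]
        ))
        aligned, traj = align_stack(stack, levels=2)
        assert np.abs(traj.shifts).max() < 0.2
        assert traj.shifts[0].tolist() == [0.0, 0.0]

    def test_planted_random_walk_recovered(self):
        ph = make_phantom((32, 128, 128), seed=1)
        deg, truth = degrade(ph, DegradationSpec(drift_step_std=1.5, seed=1))
        _, traj = align_stack(deg, levels=3)
        rms = np.sqrt(np.mean((traj.shifts - truth["shifts"]) ** 2))
        assert rms <= 0.5

    def test_realignment_residual_small(self):
        ph = make_phantom((16, 128, 128), seed=4)
        deg, _ = degrade(ph, DegradationSpec(drift_step_std=1.0, seed=4))
        aligned, _ = align_stack(deg, levels=3)
        _, traj2 = align_stack(aligned, levels=3)
        assert np.abs(traj2.shifts).max() <= 0.5

    def test_flat_slice_inherits_previous_shift(self, phantom_small):
        data = phantom_small.data.copy()
        data[7] = 0.0  # zero-variance slice
        with pytest.warns(UserWarning, match="re-using"):
            _, traj = align_stack(phantom_small.with_data(data), levels=2)
        assert np.isfinite(traj.shifts).all()
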