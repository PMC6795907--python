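"""Fiducial PSF estimation, merged Wiener reconstruction, edge-spread analysis."""

import numpy as np
import pytest
from scipy import ndimage

from epiglim import (
    VolumeStack,
    esf_to_lsf,
    estimate_psf_fiducial,
    lsf_to_transfer,
    register_fiducials,
    render_sphere_potential,
    simulate_edge_target,
    tomographic_highpass,
    wiener_reconstruct,
)
from epiglim.psf_recon import FiducialSpec, build_wiener_filter

SAMPLING = (0.25, 0.25, 0.25)
SHAPE = (32, 32, 32)


@pytest.fixture(scope="module")
def sphere():
    """3 um polystyrene fiducial potential on a 0.25 um voxel grid."""
    return render_sphere_potential(3.0, 1.605, 1.518, SHAPE, SAMPLING)


@pytest.fixture(scope="module")
def blob():
    """Full-spectral-support fiducial (Gaussian blob): no spectral nulls.

    A sphere's discrete spectrum has exact nulls, at which a perfect-system
    deconvolution is undefined; the blob isolates properties that hold on
    full support.
    """
    z, y, x = np.mgrid[0:32, 0:32, 0:32].astype(float)
    r2 = (z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2
    return np.exp(-r2 / (2 * 4.0**2))


def _vol(data):
    return VolumeStack(data=data, sampling=SAMPLING)


def _spectral_blur(data, sigma):
    """Gaussian blur applied exactly in the frequency domain."""
    return np.fft.ifftn(ndimage.fourier_gaussian(np.fft.fftn(data), sigma)).real


def _moment_sigma(profile):
    profile = np.clip(profile, 0.0, None)
    x = np.arange(profile.size, dtype=float)
    mu = (x * profile).sum() / profile.sum()
    return np.sqrt(((x - mu) ** 2 * profile).sum() / profile.sum())


def _fwhm(profile, step):
    p = np.asarray(profile, dtype=float)
    p = p - p.min()
    half = p.max() / 2.0
    above = np.where(p >= half)[0]
    lo, hi = int(above[0]), int(above[-1])

    def cross(i, j):
        return i + (half - p[i]) / (p[j] - p[i]) * (j - i)

    left = cross(lo, lo - 1) if lo > 0 else float(lo)
    right = cross(hi, hi + 1) if hi < p.size - 1 else float(hi)
    return (right - left) * step


class TestRegisterFiducials:
    def test_single_volume_returned_unchanged(self, sphere):
        out = register_fiducials([_vol(sphere)])
        np.testing.assert_array_equal(out.data, sphere)

    def test_integer_shift_recovered_exactly(self, sphere):
        shifted = np.roll(sphere, (1, 2, 3), axis=(0, 1, 2))
        out = register_fiducials([_vol(sphere), _vol(shifted)])
        # brute-force oracle: the best integer shift re-aligns perfectly,
        # so the average equals the reference
        np.testing.assert_allclose(out.data, sphere, atol=1e-10)

    def test_subvoxel_shift_recovered_within_quarter_voxel(self, sphere):
        from epiglim._utils import subpixel_argmax, wrap_offset
        from epiglim.psf_recon import _cross_correlate

        shifted = np.fft.ifftn(
            ndimage.fourier_shift(np.fft.fftn(sphere), (0.0, 0.4, 0.0))
        ).real
        corr = _cross_correlate(sphere, _vol(shifted).data)
        pos, _ = subpixel_argmax(corr)
        shift = wrap_offset(pos, corr.shape)
        assert abs(-shift[1] - 0.4) < 0.25

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            register_fiducials([])


class TestEstimatePsf:
    def test_identity_system_yields_discrete_delta(self, blob):
        psf = estimate_psf_fiducial(_vol(blob), blob, spectral_floor=0.0)
        center = tuple(s // 2 for s in SHAPE)
        assert psf.psf_r[center] == pytest.approx(1.0, abs=1e-6)
        off_center = psf.psf_r.copy()
        off_center[center] = 0.0
        assert np.abs(off_center).max() < 1e-6

    def test_gaussian_blur_recovered_within_five_percent(self, sphere):
        sigma = 2.0
        blurred = ndimage.gaussian_filter(sphere, sigma)
        psf = estimate_psf_fiducial(_vol(blurred), sphere, spectral_floor=1e-9)
        center = tuple(s // 2 for s in SHAPE)
        for axis_profile in (
            psf.psf_r[center[0], center[1], :],
            psf.psf_r[center[0], :, center[2]],
            psf.psf_r[:, center[1], center[2]],
        ):
            assert _moment_sigma(axis_profile) == pytest.approx(sigma, rel=0.05)

    def test_shifted_fiducial_gives_shifted_delta(self, sphere):
        shifted = np.roll(sphere, (2, -1, 3), axis=(0, 1, 2))
        psf = estimate_psf_fiducial(_vol(shifted), sphere, spectral_floor=0.0)
        center = np.array(SHAPE) // 2
        peak = np.unravel_index(np.argmax(psf.psf_r), SHAPE)
        np.testing.assert_array_equal(peak, center + (2, -1, 3))

    def test_normalization_invariants(self, sphere):
        psf = estimate_psf_fiducial(
            _vol(ndimage.gaussian_filter(sphere, 1.5)), sphere
        )
        assert psf.psf_r.sum() == pytest.approx(1.0, abs=1e-9)
        assert psf.otf_k.flat[0] == pytest.approx(1.0, abs=1e-9)


class TestWienerReconstruct:
    def test_delta_system_with_zero_regularizer_is_identity(self, blob):
        rng = np.random.default_rng(0)
        y = _vol(ndimage.gaussian_filter(rng.standard_normal(SHAPE), 2.0))
        recon, _ = wiener_reconstruct(y, _vol(blob), blob, epsilon=0.0,
                                      spectral_floor=0.0)
        np.testing.assert_allclose(recon.data, y.data, atol=1e-10)

    def test_exact_inverse_limit_on_fiducial_band(self, sphere):
        """Known Gaussian blur, eps=0: exact recovery above the spectral floor.

        The blur is applied spectrally so the forward model is exactly
        ``y(k) = G(k) x(k)`` at every frequency; the comparison excludes the
        sphere spectrum's exact nulls, where the fiducial carries no
        information.
        """
        rng = np.random.default_rng(1)
        truth = ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.5)
        psf_sigma = 1.2
        y = _vol(_spectral_blur(truth, psf_sigma))
        y_o = _vol(_spectral_blur(sphere, psf_sigma))
        recon, filt = wiener_reconstruct(y, y_o, sphere, epsilon=0.0,
                                         spectral_floor=0.0)
        band = filt.band_mask(0.0)  # frequencies where the sphere spectrum is nonzero
        err_k = (np.fft.fftn(recon.data) - np.fft.fftn(truth))[band]
        rel = np.linalg.norm(err_k) / np.linalg.norm(np.fft.fftn(truth)[band])
        assert rel < 1e-6

    def test_merged_filter_equals_estimate_then_deconvolve(self, sphere):
        """Merging PSF estimation and Wiener deconvolution is an identity."""
        eps, floor = 0.003, 1e-6
        rng = np.random.default_rng(2)
        truth = ndimage.gaussian_filter(rng.standard_normal(SHAPE), 1.5)
        y = _vol(ndimage.gaussian_filter(truth, 1.0))
        y_o = _vol(ndimage.gaussian_filter(sphere, 1.0))
        merged, _ = wiener_reconstruct(y, y_o, sphere, epsilon=eps, spectral_floor=floor)

        # two-step route: estimate H(k) explicitly, then classical Wiener
        xk = np.fft.fftn(sphere)
        x_pow = np.abs(xk) ** 2
        h = np.fft.fftn(y_o.data) * np.conj(xk) / (x_pow + floor * x_pow.max())
        w = np.conj(h) / (np.abs(h) ** 2 + eps)
        two_step = np.fft.ifftn(np.fft.fftn(y.data) * w).real
        rel = np.linalg.norm(merged.data - two_step) / np.linalg.norm(two_step)
        assert rel < 1e-6

    def test_filter_finite_even_at_zero_regularizer(self, sphere):
        y_o = _vol(np.zeros(SHAPE))  # H == 0 everywhere
        filt = build_wiener_filter(y_o, sphere, epsilon=0.0)
        assert np.all(np.isfinite(filt.w_k))

    def test_negative_regularizer_rejected(self, sphere):
        with pytest.raises(ValueError):
            build_wiener_filter(_vol(sphere), sphere, epsilon=-0.1)

    def test_noisy_sphere_recovers_shape_over_realizations(self, sphere):
        """Blurred + noisy 3 um sphere: Wiener at eps=0.003 restores diameter
        and spherical symmetry (axial/lateral FWHM ratio near 1)."""
        psf_sigma = (2.0, 1.2, 1.2)  # axially elongated response
        y_clean = ndimage.gaussian_filter(sphere, psf_sigma)
        yo_clean = ndimage.gaussian_filter(sphere, psf_sigma)
        noise_sigma = 0.003
        c = SHAPE[0] // 2
        fwhms_x, fwhms_z = [], []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            y = _vol(y_clean + rng.normal(0, noise_sigma, SHAPE))
            y_o = _vol(yo_clean + rng.normal(0, noise_sigma, SHAPE))
            recon, _ = wiener_reconstruct(y, y_o, sphere, epsilon=0.003)
            fwhms_x.append(_fwhm(recon.data[c, c, :], SAMPLING[2]))
            fwhms_z.append(_fwhm(recon.data[:, c, c], SAMPLING[0]))
        mean_x, mean_z = np.mean(fwhms_x), np.mean(fwhms_z)
        assert mean_x == pytest.approx(3.0, rel=0.10)
        assert mean_z == pytest.approx(3.0, rel=0.10)
        assert mean_z / mean_x == pytest.approx(1.0, abs=0.15)


class TestEdgeSpread:
    def _edge_stack(self, angle, sigma, n_z=5):
        obj = simulate_edge_target(
            edge_angle=angle, blur_sigma=sigma, shape=(64, 64), pixel_pitch=0.1
        )
        return VolumeStack(
            data=np.stack([obj.phase_map] * n_z), sampling=(1.0, 0.1, 0.1)
        )

    def test_ideal_step_gives_impulse_lsf(self):
        lsf, _ = esf_to_lsf(self._edge_stack(0.0, 0.0))
        profile = np.abs(lsf[0])
        # central-difference impulse spreads over two samples at the jump
        assert profile.max() > 0
        assert np.count_nonzero(profile > 0.1 * profile.max()) <= 3

    @pytest.mark.parametrize("angle", [0.0, 5.0])
    def test_gaussian_width_recovered(self, angle):
        sigma_um = 0.3
        lsf, _ = esf_to_lsf(self._edge_stack(angle, sigma_um), edge_angle_hint=angle)
        width_px = _moment_sigma(lsf[2])
        assert width_px * 0.1 == pytest.approx(sigma_um, rel=0.05)

    def test_featureless_stack_rejected(self):
        flat = VolumeStack(data=np.zeros((4, 32, 32)), sampling=(1, 1, 1))
        with pytest.raises(ValueError, match="edge"):
            esf_to_lsf(flat)


class TestTransferFunction:
    def test_separable_gaussian_lsf_transforms_separably(self):
        x = np.arange(64) - 32.0
        lsf = np.tile(np.exp(-0.5 * (x / 3.0) ** 2), (8, 1))
        tf = lsf_to_transfer(lsf, dx=0.1, dz=1.0, taper_fraction=0.0)
        mag = tf["magnitude"]
        # all energy at k_z = 0 (constant along z)
        kz0 = np.argmin(np.abs(tf["kz"]))
        off_axis = np.delete(mag, kz0, axis=0)
        assert off_axis.max() < 1e-9 * mag.max()
        # Gaussian along k_x with reciprocal width
        row = mag[kz0]
        sigma_k = _moment_sigma(row) * (tf["kx"][1] - tf["kx"][0])
        assert sigma_k == pytest.approx(1.0 / (2 * np.pi * 3.0 * 0.1), rel=0.05)

    def test_parseval_energy_conserved(self):
        rng = np.random.default_rng(3)
        lsf = rng.standard_normal((8, 32))
        tf = lsf_to_transfer(lsf, taper_fraction=0.1)
        spatial = np.sum(tf["windowed"] ** 2)
        spectral = np.sum(tf["magnitude"] ** 2) / tf["magnitude"].size
        assert spectral == pytest.approx(spatial, rel=1e-9)

    def test_too_few_planes_rejected(self):
        with pytest.raises(ValueError):
            lsf_to_transfer(np.zeros((3, 32)))


class TestTomographicHighpass:
    def test_constant_slices_become_zero(self):
        stack = VolumeStack(data=np.full((3, 32, 32), 7.0), sampling=(1, 1, 1))
        out = tomographic_highpass(stack, 0.1)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_scatterers_retained_background_suppressed(self):
        rng = np.random.default_rng(5)
        y, x = np.mgrid[0:64, 0:64].astype(float)
        background = 5.0 * np.sin(2 * np.pi * x / 64) * np.cos(2 * np.pi * y / 64)
        points = np.zeros((64, 64))
        for py, px in [(20, 20), (40, 45), (30, 10)]:
            points[py, px] = 3.0
        stack = VolumeStack(data=(background + points)[None], sampling=(1, 1, 1))
        stack.data = np.repeat(stack.data, 2, axis=0)
        out = tomographic_highpass(stack, cutoff_fraction=0.05)
        empty = ~ndimage.binary_dilation(points > 0, iterations=8)
        bg_rms_in = np.sqrt(np.mean(background**2))
        bg_rms_out = np.sqrt(np.mean(out.data[0][empty] ** 2))
        assert bg_rms_out < bg_rms_in / 10
        for py, px in [(20, 20), (40, 45), (30, 10)]:
            # peak height above the local residual background level
            ring = out.data[0][py - 6 : py + 7, px - 6 : px + 7].copy()
            ring[4:9, 4:9] = np.nan
            local = float(np.nanmedian(ring))
            assert out.data[0][py, px] - local == pytest.approx(3.0, rel=0.10)

    def test_slice_means_are_zero(self):
        rng = np.random.default_rng(6)
        stack = VolumeStack(data=rng.standard_normal((4, 32, 32)) + 5.0, sampling=(1, 1, 1))
        out = tomographic_highpass(stack, 0.1)
        rng_in = np.ptp(stack.data)
        assert np.abs(out.data.mean(axis=(1, 2))).max() < 1e-9 * rng_in

    def test_bilateral_smooths_without_shifting_mean(self):
        rng = np.random.default_rng(7)
        stack = VolumeStack(data=rng.standard_normal((2, 32, 32)), sampling=(1, 1, 1))
        out = tomographic_highpass(stack, 0.1, bilateral=True, sigma_spatial=2.0)
        assert np.all(np.isfinite(out.data))
        assert np.var(out.data[0]) < np.var(stack.data[0])

    def test_invalid_sigmas_rejected(self):
        stack = VolumeStack(data=np.zeros((2, 16, 16)), sampling=(1, 1, 1))
        with pytest.raises(ValueError):
            tomographic_highpass(stack, 0.1, bilateral=True, sigma_spatial=-1.0)
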