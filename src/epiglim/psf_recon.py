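"""System-response characterization and Wiener tomographic reconstruction.

Two complementary calibrations are implemented:

* **Fiducial beads** — microspheres of known geometry co-embedded with the
  specimen share its optical path, so any difference between their known
  scattering potential ``x_o(r)`` and the measured volume ``y_o(r)`` is the
  system response: ``y_o = PSF (*) x_o``, hence ``PSF(k) = y_o(k)/x_o(k)``
  (stabilized by a spectral floor where the sphere spectrum has nulls).
  An unknown object measured as ``y`` is then reconstructed by a single
  merged Wiener filter ``x(k) = y(k) * conj(H)/(|H|^2 + eps)`` with
  ``H = y_o(k)/x_o(k)``; merging PSF estimation and deconvolution avoids a
  second regularizer. The regularizer ``eps`` is a noise-to-signal power
  ratio (default 0.003).

* **Edge targets** — a through-focus stack of a phase step (micropillar
  edge) yields an edge-spread function per focus position; its lateral
  derivative is the line-spread function, and a 2D Fourier transform over
  (x, z) gives the instrument transfer function in the (k_x, k_z) domain.

A slice-by-slice high-pass filter (optionally followed by edge-preserving
bilateral smoothing) provides the simple tomographic rendering used for
large, absorbing specimens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import restoration, transform

from ._utils import subpixel_argmax, wrap_offset
from .datatypes import VolumeStack

__all__ = [
    "PSFModel",
    "FiducialSpec",
    "WienerFilter",
    "render_sphere_potential",
    "register_fiducials",
    "estimate_psf_fiducial",
    "wiener_reconstruct",
    "esf_to_lsf",
    "lsf_to_transfer",
    "tomographic_highpass",
    "IllConditionedFiducialError",
]


class IllConditionedFiducialError(ValueError):
    """Fiducial spectrum too weak over most of the band to deconvolve."""


@dataclass
class PSFModel:
    """Real-space point spread function and its transfer function.

    ``psf_r`` is unit-sum normalized (so the zero-frequency value of
    ``otf_k`` is 1); ``sampling`` is (dz, dy, dx) in micrometres for 3D or
    (dy, dx) for 2D.
    """

    psf_r: np.ndarray
    sampling: tuple[float, ...]

    def __post_init__(self) -> None:
        self.psf_r = np.asarray(self.psf_r, dtype=float)
        total = self.psf_r.sum()
        if total == 0:
            raise ValueError("PSF has zero integral; cannot normalize")
        self.psf_r = self.psf_r / total

    @property
    def otf_k(self) -> np.ndarray:
        """Discrete transfer function (DFT of the centred PSF)."""
        return np.fft.fftn(np.fft.ifftshift(self.psf_r))


@dataclass
class FiducialSpec:
    """A spherical fiducial of known geometry and refractive contrast.

    ``diameter`` in micrometres; ``n``/``n0`` the sphere and medium indices;
    ``center`` the (z, y, x) position in micrometres on the target grid.
    """

    diameter: float
    n: float
    n0: float
    center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("fiducial diameter must be > 0")

    def render(
        self, shape: tuple[int, int, int], sampling: tuple[float, float, float]
    ) -> np.ndarray:
        """Known scattering potential ``x_o`` on a voxel grid (see below)."""
        return render_sphere_potential(
            self.diameter, self.n, self.n0, shape, sampling, center=self.center
        )


def render_sphere_potential(
    diameter: float,
    n: float,
    n0: float,
    shape: tuple[int, int, int],
    sampling: tuple[float, float, float],
    center: tuple[float, float, float] | None = None,
    supersample: int = 3,
) -> np.ndarray:
    """Rasterize a sphere's scattering potential on a voxel grid.

    The potential is the refractive contrast ``n - n0`` inside the sphere
    support and zero outside, sampled with ``supersample``-point antialiasing
    per axis so the sphere boundary does not alias into the spectrum. The
    grid centre is used when ``center`` is None.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    nz, ny, nx = shape
    dz, dy, dx = sampling
    if center is None:
        center = (nz / 2.0 * dz, ny / 2.0 * dy, nx / 2.0 * dx)
    s = max(int(supersample), 1)
    axes = []
    for npix, step, c in zip(shape, sampling, center):
        coords = ((np.arange(npix * s) + 0.5) / s) * step - c
        axes.append(coords)
    r2 = (
        axes[0][:, None, None] ** 2
        + axes[1][None, :, None] ** 2
        + axes[2][None, None, :] ** 2
    )
    ball = (r2 <= (diameter / 2.0) ** 2).astype(float)
    if s > 1:
        ball = ball.reshape(nz, s, ny, s, nx, s).mean(axis=(1, 3, 5))
    return (n - n0) * ball


def _cross_correlate(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation of ``a`` with ``b`` via the FFT."""
    fa = np.fft.fftn(a)
    fb = np.fft.fftn(b)
    return np.real(np.fft.ifftn(fa * np.conj(fb)))


def register_fiducials(volumes: list[VolumeStack]) -> VolumeStack:
    """Align bead volumes by rigid translation and average them.

    The first volume anchors the frame; every other volume is registered to
    it by the cross-correlation peak (sub-voxel via parabolic fit), shifted
    back by band-limited interpolation, and the aligned volumes are averaged
    voxelwise. Averaging several fiducials suppresses uncorrelated noise in
    the response estimate. If two correlation peaks tie, the argmax picks
    the first in scan order, i.e. the smaller-magnitude shift after
    periodic wrapping.
    """
    if not volumes:
        raise ValueError("need at least one fiducial volume")
    ref = volumes[0]
    if any(v.data.shape != ref.data.shape for v in volumes):
        raise ValueError("all fiducial volumes must share one shape (crop first)")
    if len(volumes) == 1:
        return ref
    acc = ref.data.astype(float).copy()
    for vol in volumes[1:]:
        corr = _cross_correlate(ref.data, vol.data)
        pos, _ = subpixel_argmax(corr)
        shift = wrap_offset(pos, corr.shape)
        moved = np.fft.ifftn(
            ndimage.fourier_shift(np.fft.fftn(vol.data), shift)
        ).real
        acc += moved
    return VolumeStack(data=acc / len(volumes), sampling=ref.sampling, z0=ref.z0)


def _spectral_ratio(
    num: np.ndarray, den: np.ndarray, floor_rel: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stabilized spectral division num/den with a floor on |den|^2.

    Returns the ratio and the |den|^2 array (for band diagnostics). With
    ``floor_rel = 0`` the division is exact wherever den != 0.
    """
    den_pow = np.abs(den) ** 2
    floor = floor_rel * float(den_pow.max()) if den_pow.size else 0.0
    ratio = num * np.conj(den) / (den_pow + floor) if floor > 0 else np.where(
        den_pow > 0, num * np.conj(den) / np.where(den_pow > 0, den_pow, 1.0), 0.0
    )
    return ratio, den_pow


def estimate_psf_fiducial(
    y_o: VolumeStack,
    spec: FiducialSpec | np.ndarray,
    spectral_floor: float = 1e-6,
) -> PSFModel:
    """Estimate the PSF by deconvolving a known fiducial from its image.

    ``PSF(k) = y_o(k) conj(x_o(k)) / (|x_o(k)|^2 + floor)``, where the floor
    is ``spectral_floor`` times the peak of ``|x_o(k)|^2`` (a sphere spectrum
    has nulls that would otherwise blow up). The inverse transform is
    recentred (zero lag at the array centre) and unit-sum normalized.
    """
    if spectral_floor < 0:
        raise ValueError("spectral_floor must be >= 0")
    x_o = spec.render(y_o.data.shape, y_o.sampling) if isinstance(spec, FiducialSpec) else spec
    x_o = np.asarray(x_o, dtype=float)
    if x_o.shape != y_o.data.shape:
        raise ValueError("known potential and measured volume shapes differ")
    xk = np.fft.fftn(x_o)
    x_pow = np.abs(xk) ** 2
    floor = spectral_floor * float(x_pow.max())
    if floor > 0 and np.mean(x_pow < floor) > 0.5:
        raise IllConditionedFiducialError(
            "fiducial spectrum is below the floor on more than half the band"
        )
    yk = np.fft.fftn(y_o.data)
    psf_k = yk * np.conj(xk) / (x_pow + floor) if floor > 0 else np.where(
        x_pow > 0, yk * np.conj(xk) / np.where(x_pow > 0, x_pow, 1.0), 0.0
    )
    psf_r = np.fft.fftshift(np.fft.ifftn(psf_k).real)
    return PSFModel(psf_r=psf_r, sampling=y_o.sampling)


@dataclass
class WienerFilter:
    """A merged reconstruction filter ``w(k)`` with its regularizer."""

    w_k: np.ndarray
    epsilon: float
    spectral_floor: float
    x_o_power: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.w_k)):
            raise ValueError("Wiener filter must be finite everywhere")

    def band_mask(self, threshold_rel: float = 1e-6) -> np.ndarray:
        """Frequencies where the fiducial spectrum carries signal."""
        return self.x_o_power > threshold_rel * float(self.x_o_power.max())


def build_wiener_filter(
    y_o: VolumeStack | np.ndarray,
    x_o: np.ndarray,
    epsilon: float = 0.003,
    spectral_floor: float = 1e-6,
) -> WienerFilter:
    """Construct the merged fiducial Wiener filter.

    ``H(k) = y_o(k)/x_o(k)`` (floored on ``|x_o|^2``), then
    ``w(k) = conj(H)/(|H|^2 + eps)``. The denominator carries an additional
    tiny floor (1e-12 of its own peak) so the filter stays finite for every
    ``eps >= 0``, including the unregularized limit where ``H`` may vanish.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    y_data = y_o.data if isinstance(y_o, VolumeStack) else np.asarray(y_o, dtype=float)
    x_o = np.asarray(x_o, dtype=float)
    if y_data.shape != x_o.shape:
        raise ValueError("y_o and x_o shapes differ")
    h, x_pow = _spectral_ratio(np.fft.fftn(y_data), np.fft.fftn(x_o), spectral_floor)
    h_pow = np.abs(h) ** 2
    denom = h_pow + epsilon
    # Frequencies where H vanishes identically (eps = 0 included) carry no
    # information; the filter is set to 0 there instead of dividing 0 by 0,
    # keeping w finite for every eps >= 0 without biasing nonzero bands.
    safe = denom > 0
    w = np.where(safe, np.conj(h) / np.where(safe, denom, 1.0), 0.0)
    w = np.where(np.isfinite(w), w, 0.0)
    return WienerFilter(w_k=w, epsilon=epsilon, spectral_floor=spectral_floor, x_o_power=x_pow)


def wiener_reconstruct(
    y: VolumeStack,
    y_o: VolumeStack | np.ndarray,
    x_o: np.ndarray,
    epsilon: float = 0.003,
    spectral_floor: float = 1e-6,
) -> tuple[VolumeStack, WienerFilter]:
    """Reconstruct an unknown object with the merged fiducial Wiener filter.

    Applies ``x(k) = y(k) w(k)`` and inverse-transforms. ``epsilon`` is the
    noise-to-signal power ratio; 0.003 was found near-optimal for this
    modality and is the default. Returns the reconstruction and the filter
    (whose ``band_mask`` delimits the frequencies actually constrained by
    the fiducial).
    """
    filt = build_wiener_filter(y_o, x_o, epsilon=epsilon, spectral_floor=spectral_floor)
    xk = np.fft.fftn(y.data) * filt.w_k
    recon = np.fft.ifftn(xk).real
    return VolumeStack(data=recon, sampling=y.sampling, z0=y.z0), filt


def esf_to_lsf(
    zstack: VolumeStack,
    edge_angle_hint: float = 0.0,
    gradient_threshold: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-spread to line-spread profiles, one per focus position.

    The dominant edge orientation is estimated from the gradient structure
    tensor of the highest-contrast slice (seeded by ``edge_angle_hint``,
    degrees between the edge normal and the x axis); every slice is rotated
    so the edge runs vertically, averaged along the edge into a 1D
    edge-spread function, and differentiated laterally (central differences)
    into the line-spread function.

    Returns ``(lsf, esf)`` arrays of shape (nz, nx).
    """
    data = zstack.data
    best = int(np.argmax([np.var(sl) for sl in data]))
    gy, gx = np.gradient(data[best])
    energy = float(np.mean(gx**2 + gy**2))
    if energy < gradient_threshold:
        raise ValueError("no edge detected: gradient energy below threshold")
    # Structure-tensor orientation of the edge normal (doubled-angle mean).
    jxx, jyy, jxy = np.sum(gx * gx), np.sum(gy * gy), np.sum(gx * gy)
    angle = 0.5 * np.degrees(np.arctan2(2 * jxy, jxx - jyy))
    # Resolve the 180-degree ambiguity toward the hint.
    for cand in (angle - 180.0, angle, angle + 180.0):
        if abs(cand - edge_angle_hint) <= 90.0:
            angle = cand
            break

    esfs = []
    for sl in data:
        rot = transform.rotate(sl, angle, order=3, mode="edge") if angle else sl
        esfs.append(rot.mean(axis=0))
    esf = np.asarray(esfs)
    lsf = np.gradient(esf, axis=1)
    return lsf, esf


def lsf_to_transfer(
    lsf_per_z: np.ndarray,
    dx: float = 1.0,
    dz: float = 1.0,
    taper_fraction: float = 0.1,
) -> dict:
    """Transfer function in the (k_x, k_z) domain from per-focus LSFs.

    A separable cosine-taper (Tukey) window of the given fraction suppresses
    wrap-around edges, then a 2D DFT over (z, x) yields the transfer map.
    Frequency axes are in cycles per micrometre.

    Returns a record with ``magnitude`` (fftshifted), ``kx``, ``kz`` and the
    ``windowed`` input (for energy bookkeeping: Parseval holds between the
    windowed input and the unshifted spectrum).
    """
    lsf = np.asarray(lsf_per_z, dtype=float)
    if lsf.ndim != 2 or lsf.shape[0] < 4:
        raise ValueError("need a 2D (nz >= 4, nx) array of line-spread profiles")
    nz, nx = lsf.shape
    win = np.outer(_tukey(nz, taper_fraction), _tukey(nx, taper_fraction))
    windowed = lsf * win
    spec = np.fft.fft2(windowed)
    return {
        "magnitude": np.fft.fftshift(np.abs(spec)),
        "kx": np.fft.fftshift(np.fft.fftfreq(nx, d=dx)),
        "kz": np.fft.fftshift(np.fft.fftfreq(nz, d=dz)),
        "windowed": windowed,
    }


def _tukey(n: int, alpha: float) -> np.ndarray:
    from scipy.signal import windows

    return windows.tukey(n, alpha=2.0 * alpha, sym=False) if alpha > 0 else np.ones(n)


def tomographic_highpass(
    stack: VolumeStack,
    cutoff_fraction: float = 0.1,
    bilateral: bool = False,
    sigma_spatial: float = 2.0,
    sigma_range: float | None = None,
) -> VolumeStack:
    """Slice-by-slice high-pass tomographic rendering.

    Each z slice is independently high-pass filtered (the Gaussian low-pass
    of width ``cutoff_fraction`` times the slice size is subtracted and the
    residual mean removed, so every output slice is zero-mean), then
    optionally smoothed edge-preservingly with a bilateral filter. Bilateral
    parameters are exposed because no canonical values exist for this
    modality; ``sigma_range`` defaults to the per-slice standard deviation.
    """
    if not 0 < cutoff_fraction < 0.5:
        raise ValueError("cutoff_fraction must lie in (0, 0.5)")
    if sigma_spatial <= 0 or (sigma_range is not None and sigma_range <= 0):
        raise ValueError("bilateral sigmas must be positive")
    out = np.empty_like(stack.data)
    ny, nx = stack.data.shape[1:]
    sigma = (cutoff_fraction * ny, cutoff_fraction * nx)
    for i, sl in enumerate(stack.data):
        hp = sl - ndimage.gaussian_filter(sl, sigma=sigma, mode="nearest")
        hp -= hp.mean()
        if bilateral and np.ptp(hp) > 0:
            srange = sigma_range if sigma_range is not None else float(np.std(hp))
            hp = restoration.denoise_bilateral(
                hp, sigma_color=srange, sigma_spatial=sigma_spatial
            )
            hp -= hp.mean()
        out[i] = hp
    return VolumeStack(data=out, sampling=stack.sampling, z0=stack.z0)
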