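"""Synthetic phantoms and sheared-beam (DIC) image formation.

This module generates every test input the reconstruction stack consumes:
projected-phase bead phantoms, phase-step (micropillar edge) targets,
multilayer spheroid z-stacks, phase-shifted interferogram series, and tile
grids for mosaicking — all with known ground truth.

The image formation model is the two-beam interference law

    I_n(r) = I(r) + I(r + dr) + 2 sqrt(I(r) I(r + dr))
             * cos[phi(r + dr) - phi(r) + phi_b(r) + phi_0 + eps_n]

plus a non-modulating additive background that emulates incoherent multiple
scattering (identical in every frame, so it cancels in phase-shifting
differences). Sub-pixel shear is applied by band-limited (Fourier) shift.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special

from ._utils import fourier_shift
from .datatypes import AcquisitionGeometry, OpticalObject, PhaseShiftSeries, VolumeStack

__all__ = [
    "simulate_bead_phase",
    "simulate_spheroid_phantom",
    "simulate_edge_target",
    "simulate_dic_frames",
    "simulate_tile_grid",
    "analytic_gradient",
    "shear_shift",
]

_GEOMETRY_FACTOR = {"transmission": 1.0, "reflection": 2.0}


def simulate_bead_phase(
    d: float,
    n: float,
    n0: float,
    wavelength: float,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch: float = 0.1,
    geometry: str = "transmission",
    supersample: int = 3,
) -> OpticalObject:
    """Projected-thickness phase map of a spherical bead.

    A sphere of diameter ``d`` and index ``n`` immersed in medium ``n0``
    imposes the phase ``phi(r) = g * (2 pi / lambda) * t(r) * (n - n0)`` on a
    plane wave, where ``t(r) = 2 sqrt((d/2)^2 - rho^2)`` is the chord length
    at lateral distance ``rho`` from the bead centre. The geometry factor is
    g = 1 in transmission and g = 2 in reflection (double pass off a mirror).

    Parameters
    ----------
    d, n, n0, wavelength
        Bead diameter (um), bead and medium refractive indices, and centre
        wavelength (um).
    shape, pixel_pitch
        Output grid (ny, nx) and lateral sampling (um / px).
    geometry
        'transmission' or 'reflection'.
    supersample
        Linear oversampling factor used to anti-alias the bead edge.

    Returns
    -------
    OpticalObject
        With peak phase ``g * (2 pi / lambda) * d * (n - n0)`` at the centre.
    """
    if d <= 0 or wavelength <= 0:
        raise ValueError("bead diameter and wavelength must be positive")
    if geometry not in _GEOMETRY_FACTOR:
        raise ValueError("geometry must be 'transmission' or 'reflection'")
    if d / pixel_pitch < 8:
        warnings.warn("bead is sampled by fewer than 8 pixels across", stacklevel=2)

    g = _GEOMETRY_FACTOR[geometry]
    ny, nx = shape
    s = max(int(supersample), 1)
    # Supersampled pixel-centre coordinates relative to the grid centre (um).
    yy = (np.arange(ny * s) + 0.5) / s - ny / 2.0
    xx = (np.arange(nx * s) + 0.5) / s - nx / 2.0
    rho2 = (yy[:, None] ** 2 + xx[None, :] ** 2) * pixel_pitch**2
    r2 = (d / 2.0) ** 2
    chord = 2.0 * np.sqrt(np.maximum(r2 - rho2, 0.0))
    phase = g * (2.0 * np.pi / wavelength) * (n - n0) * chord
    if s > 1:
        phase = phase.reshape(ny, s, nx, s).mean(axis=(1, 3))
    meta = {"d": d, "n": n, "n0": n0, "wavelength": wavelength, "geometry": geometry}
    return OpticalObject(phase_map=phase, pixel_pitch=pixel_pitch, truth_meta=meta)


def simulate_edge_target(
    edge_angle: float = 0.0,
    blur_sigma: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    pixel_pitch: float = 0.1,
    step_height: float = 1.0,
) -> OpticalObject:
    """Phase-step (micropillar edge) target for edge-spread analysis.

    The step rises across a straight line through the grid centre whose
    normal makes ``edge_angle`` degrees with the shear (+x) axis: at 0 deg
    the edge line runs along y and the full step gradient lies along the
    shear; at 90 deg the edge is parallel to the shear and produces no
    contrast along it. With ``blur_sigma > 0`` (um) the ideal step is
    replaced by its convolution with an isotropic Gaussian, i.e. the profile
    ``step_height * Phi(s / sigma)`` of the signed distance ``s``.
    """
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be >= 0")
    ny, nx = shape
    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    theta = np.deg2rad(edge_angle)
    s = ((x - nx / 2.0 + 0.5) * np.cos(theta) + (y - ny / 2.0 + 0.5) * np.sin(theta)) * pixel_pitch
    if blur_sigma == 0:
        phase = step_height * (s > 0).astype(float)
    else:
        phase = step_height * special.ndtr(s / blur_sigma)
    meta = {"edge_angle": edge_angle, "blur_sigma": blur_sigma, "step_height": step_height}
    return OpticalObject(phase_map=phase, pixel_pitch=pixel_pitch, truth_meta=meta)


def simulate_spheroid_phantom(
    layer_thickness: float,
    layers_per_region: list[int],
    shape: tuple[int, int] = (96, 96),
    z_count: int = 12,
    z_spacing: float = 5.0,
    pixel_pitch: float = 1.0,
    focus_sigma: float | None = None,
    seed: int = 0,
) -> tuple[VolumeStack, np.ndarray, np.ndarray]:
    """Multilayer-culture z-stack with plateau regions of known height.

    Emulates a through-focus scan of flat cell plateaus whose thicknesses
    are integer multiples of one cell-layer thickness: each lateral region
    carries a static random texture whose contrast is maximal at the axial
    slice nearest its true height (Gaussian focus envelope), so a windowed
    variance focus metric recovers the plateau height.

    Returns
    -------
    stack : VolumeStack
        (z_count, ny, nx) with ``sampling = (z_spacing, pitch, pitch)``.
    truth_height : 2D array
        Ground-truth height in micrometres per pixel.
    labels : 2D int array
        Region label per pixel (0-based vertical strips).
    """
    if layer_thickness <= 0:
        raise ValueError("layer_thickness must be > 0")
    if z_count < 2 or z_spacing <= 0:
        raise ValueError("need at least 2 slices with positive z_spacing")
    heights = np.asarray(layers_per_region, dtype=float) * layer_thickness
    z_max = (z_count - 1) * z_spacing
    if heights.max(initial=0.0) > z_max:
        raise ValueError(
            f"z range {z_max} um does not cover the tallest region ({heights.max()} um)"
        )
    if focus_sigma is None:
        focus_sigma = 0.75 * z_spacing

    rng = np.random.default_rng(seed)
    ny, nx = shape
    n_regions = len(layers_per_region)
    labels = np.minimum((np.arange(nx) * n_regions) // nx, n_regions - 1)
    labels = np.broadcast_to(labels[None, :], (ny, nx)).copy()
    truth = heights[labels]

    texture = rng.standard_normal((ny, nx))
    z = np.arange(z_count) * z_spacing
    envelope = np.exp(-0.5 * ((z[:, None, None] - truth[None]) / focus_sigma) ** 2)
    data = texture[None] * envelope
    stack = VolumeStack(data=data, sampling=(z_spacing, pixel_pitch, pixel_pitch))
    return stack, truth, labels


def shear_shift(field: np.ndarray, geom: AcquisitionGeometry, pixel_pitch: float) -> np.ndarray:
    """Evaluate ``f(r + dr)`` on the pixel grid by band-limited interpolation.

    The shear ``delta r`` is typically a fraction of a pixel, so the shifted
    copy is obtained by a frequency-domain (sinc) shift rather than by
    resampling on integer pixels.
    """
    shift_px = geom.shear_distance / pixel_pitch
    axis = 1 if geom.shear_axis == "x" else 0
    vec = [0.0, 0.0]
    vec[axis] = -shift_px  # sampling at r + dr pulls content from +dr
    return fourier_shift(field, tuple(vec))


def analytic_gradient(obj: OpticalObject, geom: AcquisitionGeometry) -> np.ndarray:
    """Ground-truth sheared phase difference ``phi(r + dr) - phi(r)``.

    This is the quantity phase retrieval should recover; it serves as the
    round-trip oracle for noiseless simulations.
    """
    return shear_shift(obj.phase_map, geom, obj.pixel_pitch) - obj.phase_map


def simulate_dic_frames(
    obj: OpticalObject,
    geom: AcquisitionGeometry,
    epsilons: list[float],
    amplitude: float | np.ndarray = 1.0,
    incoherent_bg: float | np.ndarray = 0.0,
    noise: str = "none",
    photons_per_unit: float = 1e4,
    read_sigma: float = 0.0,
    seed: int | None = None,
) -> PhaseShiftSeries:
    """Phase-shifted interferogram series for an optical object.

    Each frame evaluates the two-beam interference law with the sheared
    copies ``I(r + dr)``, ``phi(r + dr)`` obtained by band-limited shift,
    plus the non-modulating incoherent background (identical in every frame)
    and, optionally, seeded shot + read noise.

    Parameters
    ----------
    amplitude
        Single-beam intensity I(r); scalar or 2D map, must be >= 0.
    incoherent_bg
        Additive non-modulating background (multiple-scattering term).
    noise
        'none' or 'shot+read'. Shot noise is Poisson at ``photons_per_unit``
        counts per intensity unit; read noise is additive Gaussian with
        standard deviation ``read_sigma`` (intensity units). Negative noisy
        counts are clipped at zero. Requires ``seed`` for reproducibility.
    """
    if np.min(amplitude) < 0 or np.min(incoherent_bg) < 0:
        raise ValueError("amplitude and incoherent background must be >= 0")
    if noise not in ("none", "shot+read"):
        raise ValueError("noise must be 'none' or 'shot+read'")

    shape = obj.phase_map.shape
    intensity = np.broadcast_to(np.asarray(amplitude, dtype=float), shape)
    bg = np.broadcast_to(np.asarray(incoherent_bg, dtype=float), shape)
    phi = obj.phase_map
    phi_shift = shear_shift(phi, geom, obj.pixel_pitch)
    i_shift = (
        np.clip(shear_shift(intensity, geom, obj.pixel_pitch), 0.0, None)
        if np.ptp(intensity) > 0
        else intensity
    )
    phi_b = geom.background_map(shape, obj.pixel_pitch)
    total = phi_shift - phi + phi_b + geom.static_bias

    rng = np.random.default_rng(seed) if noise != "none" else None
    frames = []
    cross = 2.0 * np.sqrt(intensity * i_shift)
    for eps in epsilons:
        frame = intensity + i_shift + cross * np.cos(total + eps) + bg
        if rng is not None:
            counts = rng.poisson(np.clip(frame, 0, None) * photons_per_unit)
            frame = counts / photons_per_unit
            if read_sigma > 0:
                frame = frame + rng.normal(0.0, read_sigma, size=shape)
            frame = np.clip(frame, 0.0, None)
        frames.append(frame)
    return PhaseShiftSeries(
        frames=frames,
        epsilons=list(epsilons),
        geometry=geom,
        pixel_pitch=obj.pixel_pitch,
        background_incoherent=incoherent_bg,
    )


def simulate_tile_grid(
    obj: OpticalObject,
    tile_shape: tuple[int, int],
    overlap_fraction: float,
    grid_shape: tuple[int, int] = (2, 2),
    true_offsets: np.ndarray | None = None,
    jitter: int = 0,
    seed: int | None = None,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Crop a tile grid with known positions out of a source object.

    Tiles are cut from ``obj.phase_map`` on a regular grid with the given
    overlap; ``true_offsets`` (n_tiles, 2) in (dy, dx) pixels overrides the
    regular placement, and ``jitter`` adds a seeded uniform integer
    perturbation of up to +/- jitter pixels to each non-anchor tile.

    Returns the tiles (row-major) and the exact (dy, dx) offset of each tile
    relative to the source origin — the stitching ground truth.
    """
    if overlap_fraction < 0.1:
        raise ValueError("overlap_fraction must be >= 0.1")
    th, tw = tile_shape
    src = obj.phase_map
    if true_offsets is None:
        rows, cols = grid_shape
        step_y = int(round(th * (1 - overlap_fraction)))
        step_x = int(round(tw * (1 - overlap_fraction)))
        offsets = np.array(
            [[r * step_y, c * step_x] for r in range(rows) for c in range(cols)], dtype=int
        )
        if jitter > 0:
            rng = np.random.default_rng(seed)
            pert = rng.integers(-jitter, jitter + 1, size=offsets.shape)
            pert[0] = 0
            offsets = np.clip(offsets + pert, 0, None)
    else:
        offsets = np.asarray(true_offsets, dtype=int)
    if offsets.min() < 0:
        raise ValueError("tile offsets must be non-negative")
    if offsets[:, 0].max() + th > src.shape[0] or offsets[:, 1].max() + tw > src.shape[1]:
        raise ValueError("tile grid does not fit inside the source object")
    tiles = [src[dy : dy + th, dx : dx + tw].copy() for dy, dx in offsets]
    return tiles, offsets
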