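"""Quantitative phase-gradient retrieval from phase-shifted interferograms.

Given N >= 3 intensity frames acquired at known interferometric modulations
``eps_n``, each pixel follows ``I_n = A + B cos(theta + eps_n)`` with total
argument ``theta = delta_phi + phi_b + phi_0``. The four-frame quadrature
formula and a generalized per-pixel least-squares solver both recover theta;
the static bias phi_0 is subtracted immediately, and the slowly varying
instrumental background phi_b is removed by high-pass filtering.

Because the measured quantity is a phase *difference* across a
sub-diffraction shear, it stays inside (-pi, pi] for realistic specimens and
no 2D phase unwrapping is performed anywhere in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._utils import wrap_phase
from .datatypes import PhaseShiftSeries

__all__ = [
    "GradientPhaseMap",
    "retrieve_gradient_4frame",
    "retrieve_gradient_lsq",
    "remove_slant_background",
    "denoise",
    "CalibrationError",
    "DegenerateCalibrationError",
]

_CANONICAL_EPS = np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2])


class CalibrationError(ValueError):
    """Phase-shift values incompatible with the requested solver."""


class DegenerateCalibrationError(CalibrationError):
    """Epsilon set spans fewer than three independent modulation states."""


@dataclass
class GradientPhaseMap:
    """Retrieved sheared phase-difference map with its modulation maps.

    Attributes
    ----------
    delta_phi
        ``phi(r + dr) - phi(r)`` in radians, wrapped to (-pi, pi].
    shear_distance, shear_axis
        Shear magnitude (um) and direction inherited from the acquisition.
    amplitude_map
        Interferometric modulation amplitude B(r) >= 0 (the term
        ``2 sqrt(I(r) I(r + dr))`` of the interference law).
    dc_map
        Non-modulating intensity A(r) >= 0 (``I(r) + I(r + dr)`` plus any
        incoherent background).
    validity
        Boolean mask, False where modulation was too weak to define a phase.
    bias_removed
        True once the slant background has been high-pass filtered away.
    pixel_pitch
        Lateral sampling in um / px.
    """

    delta_phi: np.ndarray
    shear_distance: float
    shear_axis: str = "x"
    amplitude_map: np.ndarray | None = None
    dc_map: np.ndarray | None = None
    validity: np.ndarray | None = None
    bias_removed: bool = False
    pixel_pitch: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta_phi = np.asarray(self.delta_phi, dtype=float)
        if self.validity is None:
            self.validity = np.ones(self.delta_phi.shape, dtype=bool)


def _modulation_floor(frames: np.ndarray, rel_floor: float) -> float:
    peak = float(np.max(np.abs(frames))) if frames.size else 0.0
    return rel_floor * peak


def retrieve_gradient_4frame(
    series: PhaseShiftSeries,
    phi_0: float | None = None,
    eps_tolerance: float = 1e-3,
    modulation_floor: float = 1e-6,
) -> GradientPhaseMap:
    """Quadrature (four-frame) phase retrieval.

    Requires exactly four frames at modulations (0, pi/2, pi, 3 pi/2) within
    ``eps_tolerance`` radians. Per pixel,

        theta = atan2(I_{3pi/2} - I_{pi/2}, I_0 - I_pi)
        delta_phi = wrap(theta - phi_0)
        A = mean of the four frames
        B = 0.5 * sqrt((I_0 - I_pi)^2 + (I_{3pi/2} - I_{pi/2})^2)

    Pixels whose modulation B falls below ``modulation_floor`` times the peak
    frame value get delta_phi = 0 and are flagged invalid (keeping downstream
    Fourier transforms finite).

    phi_0 defaults to the acquisition geometry's static bias (pi for a
    dark-background Nomarski setting).
    """
    if len(series.frames) != 4:
        raise CalibrationError(
            "four-frame retrieval needs exactly 4 frames; use retrieve_gradient_lsq"
        )
    eps = np.asarray(series.epsilons, dtype=float)
    if np.max(np.abs(wrap_phase(eps - _CANONICAL_EPS))) > eps_tolerance:
        raise CalibrationError(
            "epsilons deviate from (0, pi/2, pi, 3pi/2) beyond tolerance; "
            "use retrieve_gradient_lsq"
        )
    if phi_0 is None:
        phi_0 = series.geometry.static_bias

    i0, i1, i2, i3 = series.frames
    cos_term = i0 - i2
    sin_term = i3 - i1
    theta = np.arctan2(sin_term, cos_term)
    amplitude = 0.5 * np.hypot(cos_term, sin_term)
    dc = (i0 + i1 + i2 + i3) / 4.0

    floor = _modulation_floor(series.as_array(), modulation_floor)
    valid = amplitude > floor
    delta_phi = np.where(valid, wrap_phase(theta - phi_0), 0.0)
    return GradientPhaseMap(
        delta_phi=delta_phi,
        shear_distance=series.geometry.shear_distance,
        shear_axis=series.geometry.shear_axis,
        amplitude_map=amplitude,
        dc_map=dc,
        validity=valid,
        pixel_pitch=series.pixel_pitch,
        meta={"method": "4frame", "phi_0": phi_0},
    )


def retrieve_gradient_lsq(
    series: PhaseShiftSeries,
    phi_0: float | None = None,
    modulation_floor: float = 1e-6,
) -> GradientPhaseMap:
    """Generalized phase-shifting retrieval by per-pixel least squares.

    Solves ``I_n = a + b cos(eps_n) + c sin(eps_n)`` for every pixel (one
    shared 3x3 normal system, since the design depends only on the eps set)
    and takes ``theta = atan2(-c, b)``, ``B = hypot(b, c)``, ``A = a``. This
    stays correct when the modulation steps differ from exact 90-degree
    increments. When the eps set *is* the canonical quadrature set (within
    1e-9 rad) the solver reduces algebraically to the four-frame formula and
    delegates to it, so the two paths agree bit-for-bit there.
    """
    eps = np.asarray(series.epsilons, dtype=float)
    if len(eps) == 4 and np.max(np.abs(wrap_phase(eps - _CANONICAL_EPS))) < 1e-9:
        out = retrieve_gradient_4frame(
            series, phi_0=phi_0, modulation_floor=modulation_floor
        )
        out.meta["method"] = "lsq(4frame reduction)"
        return out
    if phi_0 is None:
        phi_0 = series.geometry.static_bias

    design = np.column_stack([np.ones_like(eps), np.cos(eps), np.sin(eps)])
    svals = np.linalg.svd(design, compute_uv=False)
    if svals[-1] < 1e-6 * svals[0]:
        raise DegenerateCalibrationError(
            "epsilon set is degenerate: cannot separate DC, cos and sin terms"
        )
    stack = series.as_array()  # (n, ny, nx)
    flat = stack.reshape(len(eps), -1)
    coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
    a, b, c = (coef[k].reshape(series.shape) for k in range(3))

    theta = np.arctan2(-c, b)
    amplitude = np.hypot(b, c)
    floor = _modulation_floor(stack, modulation_floor)
    valid = amplitude > floor
    delta_phi = np.where(valid, wrap_phase(theta - phi_0), 0.0)
    return GradientPhaseMap(
        delta_phi=delta_phi,
        shear_distance=series.geometry.shear_distance,
        shear_axis=series.geometry.shear_axis,
        amplitude_map=amplitude,
        dc_map=np.clip(a, 0.0, None),
        validity=valid,
        pixel_pitch=series.pixel_pitch,
        meta={"method": "lsq", "phi_0": phi_0},
    )


def remove_slant_background(
    gmap: GradientPhaseMap, cutoff_fraction: float = 0.1
) -> GradientPhaseMap:
    """High-pass filter away the slant-like instrumental background.

    The DIC optics superpose a slowly varying, essentially planar background
    phi_b on the gradient map. It is estimated as the best-fit plane plus a
    Gaussian low-pass (sigma = ``cutoff_fraction`` times the image size) of
    the residual, and subtracted; the explicit plane term keeps the removal
    exact at the image borders, where a finite-window low-pass alone would
    under-fit a ramp. The output has (numerically) zero mean and its
    ``bias_removed`` flag set.
    """
    if not 0 < cutoff_fraction < 0.5:
        raise ValueError("cutoff_fraction must lie in (0, 0.5)")
    data = gmap.delta_phi
    ny, nx = data.shape
    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    design = np.column_stack([x.ravel(), y.ravel(), np.ones(data.size)])
    coef, *_ = np.linalg.lstsq(design, data.ravel(), rcond=None)
    plane = (design @ coef).reshape(data.shape)
    residual = data - plane
    sigma = (cutoff_fraction * ny, cutoff_fraction * nx)
    lowpass = ndimage.gaussian_filter(residual, sigma=sigma, mode="nearest")
    out = residual - lowpass
    out -= out.mean()
    return GradientPhaseMap(
        delta_phi=out,
        shear_distance=gmap.shear_distance,
        shear_axis=gmap.shear_axis,
        amplitude_map=gmap.amplitude_map,
        dc_map=gmap.dc_map,
        validity=gmap.validity,
        bias_removed=True,
        pixel_pitch=gmap.pixel_pitch,
        meta={**gmap.meta, "highpass_cutoff_fraction": cutoff_fraction},
    )


def denoise(
    data: GradientPhaseMap | np.ndarray, method: str = "none", size: float = 3
) -> GradientPhaseMap | np.ndarray:
    """Spatial denoising of a gradient map or a raw frame.

    method 'none' is the identity; 'median' applies a square median filter of
    side ``size`` pixels; 'gaussian' applies an isotropic Gaussian of
    standard deviation ``size`` pixels.
    """
    if method not in ("none", "median", "gaussian"):
        raise ValueError(f"unknown denoise method {method!r}")
    if size < 1 and method == "median":
        raise ValueError("median size must be >= 1")
    arr = data.delta_phi if isinstance(data, GradientPhaseMap) else np.asarray(data)
    if method == "none":
        out = arr
    elif method == "median":
        out = ndimage.median_filter(arr, size=int(size), mode="reflect")
    else:
        out = ndimage.gaussian_filter(arr, sigma=float(size), mode="reflect")
    if isinstance(data, GradientPhaseMap):
        return GradientPhaseMap(
            delta_phi=out,
            shear_distance=data.shear_distance,
            shear_axis=data.shear_axis,
            amplitude_map=data.amplitude_map,
            dc_map=data.dc_map,
            validity=data.validity,
            bias_removed=data.bias_removed,
            pixel_pitch=data.pixel_pitch,
            meta={**data.meta, "denoise": (method, size)},
        )
    return out
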