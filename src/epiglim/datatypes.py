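"""Core data containers shared across the reconstruction pipeline.

Conventions (used package-wide): axis order is (z, y, x); the DIC shear runs
along +x by default; pixel indices are 0-based; lengths are in micrometres and
phases in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from ._utils import TWO_PI


@dataclass
class OpticalObject:
    """A ground-truth 2D optical phase map with its lateral sampling.

    Parameters
    ----------
    phase_map
        Optical phase in radians, shape (ny, nx). Must be finite everywhere.
    pixel_pitch
        Lateral sampling in micrometres per pixel (> 0).
    truth_meta
        Free-form record of the generating parameters (e.g. bead diameter,
        refractive indices, wavelength) kept for round-trip validation.
    """

    phase_map: np.ndarray
    pixel_pitch: float
    truth_meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.phase_map = np.asarray(self.phase_map, dtype=float)
        if self.phase_map.ndim != 2:
            raise ValueError("phase_map must be 2D (ny, nx)")
        if not np.all(np.isfinite(self.phase_map)):
            raise ValueError("phase_map must be finite everywhere")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be > 0")


@dataclass
class AcquisitionGeometry:
    """Interferometric acquisition geometry for a sheared-beam (DIC) system.

    Parameters
    ----------
    shear_distance
        Lateral beam shear ``delta r`` in micrometres (> 0); sub-diffraction
        in a well-configured instrument.
    shear_axis
        'x' (default) or 'y'.
    static_bias
        Constant interferometric offset ``phi_0`` set by the Nomarski prism
        position. Defaults to pi so the specimen is measured against a dark
        background.
    slant_background
        The slowly varying instrumental background ``phi_b``: either a 2D
        array of radians or a plane ``(a, b, c)`` meaning ``a*x + b*y + c``
        with x, y in micrometres.
    geometry
        'transmission' or 'reflection'. Reflection doubles the single-pass
        phase of a specimen imaged against a mirror.
    wavelength
        Centre illumination wavelength in micrometres.
    """

    shear_distance: float
    shear_axis: str = "x"
    static_bias: float = np.pi
    slant_background: np.ndarray | tuple[float, float, float] | None = None
    geometry: str = "transmission"
    wavelength: float = 0.490

    def __post_init__(self) -> None:
        if not self.shear_distance > 0:
            raise ValueError("shear_distance must be > 0")
        if self.shear_axis not in ("x", "y"):
            raise ValueError("shear_axis must be 'x' or 'y'")
        if self.geometry not in ("transmission", "reflection"):
            raise ValueError("geometry must be 'transmission' or 'reflection'")
        # A shear larger than ~ the diffraction spot (lambda / 2 NA, NA <= 1)
        # defeats the gradient approximation; warn rather than refuse.
        if self.wavelength > 0 and self.shear_distance > self.wavelength:
            warnings.warn(
                "shear_distance exceeds the illumination wavelength; the "
                "measured signal will no longer approximate a phase gradient",
                stacklevel=2,
            )

    def background_map(self, shape: tuple[int, int], pixel_pitch: float) -> np.ndarray:
        """Materialise ``phi_b`` on a pixel grid of the given shape."""
        if self.slant_background is None:
            return np.zeros(shape)
        if isinstance(self.slant_background, np.ndarray):
            if self.slant_background.shape != shape:
                raise ValueError("slant_background array shape mismatch")
            return self.slant_background
        a, b, c = self.slant_background
        y, x = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float) * pixel_pitch
        return a * x + b * y + c


@dataclass
class PhaseShiftSeries:
    """An ordered set of intensity frames with their phase shifts.

    ``frames[n]`` was acquired with interferometric modulation ``epsilons[n]``
    (radians). Frames are non-negative and share one shape; at least three
    distinct modulation values (mod 2 pi) are required for phase retrieval.
    """

    frames: list[np.ndarray]
    epsilons: list[float]
    geometry: AcquisitionGeometry
    pixel_pitch: float = 1.0
    background_incoherent: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        self.epsilons = [float(e) for e in self.epsilons]
        if len(self.frames) != len(self.epsilons):
            raise ValueError("frames and epsilons must have the same length")
        if len(self.frames) < 3:
            raise ValueError("need at least 3 phase-shifted frames")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share one shape")
        if any(np.min(f) < 0 for f in self.frames):
            raise ValueError("intensities must be non-negative")
        eps = np.mod(self.epsilons, TWO_PI)
        if len(np.unique(np.round(eps, 9))) < 3:
            raise ValueError("need at least 3 distinct epsilon values mod 2*pi")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    def as_array(self) -> np.ndarray:
        """Stack frames into one (n_frames, ny, nx) array."""
        return np.stack(self.frames, axis=0)


@dataclass
class VolumeStack:
    """A 3D scalar field (phase or intensity) with physical sampling.

    ``data`` is ordered (z, y, x); ``sampling = (dz, dy, dx)`` in micrometres;
    ``z0`` is the axial coordinate of the first slice.
    """

    data: np.ndarray
    sampling: tuple[float, float, float] = (1.0, 1.0, 1.0)
    z0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VolumeStack data must be 3D (z, y, x)")
        if any(s <= 0 for s in self.sampling):
            raise ValueError("sampling steps must be > 0")

    @property
    def z_coords(self) -> np.ndarray:
        """Axial coordinate of every slice, in micrometres."""
        return self.z0 + np.arange(self.data.shape[0]) * self.sampling[0]
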