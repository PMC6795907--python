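"""Shared numerical helpers: phase wrapping and band-limited shifts."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

TWO_PI = 2.0 * np.pi


def wrap_phase(x: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase values into the principal interval (-pi, pi].

    The convention matters at the branch point: -pi maps to +pi so that the
    interval is half-open on the left, matching ``atan2``-style outputs.
    """
    w = np.mod(np.asarray(x, dtype=float) + np.pi, TWO_PI) - np.pi
    # np.mod puts the result in [-pi, pi); fold the single excluded endpoint.
    w = np.where(w == -np.pi, np.pi, w)
    if np.isscalar(x):
        return float(w)
    return w


def fourier_shift(image: np.ndarray, shift: tuple[float, ...]) -> np.ndarray:
    """Band-limited (sinc-interpolated) circular shift of a real array.

    ``shift`` is expressed in pixels per axis, positive values moving content
    toward increasing indices. Exact for band-limited periodic signals, which
    is what sub-pixel DIC shear (``delta r`` below one pixel pitch) requires.
    """
    image = np.asarray(image, dtype=float)
    out = ndimage.fourier_shift(np.fft.fftn(image), shift)
    return np.real(np.fft.ifftn(out))


def parabolic_peak_1d(ym: float, y0: float, yp: float) -> float:
    """Sub-sample offset of a local maximum from three samples around it.

    Fits a parabola through (-1, ym), (0, y0), (1, yp); returns the vertex
    abscissa clipped to [-0.5, 0.5]. Degenerate (flat) neighborhoods give 0.
    """
    denom = ym - 2.0 * y0 + yp
    if denom == 0:
        return 0.0
    delta = 0.5 * (ym - yp) / denom
    return float(np.clip(delta, -0.5, 0.5))


def subpixel_argmax(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Locate the maximum of a correlation surface with parabolic refinement.

    Returns the refined peak position (float per axis, in array coordinates,
    wrapping ignored) and the peak value. Works for any dimensionality.
    """
    corr = np.asarray(corr)
    idx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    pos = []
    for ax, i in enumerate(idx):
        n = corr.shape[ax]
        sl = list(idx)
        sl[ax] = (i - 1) % n
        ym = corr[tuple(sl)]
        sl[ax] = (i + 1) % n
        yp = corr[tuple(sl)]
        pos.append(i + parabolic_peak_1d(float(ym), float(corr[idx]), float(yp)))
    return np.asarray(pos), float(corr[idx])


def wrap_offset(pos: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Map array-coordinate peak positions to signed offsets.

    Correlation peaks live on a periodic grid; offsets beyond half the array
    size alias to negative shifts.
    """
    pos = np.asarray(pos, dtype=float)
    shape_arr = np.asarray(shape, dtype=float)
    return np.where(pos > shape_arr / 2.0, pos - shape_arr, pos)
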