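"""Large-field mosaicking: flat-field, phase correlation, global placement.

Tiles scanned on a motorized stage are assembled in four steps: a
sample-free background (flat-field) estimate is subtracted from every tile;
tiles are band-pass filtered in the Fourier domain to stabilize correlation
peaks; pairwise translations between overlapping neighbors are measured by
phase correlation (normalized cross-power spectrum) with parabolic sub-pixel
refinement; and the tile positions are solved globally by least squares on
the pairwise-offset graph, anchored at the first tile, before feathered
(linear-ramp) blending into the final mosaic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._utils import parabolic_peak_1d

__all__ = [
    "TileGrid",
    "flat_field",
    "fourier_bandpass",
    "phase_correlate",
    "assemble_mosaic",
    "StitchingGraphError",
]


class StitchingGraphError(ValueError):
    """The tile overlap graph is disconnected; no global placement exists."""


@dataclass
class TileGrid:
    """A rectangular grid of equally shaped tiles with nominal positions.

    ``nominal_offsets`` holds the expected (dy, dx) pixel offset of each tile
    relative to the mosaic origin (row-major tile order), typically derived
    from stage coordinates; ``grid_shape`` is (rows, cols).
    """

    tiles: list[np.ndarray]
    grid_shape: tuple[int, int]
    nominal_offsets: np.ndarray
    overlap_fraction: float = 0.1
    pixel_pitch: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tiles = [np.asarray(t, dtype=float) for t in self.tiles]
        if len(self.tiles) != self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("tile count does not match grid shape")
        shape = self.tiles[0].shape
        if any(t.shape != shape for t in self.tiles):
            raise ValueError("all tiles must share one shape")
        if self.overlap_fraction < 0.05:
            raise ValueError("overlap_fraction must be >= 0.05")
        self.nominal_offsets = np.asarray(self.nominal_offsets, dtype=float)
        if self.nominal_offsets.shape != (len(self.tiles), 2):
            raise ValueError("nominal_offsets must be (n_tiles, 2)")

    @property
    def tile_shape(self) -> tuple[int, int]:
        return self.tiles[0].shape


def flat_field(grid: TileGrid, background: np.ndarray | str = "median") -> TileGrid:
    """Subtract a sample-free background estimate from every tile.

    ``background`` is either an explicit background tile or the string
    'median', which takes the pixelwise median across all tiles — a robust
    estimate of the common fixed pattern when most tiles are mostly empty.
    """
    if isinstance(background, str):
        if background != "median":
            raise ValueError("background must be an array or 'median'")
        if len(grid.tiles) < 3:
            raise ValueError("median flat-field needs at least 3 tiles")
        bg = np.median(np.stack(grid.tiles), axis=0)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != grid.tile_shape:
            raise ValueError("background tile shape mismatch")
    return TileGrid(
        tiles=[t - bg for t in grid.tiles],
        grid_shape=grid.grid_shape,
        nominal_offsets=grid.nominal_offsets,
        overlap_fraction=grid.overlap_fraction,
        pixel_pitch=grid.pixel_pitch,
        meta={**grid.meta, "flat_field": True},
    )


def fourier_bandpass(
    tile: np.ndarray, low_fraction: float = 0.02, high_fraction: float = 0.10
) -> np.ndarray:
    """Band-pass a tile: drop DC plus the lowest and highest frequencies.

    Removing the lowest ``low_fraction`` of the Nyquist band suppresses
    illumination gradients that bias the correlation peak; removing the top
    ``high_fraction`` suppresses pixel noise. Fractions are of the Nyquist
    frequency; both cuts are soft (Gaussian shoulders) to avoid ringing.
    """
    tile = np.asarray(tile, dtype=float)
    fy = np.fft.fftfreq(tile.shape[0])[:, None]
    fx = np.fft.fftfreq(tile.shape[1])[None, :]
    r = np.hypot(fy, fx) / 0.5  # radius as a fraction of Nyquist
    lo = 1.0 - np.exp(-0.5 * (r / max(low_fraction, 1e-9)) ** 2)
    hi = np.exp(-0.5 * (np.clip(r - (1.0 - high_fraction), 0, None) / 0.05) ** 2)
    spec = np.fft.fft2(tile) * lo * hi
    return np.real(np.fft.ifft2(spec))


def phase_correlate(
    a: np.ndarray, b: np.ndarray, eps: float = 1e-12
) -> tuple[tuple[float, float], float]:
    """Translation of ``b`` relative to ``a`` by phase correlation.

    Computes the normalized cross-power spectrum, inverse-transforms it, and
    refines the correlation peak with a per-axis parabolic fit. The returned
    offset (dy, dx) satisfies ``b(y, x) ~= a(y - dy, x - dx)``: it is the
    displacement of b's content relative to a's. Confidence is the ratio of
    the main peak to the strongest secondary peak (outside the main peak's
    immediate neighborhood); pure translations of rich content give large
    ratios, featureless or ambiguous content gives values near 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("inputs must share one shape")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant input carries no registration signal")
    fa = np.fft.fft2(a)
    fb = np.fft.fft2(b)
    cross = fb * np.conj(fa)
    corr = np.real(np.fft.ifft2(cross / (np.abs(cross) + eps)))

    peak_idx = np.unravel_index(int(np.argmax(corr)), corr.shape)
    peak_val = float(corr[peak_idx])
    offset = []
    for ax, i in enumerate(peak_idx):
        n = corr.shape[ax]
        sl = list(peak_idx)
        sl[ax] = (i - 1) % n
        ym = float(corr[tuple(sl)])
        sl[ax] = (i + 1) % n
        yp = float(corr[tuple(sl)])
        pos = i + parabolic_peak_1d(ym, peak_val, yp)
        offset.append(pos - n if pos > n / 2 else pos)

    # Secondary peak: blank a 5x5 neighborhood around the main peak.
    masked = corr.copy()
    yy = (np.arange(-2, 3) + peak_idx[0]) % corr.shape[0]
    xx = (np.arange(-2, 3) + peak_idx[1]) % corr.shape[1]
    masked[np.ix_(yy, xx)] = -np.inf
    second = float(np.max(masked))
    confidence = peak_val / second if second > 0 else np.inf
    return (offset[0], offset[1]), confidence


def _neighbor_pairs(grid_shape: tuple[int, int]) -> list[tuple[int, int]]:
    rows, cols = grid_shape
    pairs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                pairs.append((i, i + 1))
            if r + 1 < rows:
                pairs.append((i, i + cols))
    return pairs


def _overlap_windows(
    ta: np.ndarray, tb: np.ndarray, dy: int, dx: int, margin: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """Co-located windows of two tiles assuming tile b sits at (dy, dx).

    Extracts the overlap region of tile a (expanded by ``margin`` pixels
    where the tiles allow it) and the congruent window of tile b. Returns
    None when the assumed offset leaves no usable overlap.
    """
    th, tw = ta.shape
    ay0 = max(0, dy - margin) if dy >= 0 else 0
    ay1 = th if dy >= 0 else min(th, th + dy + margin)
    ax0 = max(0, dx - margin) if dx >= 0 else 0
    ax1 = tw if dx >= 0 else min(tw, tw + dx + margin)
    # Keep the congruent b-window inside tile b.
    ay0, ay1 = max(ay0, dy), min(ay1, th + dy)
    ax0, ax1 = max(ax0, dx), min(ax1, tw + dx)
    if ay1 - ay0 < 8 or ax1 - ax0 < 8:
        return None
    win_a = ta[ay0:ay1, ax0:ax1]
    win_b = tb[ay0 - dy : ay1 - dy, ax0 - dx : ax1 - dx]
    return win_a, win_b


def _constrained_peak(
    a: np.ndarray, b: np.ndarray, limit: int, eps: float = 1e-12
) -> tuple[tuple[float, float], float]:
    """Phase-correlation peak restricted to shifts within ``+/- limit`` px.

    Identical to :func:`phase_correlate` except that the peak (and the
    secondary peak defining the confidence) are searched only inside the
    allowed shift window. Used when a nominal stage position bounds the
    plausible displacement: spurious far-field peaks from noise or repeated
    texture are excluded by construction, and among equal peaks the search
    order favors the one closest to the prediction.
    """
    fa = np.fft.fft2(np.asarray(a, dtype=float))
    fb = np.fft.fft2(np.asarray(b, dtype=float))
    cross = fb * np.conj(fa)
    corr = np.real(np.fft.ifft2(cross / (np.abs(cross) + eps)))
    ny, nx = corr.shape
    sy = np.minimum(np.arange(ny), ny - np.arange(ny))  # |signed shift| per row
    sx = np.minimum(np.arange(nx), nx - np.arange(nx))
    allowed = (sy[:, None] <= limit) & (sx[None, :] <= limit)
    masked = np.where(allowed, corr, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(masked)), corr.shape)
    peak_val = float(corr[peak_idx])
    offset = []
    for ax, i in enumerate(peak_idx):
        n = corr.shape[ax]
        sl = list(peak_idx)
        sl[ax] = (i - 1) % n
        ym = float(corr[tuple(sl)])
        sl[ax] = (i + 1) % n
        yp = float(corr[tuple(sl)])
        pos = i + parabolic_peak_1d(ym, peak_val, yp)
        offset.append(pos - n if pos > n / 2 else pos)
    second = masked.copy()
    yy = (np.arange(-2, 3) + peak_idx[0]) % ny
    xx = (np.arange(-2, 3) + peak_idx[1]) % nx
    second[np.ix_(yy, xx)] = -np.inf
    second_val = float(np.max(second))
    confidence = peak_val / second_val if second_val > 0 else np.inf
    return (offset[0], offset[1]), confidence


def _phase_plane_shift(win_a: np.ndarray, win_b: np.ndarray) -> np.ndarray:
    """Sub-pixel displacement of b vs a by a weighted cross-spectrum phase fit.

    For ``win_b(y, x) = win_a(y - dy, x - dx)`` the cross-power phase is the
    plane ``-2 pi (fy dy + fx dx)``; fitting it by least squares weighted by
    the cross-power magnitude (restricted to |f| < 0.25, where the phase
    cannot wrap for sub-pixel displacements and the signal spectrum is
    strongest) estimates (dy, dx) with far less noise sensitivity than a
    3-point parabola on the correlation peak. Identical windows give an
    identically zero phase, hence an exactly zero shift.
    """
    hann = np.outer(np.hanning(win_a.shape[0]), np.hanning(win_a.shape[1]))
    fa = np.fft.fft2((win_a - win_a.mean()) * hann)
    fb = np.fft.fft2((win_b - win_b.mean()) * hann)
    cross = fb * np.conj(fa)
    ny, nx = cross.shape
    fy = np.broadcast_to(np.fft.fftfreq(ny)[:, None], cross.shape)
    fx = np.broadcast_to(np.fft.fftfreq(nx)[None, :], cross.shape)
    mask = (np.hypot(fy, fx) < 0.25) & (np.abs(cross) > 0)
    if mask.sum() < 8:
        return np.zeros(2)
    w = np.sqrt(np.abs(cross[mask]))
    design = np.column_stack([fy[mask], fx[mask]]) * w[:, None]
    rhs = np.angle(cross[mask]) * w
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return -sol / (2.0 * np.pi)


def _pairwise_offset(
    grid: TileGrid,
    i: int,
    j: int,
    use_nominal_prior: bool,
    bandpass: bool,
    margin: int = 8,
) -> tuple[np.ndarray, float]:
    """Measured (dy, dx) offset of tile j relative to tile i.

    Correlates Hann-windowed overlap strips (so non-shared tile content does
    not pollute the cross-power spectrum) in two passes: the first pass,
    seeded by the nominal stage offset, finds the integer displacement; the
    second re-extracts the windows at that displacement, where the residual
    shift is near zero and the sub-pixel parabolic fit is unbiased.
    """
    nominal = grid.nominal_offsets[j] - grid.nominal_offsets[i]
    ta, tb = grid.tiles[i], grid.tiles[j]
    if bandpass:
        ta, tb = fourier_bandpass(ta), fourier_bandpass(tb)
    if not use_nominal_prior:
        (ry, rx), conf = phase_correlate(ta, tb)
        return -np.array([ry, rx]), conf

    guess = np.array([int(round(nominal[0])), int(round(nominal[1]))])
    result, conf = None, 0.0
    for _ in range(4):
        wins = _overlap_windows(ta, tb, int(guess[0]), int(guess[1]), margin)
        if wins is None:
            break
        win_a, win_b = wins
        hann = np.outer(np.hanning(win_a.shape[0]), np.hanning(win_a.shape[1]))
        (ry, rx), conf = _constrained_peak(win_a * hann, win_b * hann, limit=margin)
        result = guess - np.array([ry, rx])
        new_guess = np.round(result).astype(int)
        if np.array_equal(new_guess, guess):
            # Converged on the integer displacement: replace the parabolic
            # sub-pixel estimate with the cross-spectrum phase-plane fit,
            # which is unbiased and much less noise-sensitive near zero
            # residual. Reject it if it disagrees grossly with the peak.
            residual = _phase_plane_shift(win_a, win_b)
            if np.max(np.abs(residual)) <= 1.0:
                result = guess - residual
            break
        guess = new_guess
    if result is None:
        # No usable overlap window: fall back to whole-tile correlation
        # with the periodic ambiguity resolved toward the nominal offset.
        (ry, rx), conf = phase_correlate(ta, tb)
        result = -np.array([ry, rx], dtype=float)
        for ax_, n in enumerate(grid.tile_shape):
            while result[ax_] - nominal[ax_] > n / 2:
                result[ax_] -= n
            while result[ax_] - nominal[ax_] < -n / 2:
                result[ax_] += n
    return result, conf


def assemble_mosaic(
    grid: TileGrid,
    use_nominal_prior: bool = True,
    bandpass: bool = False,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stitch a tile grid into one mosaic with a global placement solve.

    Pairwise offsets are measured on every overlapping neighbor pair, then
    the per-tile positions are the least-squares solution of the offset
    graph (equations ``p_j - p_i = o_ij`` weighted by correlation
    confidence) anchored at tile 0. Tiles are composited at their rounded
    positions with linear-feather weights (triangle window per tile), which
    reproduces the source exactly wherever aligned tiles agree.

    Returns the mosaic and a placements table with per-tile positions and
    per-pair residuals folded into a summary column.
    """
    n = len(grid.tiles)
    if n == 1:
        table = pd.DataFrame({"tile": [0], "y": [0.0], "x": [0.0], "residual": [0.0]})
        return grid.tiles[0].copy(), table

    pairs = _neighbor_pairs(grid.grid_shape)
    if not pairs:
        raise StitchingGraphError("no overlapping neighbor pairs")
    offsets, weights = [], []
    for i, j in pairs:
        off, conf = _pairwise_offset(grid, i, j, use_nominal_prior, bandpass)
        offsets.append(off)
        weights.append(min(conf, 1e3))

    # Connectivity check on the measured-pair graph.
    seen = {0}
    frontier = [0]
    adj: dict[int, list[int]] = {k: [] for k in range(n)}
    for i, j in pairs:
        adj[i].append(j)
        adj[j].append(i)
    while frontier:
        k = frontier.pop()
        for m in adj[k]:
            if m not in seen:
                seen.add(m)
                frontier.append(m)
    if len(seen) < n:
        missing = sorted(set(range(n)) - seen)
        raise StitchingGraphError(f"overlap graph disconnected; unreachable tiles {missing}")

    # Weighted least squares for positions, anchored at tile 0, with one
    # robust reweighting pass: loop-closure redundancy in the pair graph
    # exposes an offset measurement that disagrees with its cycles, and a
    # Cauchy weight (unit scale: 1 px) suppresses it in the second solve.
    def solve(wvec: np.ndarray) -> np.ndarray:
        a_mat = np.zeros((len(pairs) + 1, n))
        rhs = np.zeros((len(pairs) + 1, 2))
        a_mat[0, 0] = 1e6  # anchor p_0 = 0
        for k, ((i, j), off) in enumerate(zip(pairs, offsets), start=1):
            sw = np.sqrt(wvec[k - 1])
            a_mat[k, i] = -sw
            a_mat[k, j] = sw
            rhs[k] = off * sw
        sol, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        return sol - sol[0]

    wvec = np.asarray(weights, dtype=float)
    positions = solve(wvec)
    res = np.array(
        [np.hypot(*(positions[j] - positions[i] - off)) for (i, j), off in zip(pairs, offsets)]
    )
    if np.any(res > 0.25):
        positions = solve(wvec / (1.0 + res**2))

    residuals = np.array(
        [
            np.hypot(*(positions[j] - positions[i] - off))
            for (i, j), off in zip(pairs, offsets)
        ]
    )

    # Composite with linear-feather (triangle) weights at rounded positions.
    th, tw = grid.tile_shape
    pos_int = np.round(positions).astype(int)
    pos_int -= pos_int.min(axis=0)
    out_h = int(pos_int[:, 0].max() + th)
    out_w = int(pos_int[:, 1].max() + tw)
    wy = np.minimum(np.arange(th) + 1, th - np.arange(th))
    wx = np.minimum(np.arange(tw) + 1, tw - np.arange(tw))
    feather = np.outer(wy, wx).astype(float)
    acc = np.zeros((out_h, out_w))
    wacc = np.zeros((out_h, out_w))
    for (dy, dx), tile in zip(pos_int, grid.tiles):
        acc[dy : dy + th, dx : dx + tw] += tile * feather
        wacc[dy : dy + th, dx : dx + tw] += feather
    mosaic = np.where(wacc > 0, acc / np.where(wacc > 0, wacc, 1.0), 0.0)

    per_tile_res = np.zeros(n)
    counts = np.zeros(n)
    for (i, j), res in zip(pairs, residuals):
        per_tile_res[i] += res
        per_tile_res[j] += res
        counts[i] += 1
        counts[j] += 1
    table = pd.DataFrame(
        {
            "tile": np.arange(n),
            "y": positions[:, 0],
            "x": positions[:, 1],
            "residual": per_tile_res / np.maximum(counts, 1),
        }
    )
    return mosaic, table


def smooth_mosaic(mosaic: np.ndarray, sigma: float = 0.0) -> np.ndarray:
    """Optional cosmetic smoothing of a stitched mosaic."""
    if sigma <= 0:
        return mosaic
    return ndimage.gaussian_filter(mosaic, sigma=sigma)
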