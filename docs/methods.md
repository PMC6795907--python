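# Methods

This note documents the models, parameter choices and numerical conventions
behind `epiglim`, and what the synthetic phantoms do and do not establish
about instrument data.

## Image formation and its assumptions

The simulator evaluates the two-beam interference law per frame,

    I_n = I(r) + I(r+δr) + 2√(I(r)I(r+δr)) cos[φ(r+δr) − φ(r) + φ_b + φ_0 + ε_n],

with the sheared copies φ(r+δr), I(r+δr) obtained by frequency-domain
(sinc-interpolated) shift: the shear (0.3 µm by default) is a fraction of a
typical pixel pitch, so band-limited interpolation is the only faithful way
to evaluate the model on the pixel grid. This is also why the retrieval
oracle uses the same definition of φ(r+δr) − φ(r): the contract is exact
recovery of the sheared difference, not of an idealized derivative.

Assumptions and simplifications:

- Multiple scattering is modeled only as a **non-modulating additive
  background** (identical in all frames). There is no source-integrated
  partially coherent propagation and no vectorial model of the Nomarski
  prism. Consequently, passing tests show algebraic correctness of
  retrieval/integration/deconvolution, not radiometric realism.
- The slant background φ_b defaults to a parametric plane a·x + b·y + c.
- Noise, when requested, is Poisson shot noise (default 10⁴ counts per
  intensity unit) plus additive Gaussian read noise, both driven by one
  recorded seed; frames are clipped at zero.
- Coordinates are (z, y, x), shear along +x, lengths in µm, phases in
  radians, 0-based pixels.

The bead phantom renders the projected chord phase
φ(r) = g·(2π/λ)·t(r)·(n−n₀) with 3× supersampled (anti-aliased) edges; the
geometry factor g (1 transmission, 2 reflection) is explicit rather than
folded into the 2π, which makes the reflection/transmission peak ratio
exactly 2 by construction and matches the printed parameter set
(d = 1.9 µm, n = 1.605, n₀ = 1.518, λ = 0.49 µm → 2.12 / 4.24 rad).

## Phase retrieval

The quadrature path implements θ = atan2(I₃π/₂ − I_π/₂, I₀ − I_π) with
A = mean(frames) and B = ½√((I₀−I_π)² + (I₃π/₂−I_π/₂)²); it requires the
ε set (0, π/2, π, 3π/2) within 1 mrad. The generalized path solves the
per-pixel linear model I_n = a + b cos ε_n + c sin ε_n (one shared design
matrix; rejected when its condition exceeds 10⁶) and takes
θ = atan2(−c, b). When the ε set is the canonical quadrature set to within
1e−9 rad the solver delegates to the quadrature formula — the algebraic
reduction made literal, so the two paths agree bit-for-bit there.

Numerical conventions:

- Output Δφ is wrapped to (−π, π]; the pipeline never performs 2D phase
  unwrapping (the gradient of realistic specimens stays far from ±π).
- Pixels whose modulation B falls below 1e−6 of the peak frame value get
  Δφ = 0 and a `validity=False` flag rather than NaN, keeping downstream
  FFTs finite.
- φ_0 (default π) is subtracted before background removal and is
  user-overridable.

**Slant-background removal.** A finite-window Gaussian low-pass cannot
reproduce a plane at the image borders (any border extension biases a
ramp), so the background estimate is the best-fit plane *plus* a Gaussian
low-pass (σ = cutoff_fraction × image size, default 0.1) of the residual.
This makes the removal exact for the planar component everywhere while
still absorbing smooth non-planar drifts; the output is re-centred to zero
mean.

## Integration and bead quantification

The measured Δφ is a finite difference over δr, so the cumulative sum along
the shear is scaled by pixel_pitch/δr. The per-line constant of integration
is undefined after high-pass background removal; the default `line-mean`
detrend sets each line's mean to zero, which suppresses running-sum streaks.
`quantify_bead` therefore measures the peak *relative to the median of the
line through the bead centre*, which is invariant to the detrend convention
as long as the bead covers less than half the line. The round-trip peak
lands within ~1 % of the analytic value on the default 64×64 grid; the 5 %
test tolerance covers the shear-difference vs derivative discretization.

## System response and Wiener reconstruction

**Fiducial route.** The known potential x_o of a fiducial sphere is
rendered as a 3×-supersampled 3D indicator scaled by the index contrast.
PSF(k) = y_o(k)·conj(x_o(k)) / (|x_o(k)|² + floor) with floor = 1e−6 of the
spectral peak by default: a sphere's discrete spectrum has exact nulls
(about 9 % of the band on a 32³ grid), at which the fiducial carries no
information. The PSF is recentred (zero lag at the array centre) and
unit-sum normalized, so its transfer function is 1 at k = 0.

**Merged Wiener filter.** Reconstruction of an unknown volume y uses
w(k) = conj(H)/(|H|² + ε) with H = y_o(k)/x_o(k) (floored as above) and
x(k) = y(k)·w(k) — estimating the PSF and deconvolving in one step, which
needs a single regularizer. ε is a dimensionless noise-to-signal power
ratio; the default 0.003 follows the value found near-optimal for this
modality. Frequencies where |H|² + ε is exactly zero get w = 0 instead of
0/0, so the filter is finite for every ε ≥ 0 including the unregularized
limit; nonzero denominators are never floored, which keeps the ε = 0 case
an exact inverse on the fiducial's support. The equivalence of the merged
filter with estimate-then-deconvolve is asserted in the tests as an
algebraic identity.

**Edge route.** Through-focus stacks of a phase step are reduced to an
edge-spread function per focus position: the edge orientation is estimated
from the gradient structure tensor (seeded by a user hint to resolve the
180° ambiguity), slices are rotated (cubic interpolation) and averaged
along the edge, and the lateral central difference gives the line-spread
function. A separable cosine-taper window (fraction 0.1) precedes the 2D
FFT to the (k_x, k_z) transfer map. The edge route characterizes a single
plane only and is not used for 3D reconstruction.

**Tomographic high-pass.** Each z slice is independently high-passed
(Gaussian complement, cutoff_fraction 0.1 by default) and re-centred to
exactly zero mean; optional bilateral smoothing (scikit-image) is exposed
with configurable σ_spatial/σ_range because no canonical parameters exist —
σ_range defaults to the slice standard deviation.

## Focus topography

The focus score is the exact windowed variance (mean of squares minus
squared mean) over a (2w+1)² neighborhood, computed with separable uniform
filters and reflection padding at the borders; tiny negative values from
catastrophic cancellation are clipped at zero. The default half-width
w = 7 (15×15 window) balances plateau fidelity against boundary blur; the
spheroid tests also pass at w = 3. Ties in the argmax resolve to the lowest
slice index, making featureless pixels deterministic. Heights come from the
stack's z metadata; volumes are Σ max(z_max − baseline, 0) · pitch².

The spheroid phantom places static random texture per lateral region under
a Gaussian focus envelope (σ = 0.75 z-steps) centred at the region's true
height — it emulates where focus lands, not how defocused texture actually
blurs, so plateau-recovery tests validate the metric and bookkeeping, not
defocus physics.

## Mosaicking

Pairwise registration correlates Hann-windowed overlap windows (predicted
from the nominal stage positions) rather than whole tiles: at 20 % overlap
the non-shared content otherwise dominates the cross-power spectrum. The
integer displacement is found by phase correlation with the peak search
constrained to ±8 px around the prediction (among equal peaks this prefers
the one closest to the stage prediction) and iterated until the extraction
window agrees with the estimate; the sub-pixel residual then comes from a
weighted least-squares fit of the cross-spectrum phase plane over
|f| < 0.25, which is unbiased at zero residual — identical windows give an
exactly zero phase, so noiseless integer-truth grids are placed exactly.

Global placement solves the pairwise-offset graph in least squares anchored
at tile 0, weighted by peak confidence (main/secondary peak ratio), with
one Cauchy-reweighted pass (unit scale 1 px) when any loop-closure residual
exceeds 0.25 px. Compositing uses rounded positions with separable triangle
(linear-feather) weights, which reproduces the source exactly wherever
aligned tiles agree. The "Fourier filtering" band-pass (drop DC + lowest
2 %, soft-cut highest 10 % of the Nyquist band) is available behind the
`bandpass` flag; its passband is a configuration default, not a calibrated
value.

At SNR 20 dB on the 3×3/20 %-overlap fixture the global placement RMS stays
below 0.5 px (typically ~0.15 px across seeds).

## Problem sizes

The validation suites use 64×64 frames (100 random maps for the retrieval
oracle), 32³ voxel volumes (20 noise realizations for the Wiener shape
recovery), 12-slice 96² spheroid stacks and 3×3 grids of 64² tiles — sizes
at which every oracle (brute-force variance, dense θ scan, integer-shift
search) runs in seconds while all phantom features remain well resolved.

## Known limitations

- No partially coherent or first-order-Born forward solver: the frequency
  coverage of the real instrument is not derived, only measured/estimated.
- Cumulative-sum integration is 1D; no Fourier/Poisson 2D integrator.
- No LVR calibration: ε_n values are taken as given.
- `esf_to_lsf` assumes one dominant straight edge per stack.
- Flat-field correction is subtraction only; no vignetting polynomial.
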