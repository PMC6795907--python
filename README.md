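# epiglim

Quantitative phase reconstruction for **epi-illumination gradient light
interference microscopy (epi-GLIM)** — phase imaging of opaque and turbid
specimens in a reflection Nomarski (DIC) geometry.

## Who this is for

Epi-GLIM instruments measure the lateral *gradient* of the optical phase by
interfering two beam copies sheared by a sub-diffraction distance δr, while a
variable retarder steps the interferometric offset ε between them. This
package implements the complete computational stack between the raw camera
frames and quantitative phase/topography/tomography, together with a phantom
generator so every stage can be validated without instrument data. It is
aimed at QPI/DIC instrument builders and image-analysis developers.

## The reconstruction model

Each detector frame obeys the two-beam interference law

    I_n(r) = I(r) + I(r+δr) + 2√(I(r)I(r+δr)) · cos[Δφ(r) + φ_b(r) + φ_0 + ε_n]

where Δφ(r) = φ(r+δr) − φ(r) ≈ ∂φ/∂x · δr is the phase-gradient signal, φ_b
a slant-like instrumental background, φ_0 the Nomarski bias (π by default:
dark background), and ε_n the commanded phase shifts. The stack provides:

- **phase_retrieval** — quadrature (0, π/2, π, 3π/2) retrieval
  θ = atan2(I₃π/₂ − I_π/₂, I₀ − I_π) and a generalized per-pixel
  least-squares solver I_n = a + b·cos ε_n + c·sin ε_n robust to non-90°
  steps; slant-background high-pass removal; optional denoising. The
  pixelwise differences cancel any non-modulating (multiple-scattering)
  background exactly.
- **integration** — cumulative sum along the shear scaled by pitch/δr, and
  quantification against the projected bead phase φ = g·(2π/λ)·d·(n−n₀)
  (g = 1 transmission, g = 2 reflection double pass).
- **psf_recon** — system response from edge targets (ESF → LSF → (k_x, k_z)
  transfer function) and from 3 µm fiducial beads co-embedded with the
  sample: PSF(k) = y_o(k)/x_o(k), and the merged Wiener reconstruction
  x(k) = y(k)·conj(H)/(|H|² + ε) with H = y_o/x_o and noise-to-signal
  regularizer ε = 0.003; plus slice-wise high-pass tomographic rendering.
- **focus_topography** — all-in-focus projection and height maps by the
  windowed-variance focus metric z_max = argmax_z var_w(Δφ), and sample
  volume from the height map.
- **mosaic** — flat-field subtraction, Fourier filtering, phase-correlation
  registration with sub-pixel refinement, global least-squares placement and
  feathered blending of large tile grids.
- **forward_model** — phantoms (beads, phase steps, multilayer spheroids,
  tile grids) and the full interferometric frame simulator with band-limited
  sub-pixel shear and seeded shot/read noise.

## Worked example

Simulate the reference experiment — a 1.9 µm polystyrene bead (n = 1.605)
in oil (n₀ = 1.518) on a mirror, imaged at 490 nm with δr = 0.3 µm — then
retrieve, integrate and quantify:

```python
import numpy as np
from epiglim import (AcquisitionGeometry, simulate_bead_phase,
                     simulate_dic_frames, retrieve_gradient_4frame,
                     integrate_gradient, quantify_bead)

geom = AcquisitionGeometry(shear_distance=0.3, geometry="reflection",
                           wavelength=0.490)
obj = simulate_bead_phase(d=1.9, n=1.605, n0=1.518, wavelength=0.490,
                          shape=(64, 64), pixel_pitch=0.1,
                          geometry="reflection")
series = simulate_dic_frames(obj, geom, [0, np.pi/2, np.pi, 3*np.pi/2])
gmap = retrieve_gradient_4frame(series)
gmap.bias_removed = True          # no slant background in this simulation
ipm = integrate_gradient(gmap)
report = quantify_bead(ipm, d=1.9, n=1.605, n0=1.518, wavelength=0.490,
                       geometry="reflection")
print(f"expected peak {report['expected_peak_rad']:.3f} rad, "
      f"measured {report['measured_peak_rad']:.3f} rad, "
      f"ratio {report['ratio']:.3f}")
```

This prints

```
expected peak 4.239 rad, measured 4.208 rad, ratio 0.993
```

The expected peak is the reflection (double-pass) value — exactly twice the
2.12 rad a transmission geometry would give — and the full
simulate → retrieve → integrate round trip recovers it to better than 1 %;
the residual comes from the finite shear difference standing in for a true
derivative.

The same pipeline is scriptable from the shell:

```sh
epiglim simulate bead bead.tif --geometry reflection
epiglim retrieve bead.tif gmap.tif --highpass 0
epiglim integrate gmap.tif phi.tif --bead-report report.json
```

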