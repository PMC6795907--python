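"""TIFF + TOML sidecar I/O for frame series, volumes and maps.

Frame series and volumes travel as multi-page 32-bit float TIFF with a TOML
sidecar carrying the acquisition metadata (pixel pitch, shear, phase shifts,
z step, geometry, seed). Page order: phase-shift index fastest, then z.

The sidecar is read with the stdlib ``tomllib``; writing uses a small flat
serializer (scalars, strings and flat lists only), which covers everything
the sidecar schema needs.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import tifffile

from .datatypes import AcquisitionGeometry, PhaseShiftSeries, VolumeStack
from .phase_retrieval import GradientPhaseMap

__all__ = [
    "write_toml",
    "read_toml",
    "write_series",
    "read_series",
    "write_volume",
    "read_volume",
    "write_gradient_map",
    "read_gradient_map",
]


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float, np.integer, np.floating)):
        return repr(float(v)) if isinstance(v, (float, np.floating)) else str(int(v))
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"unsupported TOML value type: {type(v)!r}")


def write_toml(path: str | Path, data: dict) -> None:
    """Serialize a flat mapping (scalars, strings, flat lists) to TOML."""
    lines = [f"{key} = {_toml_value(val)}" for key, val in data.items() if val is not None]
    Path(path).write_text("\n".join(lines) + "\n")


def read_toml(path: str | Path) -> dict:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".toml")


def write_series(path: str | Path, series: PhaseShiftSeries, seed: int | None = None) -> None:
    """Write a phase-shift series as multi-page float32 TIFF + TOML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, series.as_array().astype(np.float32))
    geom = series.geometry
    write_toml(
        _sidecar(path),
        {
            "pixel_pitch_um": series.pixel_pitch,
            "shear_um": geom.shear_distance,
            "shear_axis": geom.shear_axis,
            "epsilons_rad": list(series.epsilons),
            "phi_0_rad": geom.static_bias,
            "geometry": geom.geometry,
            "wavelength_um": geom.wavelength,
            "seed": seed,
        },
    )


def read_series(path: str | Path, frame_order: list[int] | None = None) -> PhaseShiftSeries:
    """Read a phase-shift series written by :func:`write_series`.

    ``frame_order`` re-indexes pages for instruments that store the phase
    shifts in a different order than the sidecar's epsilon list.
    """
    path = Path(path)
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim == 2:
        pages = pages[None]
    meta = read_toml(_sidecar(path))
    if frame_order is not None:
        pages = pages[list(frame_order)]
    geom = AcquisitionGeometry(
        shear_distance=float(meta["shear_um"]),
        shear_axis=meta.get("shear_axis", "x"),
        static_bias=float(meta.get("phi_0_rad", np.pi)),
        geometry=meta.get("geometry", "reflection"),
        wavelength=float(meta.get("wavelength_um", 0.490)),
    )
    return PhaseShiftSeries(
        frames=list(pages),
        epsilons=[float(e) for e in meta["epsilons_rad"]],
        geometry=geom,
        pixel_pitch=float(meta.get("pixel_pitch_um", 1.0)),
    )


def write_volume(path: str | Path, vol: VolumeStack) -> None:
    path = Path(path)
    tifffile.imwrite(path, vol.data.astype(np.float32))
    dz, dy, dx = vol.sampling
    write_toml(
        _sidecar(path),
        {"dz_um": dz, "dy_um": dy, "dx_um": dx, "z0_um": vol.z0},
    )


def read_volume(path: str | Path) -> VolumeStack:
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    if data.ndim == 2:
        data = data[None]
    meta = read_toml(_sidecar(path)) if _sidecar(path).exists() else {}
    return VolumeStack(
        data=data,
        sampling=(
            float(meta.get("dz_um", 1.0)),
            float(meta.get("dy_um", 1.0)),
            float(meta.get("dx_um", 1.0)),
        ),
        z0=float(meta.get("z0_um", 0.0)),
    )


def write_gradient_map(path: str | Path, gmap: GradientPhaseMap) -> None:
    """Write a gradient map (float32 TIFF) plus its validity mask TIFF."""
    path = Path(path)
    tifffile.imwrite(path, gmap.delta_phi.astype(np.float32))
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    tifffile.imwrite(mask_path, gmap.validity.astype(np.uint8))
    write_toml(
        _sidecar(path),
        {
            "shear_um": gmap.shear_distance,
            "shear_axis": gmap.shear_axis,
            "pixel_pitch_um": gmap.pixel_pitch,
            "bias_removed": bool(gmap.bias_removed),
        },
    )


def read_gradient_map(path: str | Path) -> GradientPhaseMap:
    path = Path(path)
    delta_phi = np.asarray(tifffile.imread(path), dtype=float)
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    validity = (
        np.asarray(tifffile.imread(mask_path)).astype(bool) if mask_path.exists() else None
    )
    meta = read_toml(_sidecar(path)) if _sidecar(path).exists() else {}
    return GradientPhaseMap(
        delta_phi=delta_phi,
        shear_distance=float(meta.get("shear_um", 1.0)),
        shear_axis=meta.get("shear_axis", "x"),
        validity=validity,
        bias_removed=bool(meta.get("bias_removed", False)),
        pixel_pitch=float(meta.get("pixel_pitch_um", 1.0)),
    )
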