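"""Reading and writing the pipeline's on-disk formats.

Parametric maps and signal stacks go to NIfTI-1 (nibabel) with a JSON
sidecar carrying units, frame labels and fit/protocol provenance; complex
wave images are stored as paired real/imaginary volumes; stain images as
single-channel TIFF (tifffile) with a JSON sidecar; cohort tables as CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .fitting import ParametricMap
from .grid import Grid
from .mre import ComplexWaveImage
from .protocols import AcquisitionProtocol
from .simulate import SignalStack
from .stain import StainImage


def _affine(grid: Grid) -> np.ndarray:
    aff = np.diag([grid.spacing_mm, grid.spacing_mm, grid.slice_thickness_mm, 1.0])
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _grid_dict(grid: Grid) -> dict:
    return dataclasses.asdict(grid)


def _grid_from_dict(d: dict) -> Grid:
    return Grid(**d)


def save_map(path: str | Path, pmap: ParametricMap) -> Path:
    path = Path(path)
    data = np.where(pmap.valid_mask, pmap.values, np.nan)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64).T[..., None], _affine(pmap.grid))
    img.header["descrip"] = pmap.units.encode()[:79]
    nib.save(img, path)
    _sidecar_path(path).write_text(
        json.dumps(
            {"units": pmap.units, "grid": _grid_dict(pmap.grid), "provenance": pmap.provenance},
            indent=2,
            default=str,
        )
    )
    return path


def load_map(path: str | Path) -> ParametricMap:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    data = np.asarray(nib.load(path).dataobj)[..., 0].T
    valid = np.isfinite(data)
    return ParametricMap(
        values=data,
        units=meta["units"],
        valid_mask=valid,
        grid=_grid_from_dict(meta["grid"]),
        provenance=meta.get("provenance", {}),
    )


def save_stack(path: str | Path, stack: SignalStack) -> Path:
    """Write frames as a 4D NIfTI (x, y, z, frame) with a JSON sidecar."""
    path = Path(path)
    frames = stack.frames
    if frames.ndim == 3:  # (frame, y, x) -> (x, y, 1, frame)
        vol = frames.transpose(2, 1, 0)[:, :, None, :]
    else:  # (frame, z, y, x) -> (x, y, z, frame)
        vol = frames.transpose(3, 2, 1, 0)
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), _affine(stack.grid)), path)
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "frame_axis": stack.frame_axis,
                "frame_values": list(stack.frame_values),
                "protocol": dataclasses.asdict(stack.protocol),
                "grid": _grid_dict(stack.grid),
                "provenance": stack.provenance,
            },
            indent=2,
            default=str,
        )
    )
    return path


def load_stack(path: str | Path) -> SignalStack:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    vol = np.asarray(nib.load(path).dataobj)
    if vol.shape[2] == 1:
        frames = vol[:, :, 0, :].transpose(2, 1, 0)
    else:
        frames = vol.transpose(3, 2, 1, 0)
    proto = meta["protocol"]
    for key in ("inversion_times_ms", "b_values", "echo_times_ms", "mt_offsets_ppm"):
        proto[key] = tuple(proto.get(key) or ())
    protocol = AcquisitionProtocol(**proto)
    frame_values = meta["frame_values"]
    if meta["frame_axis"] != "mt_state":
        frame_values = [float(v) for v in frame_values]
    return SignalStack(
        frames=frames,
        frame_axis=meta["frame_axis"],
        frame_values=tuple(frame_values),
        protocol=protocol,
        grid=_grid_from_dict(meta["grid"]),
        provenance=meta.get("provenance", {}),
    )


def save_wave(path_real: str | Path, path_imag: str | Path, wave: ComplexWaveImage) -> None:
    for path, part in ((path_real, wave.amplitude.real), (path_imag, wave.amplitude.imag)):
        path = Path(path)
        vol = part.transpose(2, 1, 0)
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), _affine(wave.grid)), path)
        _sidecar_path(path).write_text(
            json.dumps(
                {"frequency_hz": wave.frequency_hz, "grid": _grid_dict(wave.grid)}, indent=2
            )
        )


def load_wave(path_real: str | Path, path_imag: str | Path) -> ComplexWaveImage:
    meta = json.loads(_sidecar_path(Path(path_real)).read_text())
    re = np.asarray(nib.load(path_real).dataobj).transpose(2, 1, 0)
    im = np.asarray(nib.load(path_imag).dataobj).transpose(2, 1, 0)
    return ComplexWaveImage(
        amplitude=re + 1j * im,
        frequency_hz=meta["frequency_hz"],
        grid=_grid_from_dict(meta["grid"]),
    )


def save_stain(path: str | Path, image: StainImage) -> Path:
    path = Path(path)
    tifffile.imwrite(path, image.pixels.astype(np.uint8))
    _sidecar_path(path).write_text(
        json.dumps(
            {"pixel_size_um": image.pixel_size_um, "provenance": image.provenance},
            indent=2,
            default=str,
        )
    )
    return path


def load_stain(path: str | Path, pixel_size_um: float | None = None) -> StainImage:
    path = Path(path)
    pixels = np.asarray(tifffile.imread(path))
    pixels = (pixels > 0).astype(np.uint8)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return StainImage(
        pixels=pixels,
        pixel_size_um=pixel_size_um or meta.get("pixel_size_um", 0.46),
        provenance=meta.get("provenance", {}),
    )
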