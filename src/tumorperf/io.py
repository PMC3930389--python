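"""NIfTI input/output with JSON sidecars for the frame axis metadata.

A series is stored as an uncompressed float64 NIfTI volume of shape
``(ny, nx, 1, n_frames)`` plus a sidecar JSON (same stem, ``.json``)
carrying the axis kind and values, the repeat count, pixel size and a
provenance note.  Voxel data round-trip bit-exactly.  Masks are stored as
unsigned 8-bit NIfTI.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .series import ImageSeries


def _affine(pixel_size_mm: float) -> np.ndarray:
    return np.diag([pixel_size_mm, pixel_size_mm, 1.0, 1.0])


def _sidecar_path(path) -> Path:
    p = Path(path)
    return p.with_suffix(".json") if p.suffix == ".nii" else Path(str(p) + ".json")


def write_series(series: ImageSeries, path) -> Path:
    """Write a series volume and its sidecar; returns the NIfTI path."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    data = series.data[:, :, None, :].astype(np.float64)
    img = nib.Nifti1Image(data, _affine(series.pixel_size_mm))
    nib.save(img, str(path))
    sidecar = {
        "axis_kind": series.axis_kind,
        "axis_values": [float(v) for v in series.axis_values],
        "repeats": int(series.repeats),
        "pixel_size_mm": float(series.pixel_size_mm),
        "provenance": series.provenance,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=2))
    return path


def read_series(path) -> ImageSeries:
    """Read a series written by :func:`write_series`, validating the sidecar."""
    path = Path(path)
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar JSON for {path}: {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4:
        data = data[:, :, 0, :]
    elif data.ndim != 3:
        raise ValueError(f"unsupported NIfTI dimensionality {data.ndim} in {path}")
    n_frames = data.shape[-1]
    expected = len(meta["axis_values"]) * int(meta.get("repeats", 1))
    if n_frames != expected:
        raise ValueError(
            f"{path}: volume holds {n_frames} frames but sidecar declares "
            f"{len(meta['axis_values'])} axis values x {meta.get('repeats', 1)} repeats = {expected}"
        )
    return ImageSeries(
        data,
        axis_kind=meta["axis_kind"],
        axis_values=np.asarray(meta["axis_values"], dtype=np.float64),
        repeats=int(meta.get("repeats", 1)),
        pixel_size_mm=float(meta.get("pixel_size_mm", 1.0)),
        provenance=str(meta.get("provenance", "")),
    )


def write_map(arr: np.ndarray, path, pixel_size_mm: float = 1.0) -> Path:
    """Write a 2D voxel map as float64 NIfTI."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    arr = np.asarray(arr, dtype=np.float64)
    img = nib.Nifti1Image(arr[:, :, None], _affine(pixel_size_mm))
    nib.save(img, str(path))
    return path


def read_map(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return np.squeeze(arr)


def write_mask(mask: np.ndarray, path, pixel_size_mm: float = 1.0) -> Path:
    """Write a binary mask as uint8 NIfTI."""
    path = Path(path)
    if path.suffix != ".nii":
        path = path.with_suffix(".nii")
    arr = np.asarray(mask).astype(np.uint8)
    img = nib.Nifti1Image(arr[:, :, None], _affine(pixel_size_mm))
    nib.save(img, str(path))
    return path


def read_mask(path) -> np.ndarray:
    return np.squeeze(np.asarray(nib.load(str(path)).dataobj)) > 0
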