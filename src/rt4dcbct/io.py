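"""Readers and writers for the standard medical-image formats.

Volumes and vector fields go through SimpleITK (NIfTI ``.nii/.nii.gz`` and
MetaImage ``.mha/.mhd``); DRRs are 32-bit TIFF with a JSON geometry
sidecar; breathing traces and coefficient tables are CSV.

Axis note: this package stores arrays as (x, y, z) with world coordinates
in mm; SimpleITK images are indexed (x, y, z) through GetPixel but their
NumPy views are (z, y, x), so arrays are transposed on the way in and out.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk
import tifffile

from .projector import ConeBeamGeometry
from .types import DRRImage, DVFVolume, Volume3D


def write_volume(vol: Volume3D, path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(vol.spacing))
    img.SetOrigin(tuple(vol.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path) -> Volume3D:
    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img).T
    return Volume3D(
        values=np.ascontiguousarray(values),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def write_dvf(dvf: DVFVolume, path) -> None:
    # (nx, ny, nz, 3) -> sitk vector image indexed (z, y, x)
    arr = np.ascontiguousarray(dvf.displacement.transpose(2, 1, 0, 3))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(tuple(dvf.spacing))
    img.SetOrigin(tuple(dvf.origin))
    sitk.WriteImage(img, str(path))


def read_dvf(path, phase_tag: int | None = None) -> DVFVolume:
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{path}: expected a 3-component vector image")
    return DVFVolume(
        displacement=np.ascontiguousarray(arr.transpose(2, 1, 0, 3)),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        phase_tag=phase_tag,
    )


def write_drr(drr: DRRImage, path) -> None:
    """32-bit TIFF plus a JSON sidecar carrying the geometry."""
    path = Path(path)
    tifffile.imwrite(path, drr.line_integrals.astype(np.float32))
    if drr.geometry is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(asdict(drr.geometry), indent=2))


def read_drr(path) -> DRRImage:
    path = Path(path)
    data = tifffile.imread(path)
    geom = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        d = json.loads(sidecar.read_text())
        d["detector_size"] = tuple(d["detector_size"])
        geom = ConeBeamGeometry(**d)
    return DRRImage(line_integrals=np.asarray(data, dtype=float), geometry=geom)


def write_trace(trace, path) -> None:
    pd.DataFrame(
        {"phase": np.arange(trace.n_phases), "amplitude": list(trace.amplitudes)}
    ).to_csv(path, index=False)


def write_coefficients(samples, path) -> None:
    """CSV table (sample_id, q1, q2, ..., qk)."""
    Q = np.stack([s.q for s in samples])
    cols = {f"q{j + 1}": Q[:, j] for j in range(Q.shape[1])}
    pd.DataFrame({"sample_id": np.arange(Q.shape[0]), **cols}).to_csv(
        path, index=False
    )


def read_coefficients(path) -> np.ndarray:
    df = pd.read_csv(path)
    qcols = [c for c in df.columns if c.startswith("q")]
    return df[qcols].to_numpy(dtype=float)
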