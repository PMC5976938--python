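"""Readers and writers for the pipeline's on-disk formats.

NIfTI is used for image-like arrays (masks, signal stacks with the
acquisition dimension as third axis, parameter maps), YAML for protocol
and run configuration, CSV for polylines and tables. The NIfTI affine is
diagonal with the pixel spacing in mm, which is all the 2-D mid-sagittal
pipeline needs.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .relaxometry import AcquisitionProtocol

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_protocol",
    "load_protocol",
    "save_curve_csv",
    "load_curve_csv",
]


def save_nifti(path, array: np.ndarray, pixel_spacing_mm: float = 1.0) -> None:
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_protocol(path, protocol: AcquisitionProtocol) -> None:
    doc = {"kind": protocol.kind, "times_ms": list(protocol.times_ms)}
    if protocol.tr_ms is not None:
        doc["tr_ms"] = protocol.tr_ms
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_protocol(path) -> AcquisitionProtocol:
    doc = yaml.safe_load(Path(path).read_text())
    return AcquisitionProtocol(
        kind=doc["kind"], times_ms=tuple(doc["times_ms"]), tr_ms=doc.get("tr_ms")
    )


def save_curve_csv(path, curve: np.ndarray) -> None:
    pd.DataFrame(curve, columns=["col_px", "row_px"]).to_csv(path, index=False)


def load_curve_csv(path) -> np.ndarray:
    return pd.read_csv(path)[["col_px", "row_px"]].to_numpy(dtype=float)
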