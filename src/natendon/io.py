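"""NIfTI / sidecar / table input-output.

Volumes and label maps are stored as single-channel 3-D NIfTI-1 files with a
diagonal affine built from voxel size and origin.  Acquisition metadata that
NIfTI headers carry unreliably (nucleus, TR, TE, label legend) lives in a JSON
sidecar next to each file, ``<stem>.json``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .datamodel import LabelMap, Nucleus, Volume3D

__all__ = [
    "load_volume",
    "save_volume",
    "load_label_map",
    "save_label_map",
    "write_table",
    "read_table",
    "sidecar_path",
]


def sidecar_path(path) -> Path:
    """Path of the JSON sidecar of a ``.nii``/``.nii.gz`` file."""
    p = Path(path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _affine(voxel_size_mm, origin_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(voxel_size_mm)
    aff[:3, 3] = origin_mm
    return aff


def _grid_from_img(img) -> tuple[np.ndarray, np.ndarray]:
    aff = img.affine
    voxel = np.sqrt((aff[:3, :3] ** 2).sum(axis=0))
    origin = aff[:3, 3].copy()
    return voxel, origin


def save_volume(volume: Volume3D, path) -> Path:
    """Write a volume as NIfTI plus a JSON sidecar; returns the NIfTI path."""
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float64), _affine(volume.voxel_size_mm, volume.origin_mm))
    nib.save(img, str(path))
    meta = {
        "nucleus": volume.nucleus.value,
        "tr_ms": volume.tr_ms,
        "te_ms": volume.te_ms,
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path) -> Volume3D:
    """Read a 3-D scalar NIfTI volume and its sidecar metadata."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"not a 3-D volume: {path} has {data.ndim} dimensions")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"volume {path} contains non-finite values")
    voxel, origin = _grid_from_img(img)
    meta = {}
    sp = sidecar_path(path)
    if sp.exists():
        meta = json.loads(sp.read_text())
    return Volume3D(
        data,
        voxel_size_mm=voxel,
        origin_mm=origin,
        nucleus=Nucleus(meta.get("nucleus", Nucleus.NA23.value)),
        tr_ms=meta.get("tr_ms"),
        te_ms=meta.get("te_ms"),
    )


def save_label_map(labelmap: LabelMap, path) -> Path:
    """Write an integer label map as NIfTI; legend goes into the sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(
        labelmap.labels.astype(np.int16), _affine(labelmap.voxel_size_mm, labelmap.origin_mm)
    )
    nib.save(img, str(path))
    meta = {"legend": {str(k): v for k, v in labelmap.legend.items()}}
    sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_label_map(path) -> LabelMap:
    """Read an integer label map and its legend sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"not a 3-D label map: {path} has {data.ndim} dimensions")
    if not np.issubdtype(data.dtype, np.integer):
        if not np.all(data == np.round(data)):
            raise ValueError(f"label map {path} contains non-integer values")
        data = data.astype(np.int32)
    voxel, origin = _grid_from_img(img)
    legend = {}
    sp = sidecar_path(path)
    if sp.exists():
        legend = {int(k): v for k, v in json.loads(sp.read_text()).get("legend", {}).items()}
    return LabelMap(data.astype(np.int32), voxel_size_mm=voxel, origin_mm=origin, legend=legend)


def write_table(rows: Sequence[dict], path, columns: Sequence[str] | None = None) -> Path:
    """Write homogeneous records to CSV with a stable column order.

    Column order is that of the first record unless ``columns`` is given.
    An empty record list still produces a header-only file when ``columns``
    is supplied, otherwise an empty file with no header.
    """
    path = Path(path)
    rows = list(rows)
    if rows:
        first = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != first:
                raise ValueError("ragged records: all rows must share the same keys")
        if columns is None:
            columns = first
    df = pd.DataFrame(rows, columns=list(columns) if columns is not None else None)
    df.to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
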