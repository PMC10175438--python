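"""Readers and writers: NIfTI / DICOM volumes, meshes, annotations, reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import trimesh

from .segmentation import FragmentLabelVolume, FragmentMesh
from .volume import CTVolume

__all__ = [
    "read_volume",
    "write_labels_nifti",
    "read_labels_nifti",
    "write_mesh",
    "read_annotations",
    "write_annotations",
    "write_polylines_json",
    "write_report",
    "config_hash",
]


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    Voxel values are returned in HU (DICOM rescale slope/intercept
    applied).  Axes are normalized to (x, y, z) with z the proximal axis;
    NIfTI input is reoriented to closest-canonical (RAS) first.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.as_closest_canonical(nib.load(str(path)))
    voxels = np.asarray(img.get_fdata(), dtype=np.float32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


def _read_dicom_series(directory: Path) -> CTVolume:
    files = sorted(p for p in directory.iterdir() if p.suffix.lower() in (".dcm", ""))
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise FileNotFoundError(f"no DICOM slices in {directory}")
    try:
        slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
    except AttributeError as exc:
        raise ValueError("DICOM slices lack ImagePositionPatient") from exc
    orientations = {tuple(np.round(np.asarray(d.ImageOrientationPatient, float), 4))
                    for d in slices if hasattr(d, "ImageOrientationPatient")}
    if len(orientations) > 1:
        raise ValueError("mixed-orientation DICOM series")
    first = slices[0]
    if not hasattr(first, "RescaleSlope") or not hasattr(first, "RescaleIntercept"):
        raise ValueError("missing rescale tags (RescaleSlope/RescaleIntercept)")
    slope = float(first.RescaleSlope)
    intercept = float(first.RescaleIntercept)
    stack = np.stack(
        [d.pixel_array.astype(np.float32) * slope + intercept for d in slices],
        axis=-1,
    )  # (row, col, z)
    # rows advance along -y (DICOM row direction), columns along x; store (x, y, z)
    voxels = np.transpose(stack, (1, 0, 2))
    px = np.asarray(first.PixelSpacing, dtype=float)  # (row, col)
    if len(slices) > 1:
        dz = abs(
            float(slices[1].ImagePositionPatient[2])
            - float(first.ImagePositionPatient[2])
        )
    else:
        dz = float(getattr(first, "SliceThickness", 1.0))
    spacing = np.array([px[1], px[0], dz])
    origin = np.asarray(first.ImagePositionPatient, dtype=float)
    return CTVolume(voxels=voxels, spacing=spacing, origin=origin)


def write_labels_nifti(labelvol: FragmentLabelVolume, path: str | Path) -> None:
    affine = np.diag([*labelvol.spacing, 1.0])
    affine[:3, 3] = labelvol.origin
    nib.save(nib.Nifti1Image(labelvol.labels.astype(np.int16), affine), str(path))


def read_labels_nifti(path: str | Path) -> FragmentLabelVolume:
    img = nib.as_closest_canonical(nib.load(str(path)))
    labels = np.asarray(img.get_fdata()).astype(np.int32)
    return FragmentLabelVolume(
        labels=labels,
        spacing=np.asarray(img.header.get_zooms()[:3], dtype=float),
        origin=np.asarray(img.affine[:3, 3], dtype=float),
    )


def write_mesh(mesh: FragmentMesh, path: str | Path) -> None:
    """Export a fragment mesh as STL or PLY (binary, by extension)."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    tm.export(str(path))


def write_annotations(
    annotations: dict[int, np.ndarray], path: str | Path
) -> None:
    """Write per-vertex articular flags as CSV (fragment_id, vertex_index, is_articular)."""
    rows = []
    for frag_id, flags in annotations.items():
        for i, v in enumerate(np.asarray(flags, dtype=int)):
            rows.append((frag_id, i, v))
    pd.DataFrame(
        rows, columns=["fragment_id", "vertex_index", "is_articular"]
    ).to_csv(path, index=False)


def read_annotations(path: str | Path) -> dict[int, np.ndarray]:
    """Read per-vertex articular flags from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
        return {int(k): np.asarray(v, dtype=bool) for k, v in data.items()}
    df = pd.read_csv(path)
    out: dict[int, np.ndarray] = {}
    for frag_id, sub in df.groupby("fragment_id"):
        n = int(sub["vertex_index"].max()) + 1
        flags = np.zeros(n, dtype=bool)
        flags[sub["vertex_index"].to_numpy(int)] = (
            sub["is_articular"].to_numpy(int) > 0
        )
        out[int(frag_id)] = flags
    return out


def write_polylines_json(polylines, path: str | Path) -> None:
    data = [
        {"closed": bool(pl.closed), "points_mm": pl.points.tolist()}
        for pl in polylines
    ]
    Path(path).write_text(json.dumps(data, indent=1))


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping (for report provenance)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
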