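"""3-D volume and nodule-annotation I/O.

Volumes are held as :class:`CTVolume`: a 3-D float32 array indexed
``[x, y, z]`` (x varies fastest on disk, matching the NIfTI convention),
with per-axis voxel spacing and an origin in millimetres. Two on-disk
formats are supported:

* NIfTI-1 (``.nii`` / ``.nii.gz``) via nibabel, restricted to axis-aligned
  affines (oblique acquisitions are rejected rather than silently
  misoriented);
* a plain fixture format: ``<name>.raw`` little-endian float32 in C order of
  the (x, y, z) array plus a ``<name>.json`` sidecar with shape, spacing,
  origin and dtype. Round-trips are bit-exact.

Annotations travel in a manifest CSV with columns
``case_id, label, center_x_mm, center_y_mm, center_z_mm, diameter_mm,
isolated, seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

LABELS = ("benign", "malignant")

MANIFEST_COLUMNS = [
    "case_id",
    "label",
    "center_x_mm",
    "center_y_mm",
    "center_z_mm",
    "diameter_mm",
    "isolated",
    "seed",
]


class VolumeFormatError(ValueError):
    """Malformed volume file or header."""


class AnnotationError(ValueError):
    """Invalid nodule annotation."""


@dataclass
class CTVolume:
    """A 3-D intensity grid (HU-like) with physical geometry.

    ``data[i, j, k]`` sits at physical position ``origin + (i, j, k) * spacing``
    (millimetres).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.size == 0:
            raise VolumeFormatError(f"volume grid must be non-empty 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise VolumeFormatError(f"voxel spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size along each axis (distance from first to last voxel)."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing))

    def contains_mm(self, point_mm) -> bool:
        p = np.asarray(point_mm, dtype=float)
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.extent_mm())
        return bool(np.all(p >= lo) and np.all(p <= hi))

    def mm_to_voxel(self, point_mm) -> np.ndarray:
        """Continuous voxel coordinates of a physical point."""
        return (np.asarray(point_mm, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)


@dataclass
class NoduleAnnotation:
    """One radiologist-style nodule annotation (center + size + label)."""

    case_id: str
    center_mm: tuple[float, float, float]
    max_diameter_mm: float
    label: str
    isolated: bool = True
    seed: int | None = None

    def __post_init__(self):
        self.center_mm = tuple(float(c) for c in self.center_mm)
        self.max_diameter_mm = float(self.max_diameter_mm)
        if self.max_diameter_mm <= 0:
            raise AnnotationError(f"case {self.case_id}: max_diameter_mm must be > 0, got {self.max_diameter_mm}")
        if self.label not in LABELS:
            raise AnnotationError(f"case {self.case_id}: label must be one of {LABELS}, got {self.label!r}")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(volume: CTVolume, path) -> None:
    """Write NIfTI (.nii/.nii.gz) or the raw+JSON fixture format (.raw)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        affine = np.eye(4)
        affine[0, 0], affine[1, 1], affine[2, 2] = volume.spacing
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(volume.data, affine), str(path))
    elif name.endswith(".raw"):
        volume.data.astype("<f4").tofile(path)
        meta = {
            "shape": list(volume.data.shape),
            "spacing_mm": list(volume.spacing),
            "origin_mm": list(volume.origin),
            "dtype": "<f4",
            "order": "C",
            "axes": "xyz",
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise VolumeFormatError(f"unsupported volume extension: {path.name}")


def _read_fixture(path: Path) -> CTVolume:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise VolumeFormatError(f"missing JSON sidecar for {path.name}")
    meta = json.loads(sidecar.read_text())
    for key in ("shape", "spacing_mm", "origin_mm", "dtype"):
        if key not in meta:
            raise VolumeFormatError(f"{sidecar.name}: missing field {key!r}")
    shape = tuple(int(n) for n in meta["shape"])
    if len(shape) != 3 or any(n <= 0 for n in shape):
        raise VolumeFormatError(f"{sidecar.name}: field 'shape' must be 3 positive ints, got {meta['shape']}")
    data = np.fromfile(path, dtype=np.dtype(meta["dtype"]))
    if data.size != int(np.prod(shape)):
        raise VolumeFormatError(
            f"{path.name}: field 'shape' {shape} implies {int(np.prod(shape))} voxels, file has {data.size}"
        )
    return CTVolume(data.reshape(shape), tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]))


def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise VolumeFormatError(
            f"{path.name}: field 'affine' is oblique (off-diagonal rotation); only axis-aligned volumes are supported"
        )
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"{path.name}: field 'affine' has non-positive diagonal spacing {spacing}")
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3 or data.size == 0:
        raise VolumeFormatError(f"{path.name}: field 'dim' must describe a non-empty 3-D grid, got {data.shape}")
    return CTVolume(data, tuple(spacing), tuple(affine[:3, 3]))


def read_volume(path) -> CTVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return _read_nifti(path)
    if name.endswith(".raw"):
        return _read_fixture(path)
    raise VolumeFormatError(f"unsupported volume extension: {path.name}")


def write_annotations(annotations, path) -> None:
    rows = [
        {
            "case_id": a.case_id,
            "label": a.label,
            "center_x_mm": a.center_mm[0],
            "center_y_mm": a.center_mm[1],
            "center_z_mm": a.center_mm[2],
            "diameter_mm": a.max_diameter_mm,
            "isolated": a.isolated,
            "seed": -1 if a.seed is None else a.seed,
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_annotations(path, bounds: CTVolume | None = None) -> list[NoduleAnnotation]:
    """Load a manifest CSV; validates each row and reports the failing row number.

    If ``bounds`` is given, each center must lie inside that volume.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = [c for c in MANIFEST_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path.name}: missing columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            ann = NoduleAnnotation(
                case_id=str(row.case_id),
                center_mm=(row.center_x_mm, row.center_y_mm, row.center_z_mm),
                max_diameter_mm=row.diameter_mm,
                label=str(row.label),
                isolated=bool(row.isolated),
                seed=int(getattr(row, "seed", -1)) if int(getattr(row, "seed", -1)) >= 0 else None,
            )
        except AnnotationError as exc:
            raise AnnotationError(f"{path.name} row {i}: {exc}") from exc
        if bounds is not None and not bounds.contains_mm(ann.center_mm):
            raise AnnotationError(f"{path.name} row {i}: center {ann.center_mm} outside volume bounds")
        out.append(ann)
    return out
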