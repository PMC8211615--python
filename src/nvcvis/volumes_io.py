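"""Volume / label-volume data model and NIfTI-1 file I/O.

Conventions used throughout the package:

* voxel indices are 0-based, sampling is at voxel centers;
* ``world = affine @ (i, j, k, 1)`` maps voxel indices to world millimetres;
* label volumes share the grid of the scalar volume they annotate.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "Modality",
    "Volume",
    "LabelVolume",
    "BoundingBox",
    "REST",
    "CSF_VESSEL",
    "BRAINSTEM",
    "NERVE",
    "VESSEL",
    "DEFAULT_LEGEND",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
]

# Fixed label ids.  VESSEL only appears after TOF fusion stamps vessel voxels.
REST = 0
CSF_VESSEL = 1
BRAINSTEM = 2
NERVE = 3
VESSEL = 4

DEFAULT_LEGEND: dict[int, str] = {
    REST: "REST",
    CSF_VESSEL: "CSF_VESSEL",
    BRAINSTEM: "BRAINSTEM",
    NERVE: "NERVE",
    VESSEL: "VESSEL",
}


class Modality(str, Enum):
    CISS = "CISS"
    TOF = "TOF"
    FUSED = "FUSED"


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("non-invertible affine")
    return affine


@dataclass
class Volume:
    """A 3-D scalar grid with isotropic-ish spacing and a world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    modality: Modality = Modality.CISS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("non-3-D: volume data must have exactly 3 axes")
        if min(self.data.shape) < 2:
            raise ValueError("each axis must have at least 2 voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values")
        self.affine = _check_affine(self.affine)
        self.modality = Modality(self.modality)

    # -- grid helpers -------------------------------------------------
    @classmethod
    def from_spacing(
        cls,
        data: np.ndarray,
        spacing: float | tuple[float, float, float] = 1.0,
        modality: Modality = Modality.CISS,
    ) -> "Volume":
        if np.isscalar(spacing):
            spacing = (float(spacing),) * 3
        affine = np.diag(list(spacing) + [1.0])
        return cls(data, tuple(spacing), affine, modality)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world(self, indices: np.ndarray) -> np.ndarray:
        """Map (N,3) voxel indices to (N,3) world mm coordinates."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map (N,3) world mm coordinates to continuous voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def world_center(self) -> np.ndarray:
        c = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.world(c)[0]

    def same_grid(self, other: "Volume | LabelVolume", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def copy_with(self, data: np.ndarray, modality: Modality | None = None) -> "Volume":
        return Volume(
            data, self.spacing, self.affine.copy(), modality or self.modality
        )


@dataclass
class LabelVolume:
    """Integer grid assigning each voxel exactly one label id."""

    labels: np.ndarray
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("non-3-D: label data must have exactly 3 axes")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integral")
        self.legend = {int(k): str(v) for k, v in self.legend.items()}
        present = set(np.unique(self.labels).tolist())
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"label ids {sorted(unknown)} missing from legend")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label_id: int) -> np.ndarray:
        return self.labels == label_id


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive voxel-index box used to restrict region growing."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo = tuple(int(v) for v in self.lo)
        hi = tuple(int(v) for v in self.hi)
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if any(l < 0 for l in lo) or any(l > h for l, h in zip(lo, hi)):
            raise ValueError("bounding box requires 0 <= lo <= hi per axis")

    def check_inside(self, shape: tuple[int, int, int]) -> None:
        if any(h >= n for h, n in zip(self.hi, shape)):
            raise ValueError(f"bounding box {self.lo}..{self.hi} exceeds grid {shape}")

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))

    def contains(self, idx: tuple[int, int, int]) -> bool:
        return all(l <= i <= h for i, l, h in zip(idx, self.lo, self.hi))

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        self.check_inside(shape)
        m = np.zeros(shape, dtype=bool)
        m[self.slices()] = True
        return m


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    return path.with_name(name + ".legend.json")


def read_volume(path: str | Path, modality: Modality = Modality.CISS) -> Volume:
    """Read a 3-D NIfTI-1 volume; intensities are returned unmodified."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3-D: {path} has {data.ndim} axes")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, _check_affine(img.affine), modality)


def write_volume(v: Volume, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> LabelVolume:
    """Read a LabelVolume; the legend is recovered from a JSON sidecar."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such label volume: {path}")
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj)
    if labels.ndim != 3:
        raise ValueError(f"non-3-D: {path} has {labels.ndim} axes")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.array_equal(labels, np.round(labels)):
            raise ValueError("labels must be integral")
        labels = labels.astype(np.int32)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        legend = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        legend = dict(DEFAULT_LEGEND)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelVolume(labels, legend, spacing, _check_affine(img.affine))


def write_labels(lv: LabelVolume, path: str | Path) -> None:
    """Write labels as integer NIfTI plus a JSON legend sidecar."""
    path = Path(path)
    if not np.issubdtype(lv.labels.dtype, np.integer):
        raise ValueError("labels must be integral")
    img = nib.Nifti1Image(lv.labels.astype(np.int16), lv.affine)
    img.header.set_zooms(lv.spacing)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({str(k): v for k, v in lv.legend.items()}, indent=2)
    )
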