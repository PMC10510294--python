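"""Shared data model and NIfTI / CSV readers-writers.

Conventions, fixed once for the whole package:

* Array axes are ordered ``(x, y, z)`` and indexing is 0-based.
* Voxel spacing is in millimetres, strictly positive per axis.
* Displacement fields are stored in **voxel units** on the grid they live on;
  conversion to millimetres happens only inside metric reporting.
* Physical coordinates: ``phys = origin + index * spacing``.  Orientation
  information in a NIfTI affine beyond diagonal scaling + translation is
  ignored (volumes are assumed axis-aligned); a warning is logged when a
  non-diagonal affine is encountered.
* Landmark tables are CSV files with header ``id,x,y,z``, coordinates in mm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "LabelMask",
    "DisplacementField",
    "LandmarkSet",
    "read_volume",
    "write_volume",
    "read_label",
    "write_label",
    "read_displacement_field",
    "write_displacement_field",
    "read_landmarks",
    "write_landmarks",
    "index_to_physical",
    "physical_to_index",
]


def _as_triple(v, name: str) -> tuple[float, float, float]:
    arr = np.atleast_1d(np.asarray(v, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.shape != (3,):
        raise ValueError(f"{name} must have 3 components, got shape {arr.shape}")
    return tuple(float(x) for x in arr)


@dataclass
class Volume:
    """A 3D scalar image on a regular grid with physical voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3 spatial dimensions, got {self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise ValueError(f"volume contains {n_nan} NaN voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelMask:
    """Integer label volume on a :class:`Volume` grid (0 = background)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3 spatial dimensions, got {self.data.ndim}"
            )
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.int16)
            else:
                rounded = np.rint(self.data)
                if not np.allclose(self.data, rounded):
                    raise ValueError("label data is not integer-valued")
                self.data = rounded.astype(np.int16)
        if (self.data < 0).any():
            raise ValueError("label values must be non-negative")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def labels(self) -> set[int]:
        return {int(v) for v in np.unique(self.data) if v != 0}


@dataclass
class DisplacementField:
    """Dense per-voxel 3-vector displacement, in voxel units.

    ``data[x, y, z]`` is the displacement (dx, dy, dz) applied when *sampling*:
    a consumer at voxel ``p`` reads the warped source at ``p + data[p]``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"displacement field must be 4D with 3 components on the last "
                f"axis, got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("displacement field contains non-finite values")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class LandmarkSet:
    """Named 3D points in physical (mm) coordinates."""

    ids: list[str]
    points: np.ndarray  # (n, 3) mm

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if len(self.ids) != len(self.points):
            raise ValueError("one id per point required")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("landmark ids must be unique")
        if not np.isfinite(self.points).all():
            raise ValueError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    def corresponds_to(self, other: "LandmarkSet") -> bool:
        return set(self.ids) == set(other.ids)

    def aligned_points(self, other: "LandmarkSet") -> tuple[np.ndarray, np.ndarray]:
        """Return (self.points, other.points) reordered to matching ids."""
        if not self.corresponds_to(other):
            raise ValueError("landmark id sets do not correspond")
        lookup = {i: k for k, i in enumerate(other.ids)}
        order = [lookup[i] for i in self.ids]
        return self.points, other.points[order]


# ---------------------------------------------------------------------------
# coordinate conversion

def index_to_physical(index, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    return np.asarray(origin, float) + np.asarray(index, float) * np.asarray(spacing, float)


def physical_to_index(phys, spacing, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    return (np.asarray(phys, float) - np.asarray(origin, float)) / np.asarray(spacing, float)


# ---------------------------------------------------------------------------
# NIfTI io

def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _spacing_origin_from(img) -> tuple[tuple, tuple]:
    aff = img.affine
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        logger.warning(
            "non-diagonal NIfTI affine found; orientation beyond voxel "
            "scaling is ignored (volumes are assumed axis-aligned)"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in aff[:3, 3])
    return spacing, origin


def read_volume(path) -> Volume:
    """Read a 3D scalar NIfTI volume; intensities are promoted to float."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(
        s == 1 for s in data.shape[3:]
    ) else data
    if data.ndim != 3:
        raise ValueError(
            f"expected 3 spatial dimensions, got {data.ndim} in {path.name}"
        )
    if np.issubdtype(data.dtype, np.floating):
        n_nan = int(np.isnan(data).sum())
        if n_nan:
            raise ValueError(f"{path.name}: {n_nan} NaN voxels; refusing to load")
    spacing, origin = _spacing_origin_from(img)
    return Volume(data=data, spacing=spacing, origin=origin)


def write_volume(vol: Volume, path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), _affine_from(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_label(path) -> LabelMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"expected 3 spatial dimensions, got {data.ndim} in {path.name}"
        )
    spacing, origin = _spacing_origin_from(img)
    return LabelMask(data=data, spacing=spacing, origin=origin)


def write_label(mask: LabelMask, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(mask.data, dtype=np.int16),
        _affine_from(mask.spacing, mask.origin),
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_displacement_field(path) -> DisplacementField:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # NIfTI vector convention
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(
            f"expected a 4D field with 3 components on the last axis, got "
            f"shape {data.shape} in {path.name}"
        )
    spacing, origin = _spacing_origin_from(img)
    return DisplacementField(data=data, spacing=spacing, origin=origin)


def write_displacement_field(phi: DisplacementField, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(phi.data, dtype=np.float32),
        _affine_from(phi.spacing, phi.origin),
    )
    img.header.set_zooms(tuple(phi.spacing) + (1.0,))
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# landmark io

def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = ["id", "x", "y", "z"]
    if list(df.columns[:4]) != required:
        raise ValueError(
            f"landmark file must have header id,x,y,z; got {list(df.columns)}"
        )
    if df["id"].duplicated().any():
        dupes = df["id"][df["id"].duplicated()].tolist()
        raise ValueError(f"duplicate landmark ids: {dupes}")
    try:
        pts = df[["x", "y", "z"]].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric landmark coordinate in {path.name}") from exc
    return LandmarkSet(ids=df["id"].tolist(), points=pts)


def write_landmarks(lms: LandmarkSet, path) -> None:
    df = pd.DataFrame(
        {"id": lms.ids, "x": lms.points[:, 0], "y": lms.points[:, 1], "z": lms.points[:, 2]}
    )
    df.to_csv(path, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
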