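"""Volume, mask and annotation I/O with a fixed coordinate convention.

Conventions
-----------
* Voxel indices are 0-based ``(i, j, k)`` tuples into a 3D array.
* ``spacing`` is millimetres per voxel along each array axis.
* ``origin`` is the world (mm) position of the *center* of voxel (0,0,0),
  so ``world = origin + index * spacing`` and voxel centers sit at integer
  indices.
* NIfTI affines must be axis-aligned (diagonal up to sign); volumes with an
  oblique rotation are rejected rather than silently resampled, because all
  downstream geometry assumes an axis-aligned grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

ANNOTATION_FORMAT_VERSION = "1.0"


def _as_spacing(spacing) -> np.ndarray:
    s = np.asarray(spacing, dtype=float)
    if s.shape != (3,):
        raise ValueError(f"spacing must be a 3-vector, got shape {s.shape}")
    if not np.all(s > 0):
        raise ValueError(f"spacing components must be strictly positive, got {s}")
    return s


def _as_origin(origin) -> np.ndarray:
    o = np.asarray(origin, dtype=float)
    if o.shape != (3,):
        raise ValueError(f"origin must be a 3-vector, got shape {o.shape}")
    return o


@dataclass
class CTVolume:
    """A 3D scalar CT grid with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        CT value per voxel (dimensionless CT units).
    spacing : array-like of 3 floats
        mm per voxel along each array axis; strictly positive.
    origin : array-like of 3 floats
        mm world position of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if min(self.data.shape) < 2:
            raise ValueError(
                f"grid must have at least 2 voxels along every axis, got {self.data.shape}"
            )
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    # -- coordinate transforms ------------------------------------------
    def world_to_index(self, point) -> np.ndarray:
        """Map world mm point(s) to continuous 0-based voxel indices."""
        p = np.asarray(point, dtype=float)
        return (p - self.origin) / self.spacing

    def index_to_world(self, index) -> np.ndarray:
        """Map continuous voxel index(es) to world mm coordinates."""
        i = np.asarray(index, dtype=float)
        return self.origin + i * self.spacing

    def in_bounds(self, point) -> np.ndarray | bool:
        """True where a world point falls inside the voxel-center grid."""
        idx = self.world_to_index(point)
        hi = np.asarray(self.shape) - 1
        ok = np.logical_and(idx >= 0, idx <= hi)
        return ok.all(axis=-1)

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class LabelMask:
    """Binary mask aligned to a :class:`CTVolume` grid."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got {self.data.ndim}D")
        if min(self.data.shape) < 2:
            raise ValueError(
                f"grid must have at least 2 voxels along every axis, got {self.data.shape}"
            )
        self.spacing = _as_spacing(self.spacing)
        self.origin = _as_origin(self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())

    def volume_mm3(self) -> float:
        """Mask volume as voxel count times voxel volume."""
        return self.count() * float(np.prod(self.spacing))

    world_to_index = CTVolume.world_to_index
    index_to_world = CTVolume.index_to_world
    in_bounds = CTVolume.in_bounds

    def like(self, data: np.ndarray) -> "LabelMask":
        """New mask with the same grid geometry."""
        return LabelMask(data, self.spacing.copy(), self.origin.copy())


def check_aligned(a, b, *, what: str = "grids") -> None:
    """Raise ValueError unless two volumes/masks share shape, spacing and origin."""
    if a.shape != b.shape:
        raise ValueError(f"misaligned {what}: shapes {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing, rtol=0, atol=1e-9):
        raise ValueError(f"misaligned {what}: spacings {a.spacing} vs {b.spacing}")
    if not np.allclose(a.origin, b.origin, rtol=0, atol=1e-6):
        raise ValueError(f"misaligned {what}: origins {a.origin} vs {b.origin}")


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def _spacing_origin_from_affine(affine: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rot = np.asarray(affine[:3, :3], dtype=float)
    off_diag = rot - np.diag(np.diag(rot))
    scale = max(1.0, float(np.abs(np.diag(rot)).max()))
    if np.abs(off_diag).max() > 1e-4 * scale:
        raise ValueError(
            "oblique NIfTI affine: this pipeline requires an axis-aligned grid "
            "(rotation-free affine); resample the volume first"
        )
    spacing = np.diag(rot).copy()
    origin = np.asarray(affine[:3, 3], dtype=float).copy()
    if np.any(spacing < 0):
        # a negative scale encodes a flipped axis direction; honouring it
        # would require mirroring the data, so reject rather than silently
        # corrupt left/right
        raise ValueError(
            "NIfTI affine has a negative axis scale; flip/resample the volume "
            "to a positive axis-aligned orientation first"
        )
    if not np.all(spacing > 0):
        raise ValueError(f"non-positive spacing in NIfTI header: {np.diag(rot)}")
    return spacing, origin


def read_volume(path) -> CTVolume:
    """Read a 3D NIfTI-1 volume as a :class:`CTVolume`.

    Header slope/intercept scaling is applied (nibabel's default); no other
    rescaling is performed. 4D or oblique images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        pass  # tolerate trailing singleton
    elif len(shape) != 3:
        raise ValueError(f"expected 3D volume, got shape {shape}")
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if data.ndim == 4:
        data = data[..., 0]
    spacing, origin = _spacing_origin_from_affine(img.affine)
    return CTVolume(data, spacing, origin)


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as float32 NIfTI-1."""
    if not isinstance(volume, CTVolume):
        raise TypeError(f"write_volume expects a CTVolume, got {type(volume).__name__}")
    img = nib.Nifti1Image(
        np.asarray(volume.data, dtype=np.float32),
        _affine_from(volume.spacing, volume.origin),
    )
    nib.save(img, str(path))


def read_mask(path) -> LabelMask:
    """Read a binary mask (any nonzero voxel is foreground)."""
    vol = read_volume(path)
    return LabelMask(vol.data != 0, vol.spacing, vol.origin)


def write_mask(mask: LabelMask, path) -> None:
    """Write a LabelMask as a 0/1 uint8 NIfTI-1 volume."""
    if not isinstance(mask, LabelMask):
        raise TypeError(f"write_mask expects a LabelMask, got {type(mask).__name__}")
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8),
        _affine_from(mask.spacing, mask.origin),
    )
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Annotation JSON
# ---------------------------------------------------------------------------
# Scribbles: {"format_version": "1.0",
#             "scribbles": {"foreground": [[i,j,k],...], "background": [[i,j,k],...]}}
# Seeds:     {"format_version": "1.0", "seeds": [[i,j,k],...], "threshold": r}
# Contours:  {"format_version": "1.0",
#             "contours": [{"plane_axis": 0|1|2, "plane_index": int,
#                           "points": [[u,v],...]}]}

def _check_version(doc: dict, path) -> None:
    v = doc.get("format_version")
    if v is None:
        raise ValueError(f"{path}: missing format_version field")
    if str(v).split(".")[0] != ANNOTATION_FORMAT_VERSION.split(".")[0]:
        raise ValueError(f"{path}: unsupported annotation format_version {v!r}")


def save_scribbles(foreground, background, path) -> None:
    doc = {
        "format_version": ANNOTATION_FORMAT_VERSION,
        "scribbles": {
            "foreground": [list(map(int, v)) for v in foreground],
            "background": [list(map(int, v)) for v in background],
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_scribbles(path) -> tuple[list, list]:
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    s = doc["scribbles"]
    return (
        [tuple(int(x) for x in v) for v in s["foreground"]],
        [tuple(int(x) for x in v) for v in s["background"]],
    )


def save_seeds(seeds, threshold, path) -> None:
    doc = {
        "format_version": ANNOTATION_FORMAT_VERSION,
        "seeds": [list(map(int, v)) for v in seeds],
        "threshold": float(threshold),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_seeds(path) -> tuple[list, float]:
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    return (
        [tuple(int(x) for x in v) for v in doc["seeds"]],
        float(doc["threshold"]),
    )


def save_contours(contours, path) -> None:
    """``contours`` is a sequence of (plane_axis, plane_index, points-(N,2))."""
    doc = {
        "format_version": ANNOTATION_FORMAT_VERSION,
        "contours": [
            {
                "plane_axis": int(ax),
                "plane_index": int(pi),
                "points": [[float(u), float(v)] for u, v in pts],
            }
            for ax, pi, pts in contours
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_contours(path) -> list:
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    out = []
    for c in doc["contours"]:
        out.append(
            (
                int(c["plane_axis"]),
                int(c["plane_index"]),
                np.asarray(c["points"], dtype=float),
            )
        )
    return out
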