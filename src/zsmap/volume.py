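"""Core 3D volume types and geometric operations.

Volumes live on axis-aligned lattices in RAS (right-anterior-superior)
millimetre space: axis 0 runs left-to-right, axis 1 posterior-to-anterior,
axis 2 inferior-to-superior.  The midsagittal plane is the centre of axis 0.
All analysis volumes (SPECT counts, T1 intensity, tissue probabilities,
Z maps, integer atlas labels) share the :class:`ImageVolume` carrier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "ImageVolume",
    "RigidRotation",
    "VolumeFormatError",
    "read_volume",
    "write_volume",
    "resample_to",
    "rotate_pitch",
    "flip_left_right",
]

MODALITY_TAGS = ("SPECT", "T1", "probability", "zmap", "label")


class VolumeFormatError(ValueError):
    """Raised for unreadable, non-3D, or geometrically invalid volumes."""


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned sampling lattice with physical geometry.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along each RAS axis.
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    origin : tuple of float
        World (mm) coordinate of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = "RAS"

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise VolumeFormatError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeFormatError(f"voxel sizes must be positive, got {self.voxel_size}")
        if self.axis_convention != "RAS":
            raise VolumeFormatError("only the RAS axis convention is supported")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (diagonal, RAS)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size)
        aff[:3, 3] = self.origin
        return aff

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinate of the grid centre."""
        idx_center = (np.asarray(self.shape) - 1) / 2.0
        return np.asarray(self.origin) + idx_center * np.asarray(self.voxel_size)

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.shape, self.voxel_size))

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centres."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.voxel_size[a] for a in range(3)
        )

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.voxel_size) + np.asarray(self.origin)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.voxel_size)


@dataclass
class ImageVolume:
    """A scalar 3D image on a :class:`VolumeGrid`.

    ``modality_tag`` records the physical meaning of the values:
    ``SPECT`` (counts), ``T1`` (MR intensity), ``probability`` (tissue
    membership in [0, 1]), ``zmap`` (Z units; may contain NaN outside the
    analysis domain) or ``label`` (integer ROI codes).
    """

    grid: VolumeGrid
    values: np.ndarray
    modality_tag: str = "SPECT"
    allow_nan: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.modality_tag not in MODALITY_TAGS:
            raise VolumeFormatError(f"unknown modality_tag {self.modality_tag!r}")
        if self.values.ndim != 3:
            raise VolumeFormatError(f"values must be 3D, got ndim={self.values.ndim}")
        if tuple(self.values.shape) != self.grid.shape:
            raise VolumeFormatError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.modality_tag == "label":
            self.values = np.asarray(np.rint(self.values), dtype=np.int32)
            return
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.isinf(self.values).any():
            raise VolumeFormatError("volume contains infinite values")
        nan_ok = self.allow_nan or self.modality_tag == "zmap"
        if not nan_ok and np.isnan(self.values).any():
            raise VolumeFormatError("volume contains NaN values")
        finite = self.values[np.isfinite(self.values)]
        if self.modality_tag in ("SPECT", "probability") and finite.size and finite.min() < -1e-9:
            raise VolumeFormatError(f"{self.modality_tag} volume has negative values")
        if self.modality_tag == "probability" and finite.size and finite.max() > 1 + 1e-6:
            raise VolumeFormatError("probability volume exceeds 1")

    def with_values(self, values: np.ndarray, modality_tag: str | None = None,
                    allow_nan: bool | None = None) -> "ImageVolume":
        return ImageVolume(
            self.grid,
            values,
            modality_tag if modality_tag is not None else self.modality_tag,
            allow_nan=self.allow_nan if allow_nan is None else allow_nan,
        )

    def copy(self) -> "ImageVolume":
        return self.with_values(self.values.copy())


@dataclass(frozen=True)
class RigidRotation:
    """Pitch rotation about the left-right axis through the grid centre.

    Positive angles tilt the anterior edge downward (towards inferior) when
    viewed from the subject's left — the sense used to bring AC-PC-aligned
    volumes parallel to the orbito-meatal line (+10 deg) or to the
    hippocampal long-axis display plane (~+34 deg).  Pass ``sign=-1`` for
    the opposite convention.
    """

    angle_deg: float
    sign: int = 1

    def __post_init__(self):
        if not -90.0 < self.angle_deg < 90.0:
            raise ValueError(f"pitch angle must be in (-90, 90) deg, got {self.angle_deg}")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")

    @property
    def matrix_yz(self) -> np.ndarray:
        """2x2 rotation acting on (anterior, superior) world offsets."""
        th = math.radians(self.sign * self.angle_deg)
        c, s = math.cos(th), math.sin(th)
        return np.array([[c, -s], [s, c]])

    def inverse(self) -> "RigidRotation":
        return RigidRotation(-self.angle_deg, self.sign)


# ---------------------------------------------------------------------------
# NIfTI I/O

def read_volume(path: str | Path, modality_tag: str = "SPECT") -> ImageVolume:
    """Read a 3D NIfTI-1 volume.

    The grid is populated from the header: voxel sizes from ``pixdim``,
    origin from the affine translation.  Values are cast to float (or int
    for ``label`` volumes).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error paths
        raise VolumeFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 3 and all(s == 1 for s in data.shape[3:]) else data
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel size {zooms}")
    origin = tuple(float(t) for t in img.affine[:3, 3])
    grid = VolumeGrid(shape=data.shape, voxel_size=zooms, origin=origin)
    return ImageVolume(grid, data, modality_tag)


def write_volume(vol: ImageVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 (float32, or uint8/int16 for labels)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if vol.modality_tag == "label":
        data = vol.values.astype(np.int16)
    else:
        data = vol.values.astype(np.float32)
    img = nib.Nifti1Image(data, vol.grid.affine)
    img.header.set_zooms(vol.grid.voxel_size)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Resampling and rigid geometry

def _interp_order(interpolation: str) -> int:
    if interpolation == "trilinear":
        return 1
    if interpolation == "nearest":
        return 0
    raise ValueError(f"unknown interpolation {interpolation!r} (use 'trilinear' or 'nearest')")


def resample_to(vol: ImageVolume, target: VolumeGrid,
                interpolation: str = "trilinear") -> ImageVolume:
    """Resample a volume onto ``target`` by world-coordinate lookup.

    Use ``nearest`` for label/mask volumes and ``trilinear`` otherwise.
    Voxels sampling outside the source field of view are filled with 0.
    """
    order = _interp_order(interpolation)
    if vol.grid == target:
        return vol.copy()
    # target voxel centres expressed as source indices
    tx, ty, tz = np.meshgrid(*target.world_coords(), indexing="ij")
    src_idx = np.stack(
        [
            (tx - vol.grid.origin[0]) / vol.grid.voxel_size[0],
            (ty - vol.grid.origin[1]) / vol.grid.voxel_size[1],
            (tz - vol.grid.origin[2]) / vol.grid.voxel_size[2],
        ]
    )
    out = ndimage.map_coordinates(
        np.asarray(vol.values, dtype=float), src_idx, order=order, mode="constant", cval=0.0
    )
    tag = vol.modality_tag
    if tag == "label":
        out = np.rint(out).astype(np.int32)
    return ImageVolume(target, out, tag, allow_nan=vol.allow_nan)


def rotate_pitch(vol: ImageVolume, rot: RigidRotation,
                 interpolation: str = "trilinear") -> ImageVolume:
    """Rotate about the left-right axis through the grid centre.

    The output stays on the input grid; signal rotated outside the field of
    view is lost, so pad volumes that must conserve total signal.
    """
    order = _interp_order(interpolation)
    if rot.angle_deg == 0.0:
        return vol.copy()
    R = rot.matrix_yz  # acts on (y, z) world offsets
    center = vol.grid.center_mm
    vy, vz = vol.grid.voxel_size[1], vol.grid.voxel_size[2]
    # inverse map: output index -> input index (rotate offsets by R^-1)
    Rinv = R.T
    # build in index space: offset_idx * voxel -> mm, rotate, back to idx
    mat = np.eye(3)
    mat[1, 1] = Rinv[0, 0]
    mat[1, 2] = Rinv[0, 1] * vz / vy
    mat[2, 1] = Rinv[1, 0] * vy / vz
    mat[2, 2] = Rinv[1, 1]
    center_idx = (np.asarray(vol.grid.shape) - 1) / 2.0
    offset = center_idx - mat @ center_idx
    out = ndimage.affine_transform(
        np.asarray(vol.values, dtype=float), mat, offset=offset, order=order,
        mode="constant", cval=0.0,
    )
    if vol.modality_tag == "label":
        out = np.rint(out).astype(np.int32)
    _ = center  # pivot is the grid centre by construction
    return vol.with_values(out)


def flip_left_right(vol: ImageVolume) -> ImageVolume:
    """Mirror across the midsagittal plane (centre of the left-right axis)."""
    return vol.with_values(np.ascontiguousarray(vol.values[::-1, :, :]))


def common_grid(vols: Iterable[ImageVolume]) -> VolumeGrid:
    """Return the shared grid of ``vols`` or raise on mismatch."""
    vols = list(vols)
    if not vols:
        raise ValueError("no volumes given")
    grid = vols[0].grid
    for v in vols[1:]:
        if v.grid != grid:
            raise VolumeFormatError("volumes are not on a common grid")
    return grid
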