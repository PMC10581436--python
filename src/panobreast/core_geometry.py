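"""Volume data model, NIfTI I/O, world-coordinate resampling and symmetry rotations.

All images live in a single fixed world convention: axis 0 = left-right (LR),
axis 1 = anterior-posterior (AP), axis 2 = head-foot (HF), coordinates in mm
(this is the RAS+ convention with anatomical labels for a supine subject).
Files read from disk are reoriented into this frame before anything else
touches them, so every downstream module can reason about "anterior" as +AP
without ever inspecting an affine.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

AXIS_LABELS = ("LR", "AP", "HF")

#: index of each anatomical axis in the canonical frame
AXIS_INDEX = {"LR": 0, "AP": 1, "HF": 2}


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    spacing = np.linalg.norm(affine[:3, :3], axis=0)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be strictly positive")
    return affine


@dataclasses.dataclass
class Volume:
    """A real scalar 3D image with a voxel-index -> world-mm affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D payload")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite voxels")
        self.affine = _check_affine(self.affine)

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm (column norms of the 3x3 affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_center(self) -> np.ndarray:
        """World coordinate of the geometric grid center."""
        ijk = (np.asarray(self.data.shape, dtype=float) - 1.0) / 2.0
        return (self.affine @ np.append(ijk, 1.0))[:3]

    def grid_world_points(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (N, 3)."""
        idx = np.indices(self.data.shape, dtype=float).reshape(3, -1)
        pts = self.affine[:3, :3] @ idx + self.affine[:3, 3:4]
        return pts.T

    def with_data(self, data: np.ndarray) -> "Volume":
        return type(self)(data=data, affine=self.affine.copy())


@dataclasses.dataclass
class Segmentation(Volume):
    """A binary mask sharing the Volume geometry; nearest-neighbor only."""

    def __post_init__(self) -> None:
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("segmentation values must be in {0, 1}")
        self.data = self.data.astype(np.uint8)


@dataclasses.dataclass
class RigidRotation:
    """Rotation by `angle_deg` about a world axis through `center` (mm)."""

    axis: str
    angle_deg: float
    center: np.ndarray

    def __post_init__(self) -> None:
        if self.axis not in AXIS_INDEX:
            raise ValueError(f"unknown axis {self.axis!r}, expected one of {AXIS_LABELS}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def matrix(self) -> np.ndarray:
        """4x4 world->world map rotating points by +angle about the axis."""
        theta = np.deg2rad(self.angle_deg)
        c, s = np.cos(theta), np.sin(theta)
        k = AXIS_INDEX[self.axis]
        i, j = [ax for ax in range(3) if ax != k]
        rot3 = np.eye(3)
        rot3[i, i] = c
        rot3[i, j] = -s
        rot3[j, i] = s
        rot3[j, j] = c
        mat = np.eye(4)
        mat[:3, :3] = rot3
        mat[:3, 3] = self.center - rot3 @ self.center
        return mat

    def inverse(self) -> "RigidRotation":
        return RigidRotation(self.axis, -self.angle_deg, self.center.copy())


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def read_nifti(path: str | Path, segmentation: bool = False) -> Volume:
    """Read a NIfTI-1 volume, reoriented into the LR/AP/HF world frame.

    Parameters
    ----------
    path:
        Path to a ``.nii`` / ``.nii.gz`` file holding a 3D scalar image.
    segmentation:
        If true, the payload is validated as a binary mask and returned as a
        :class:`Segmentation`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # RAS+ == LR/AP/HF
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D payload in {path}")
    if not np.isfinite(data).all():
        raise ValueError(f"non-finite voxels in {path}")
    cls = Segmentation if segmentation else Volume
    return cls(data=data, affine=np.asarray(img.affine, dtype=float))


def write_nifti(vol: Volume, path: str | Path) -> Path:
    """Write a Volume/Segmentation as NIfTI-1; round-trips losslessly."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# World-coordinate sampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"linear": 1, "nearest": 0}


def sample_world(vol: Volume, points: np.ndarray, interp: str = "linear") -> np.ndarray:
    """Sample a volume at world-mm points; out-of-field points return 0.

    ``interp`` is ``"linear"`` (images) or ``"nearest"`` (segmentations).
    Linear sampling at an exact voxel center reproduces the stored value.
    """
    if interp not in _INTERP_ORDER:
        raise ValueError(f"unknown interpolation mode {interp!r}")
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if not np.isfinite(pts).all():
        raise ValueError("sample points must be finite")
    inv = np.linalg.inv(vol.affine)
    ijk = (inv[:3, :3] @ pts.T + inv[:3, 3:4])
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float),
        ijk,
        order=_INTERP_ORDER[interp],
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return out[0] if single else out


def resample_to_grid(
    vol: Volume,
    world_points: np.ndarray,
    out_shape: tuple[int, ...],
    out_affine: np.ndarray,
    interp: str = "linear",
) -> Volume:
    """Sample `vol` at `world_points` and wrap the result on a new grid.

    Segmentations are always sampled nearest-neighbor (label preservation),
    whatever `interp` says.
    """
    if isinstance(vol, Segmentation):
        values = sample_world(vol, world_points, interp="nearest").reshape(out_shape)
        return Segmentation(data=values.astype(np.uint8), affine=out_affine)
    values = sample_world(vol, world_points, interp=interp).reshape(out_shape)
    return Volume(data=values, affine=out_affine)


def rotate_volume(vol: Volume, rotation: RigidRotation, interp: str = "linear") -> Volume:
    """Resample `vol` on its own grid after rotating the object by `rotation`."""
    inv = np.linalg.inv(rotation.matrix())
    pts = vol.grid_world_points()
    src = (inv[:3, :3] @ pts.T + inv[:3, 3:4]).T
    return resample_to_grid(vol, src, vol.data.shape, vol.affine.copy(), interp=interp)


# ---------------------------------------------------------------------------
# Symmetry-optimizing rotation
# ---------------------------------------------------------------------------

def _mirror_lr(data: np.ndarray) -> np.ndarray:
    return data[::-1, :, :]


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return np.nan
    return float(a @ b / denom)


def rotate_for_symmetry(
    vol: Volume,
    axis: str = "HF",
    search_range: float = 15.0,
    step: float = 1.0,
) -> tuple[RigidRotation, Volume]:
    """Find the rotation maximizing left-right mirror symmetry.

    A 1D grid search over angles in [-search_range, +search_range] (degrees,
    given step) about the world `axis` through the grid center.  The score is
    the normalized cross-correlation between the rotated volume and its LR
    mirror image; ties are broken toward the smaller |angle|.  Returns the
    winning rotation and the volume resampled once at that angle.
    """
    if search_range <= 0 or step <= 0 or step > search_range:
        raise ValueError("require 0 < step <= search_range")
    if np.ptp(vol.data) == 0:
        raise ValueError("symmetry score undefined for a constant volume")

    center = vol.world_center()
    n = int(round(search_range / step))
    angles = np.concatenate(([0.0], *[[-k * step, k * step] for k in range(1, n + 1)]))
    # ordered by |angle| so a strict ">" comparison breaks ties toward 0
    best_score = -np.inf
    best_angle = 0.0
    best_vol: Volume | None = None
    for angle in angles:
        rot = RigidRotation(axis, float(angle), center)
        rotated = rotate_volume(vol, rot, interp="linear")
        score = _ncc(rotated.data, _mirror_lr(rotated.data))
        if np.isnan(score):
            continue
        if score > best_score + 1e-12:
            best_score, best_angle, best_vol = score, float(angle), rotated
    if best_vol is None:
        raise ValueError("symmetry score undefined for a constant volume")
    return RigidRotation(axis, best_angle, center), best_vol
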