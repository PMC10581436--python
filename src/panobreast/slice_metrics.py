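"""Reading-efficiency metrics: slice counts, tight crops, reduction factors.

A slice "contains breast tissue" when it holds strictly more than
`min_voxels` (default 10) segmented voxels — the threshold is strict by
design.  Counts are taken after tight cropping to the slices passing that
rule, so isolated specks neither extend the crop box nor the count.
The panoramic view is counted along its flattened-depth (AP-like) axis,
mirroring coronal-style reading of the flattened slab; Cartesian axial
views count along HF and coronal views along AP.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np

from .core_geometry import AXIS_INDEX, Segmentation

#: counting axis per named view
VIEW_AXES = {
    "prone_axial_ref": "HF",
    "supine_axial": "HF",
    "supine_coronal": "AP",
    "panoramic": "AP",
}


@dataclasses.dataclass
class BoundingBox:
    lo_voxel: tuple[int, int, int]
    hi_voxel: tuple[int, int, int]  # inclusive
    size_voxels: tuple[int, int, int]
    size_mm: tuple[float, float, float]
    empty: bool = False

    @classmethod
    def empty_box(cls) -> "BoundingBox":
        return cls((0, 0, 0), (-1, -1, -1), (0, 0, 0), (0.0, 0.0, 0.0), empty=True)


@dataclasses.dataclass
class SliceCountReport:
    counts: dict[str, int]
    reduction_factors: dict[str, float]
    crop_extents: dict[str, BoundingBox]

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "reduction_factors": self.reduction_factors,
            "crop_extents": {
                k: dataclasses.asdict(v) for k, v in self.crop_extents.items()
            },
        }
        return json.dumps(payload, indent=1)

    def table(self) -> str:
        lines = [f"{'view':<18}{'slices':>8}", "-" * 26]
        lines += [f"{k:<18}{v:>8}" for k, v in self.counts.items()]
        lines.append("")
        lines += [f"{k}: x{v:.2f}" for k, v in self.reduction_factors.items()]
        return "\n".join(lines)


def _axis_index(axis: int | str) -> int:
    return AXIS_INDEX[axis] if isinstance(axis, str) else int(axis)


def _slice_counts(seg: Segmentation, axis: int) -> np.ndarray:
    other = tuple(ax for ax in range(3) if ax != axis)
    return seg.data.astype(np.int64).sum(axis=other)


def slices_with_tissue(seg: Segmentation, axis: int | str, min_voxels: int = 10) -> int:
    """Number of slices along `axis` with strictly more than `min_voxels`
    tissue voxels ("more than 10" is > 10, not >= 10)."""
    axis = _axis_index(axis)
    if not seg.data.any():
        warnings.warn("empty segmentation: slice count is 0")
        return 0
    return int((_slice_counts(seg, axis) > min_voxels).sum())


def tight_crop(seg: Segmentation, min_voxels: int = 10) -> BoundingBox:
    """Smallest box containing, on every axis, all slices passing the
    min_voxels rule; reported in voxels and mm."""
    lo, hi = [], []
    for axis in range(3):
        passing = np.flatnonzero(_slice_counts(seg, axis) > min_voxels)
        if passing.size == 0:
            return BoundingBox.empty_box()
        lo.append(int(passing[0]))
        hi.append(int(passing[-1]))
    size_vox = tuple(h - l + 1 for l, h in zip(lo, hi))
    spacing = seg.spacing
    return BoundingBox(
        lo_voxel=tuple(lo),
        hi_voxel=tuple(hi),
        size_voxels=size_vox,  # type: ignore[arg-type]
        size_mm=tuple(float(n * s) for n, s in zip(size_vox, spacing)),
    )


def reduction_report(
    roi_views: dict[str, Segmentation],
    panoramic_roi: Segmentation,
    min_voxels: int = 10,
) -> SliceCountReport:
    """Slice counts per view and reference/panoramic reduction factors."""
    counts: dict[str, int] = {}
    crops: dict[str, BoundingBox] = {}

    pano_axis = VIEW_AXES["panoramic"]
    pano_count = slices_with_tissue(panoramic_roi, pano_axis, min_voxels)
    counts["panoramic"] = pano_count
    crops["panoramic"] = tight_crop(panoramic_roi, min_voxels)

    factors: dict[str, float] = {}
    for view, axis in VIEW_AXES.items():
        if view == "panoramic":
            continue
        seg = roi_views.get(view)
        if seg is None:
            warnings.warn(f"reference view {view!r} missing; skipped")
            continue
        n = slices_with_tissue(seg, axis, min_voxels)
        counts[view] = n
        crops[view] = tight_crop(seg, min_voxels)
        if pano_count > 0:
            factors[f"{view}_vs_panoramic"] = n / pano_count
    return SliceCountReport(counts=counts, reduction_factors=factors, crop_extents=crops)


def breast_volume_ml(seg: Segmentation) -> float:
    """Segmented volume in mL: voxel count x voxel volume (mm^3) / 1000."""
    vals = np.unique(seg.data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("segmentation must be binary")
    voxel_mm3 = float(abs(np.linalg.det(seg.affine[:3, :3])))
    return float(seg.data.sum()) * voxel_mm3 / 1000.0
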