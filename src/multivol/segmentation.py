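"""Ad hoc segmentation and sub-volume extraction.

A sphere brush (the scripted stand-in for painting with a motion-tracked
controller) assigns labels to voxels; a segment's tight axis-aligned voxel
bounding box is then computed and the labelled region is copied out into a
new, independently posed volume node.  The source volume hides the segment
purely by setting its per-segment opacity to zero — no voxel data is
mutated, so the operation is trivially reversible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import (
    AffinePose,
    ScalarVolume,
    Scene,
    SegmentationMask,
    VolumeNode,
    transform_point,
)

__all__ = ["VoxelAABB", "paint_sphere", "segment_aabb", "extract_segment"]


@dataclass(frozen=True)
class VoxelAABB:
    """Inclusive integer voxel bounds, ``lo <= hi`` componentwise."""

    lo: Tuple[int, int, int]
    hi: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(l > h for l, h in zip(self.lo, self.hi)):
            raise ValueError("AABB lo must be <= hi componentwise")

    def padded(self, pad: int, dims: Tuple[int, int, int]) -> "VoxelAABB":
        lo = tuple(max(0, l - pad) for l in self.lo)
        hi = tuple(min(d - 1, h + pad) for h, d in zip(self.hi, dims))
        return VoxelAABB(lo, hi)

    def slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(l, h + 1) for l, h in zip(self.lo, self.hi))  # type: ignore


def paint_sphere(
    mask: SegmentationMask,
    center: np.ndarray,
    radius: float,
    label: int,
    volume: ScalarVolume,
    pose: AffinePose = None,
) -> SegmentationMask:
    """Assign ``label`` to every voxel whose world-space center lies within
    ``radius`` mm of ``center``, overwriting previous labels (in place).

    ``volume``/``pose`` define the voxel-to-world mapping of the painted
    grid; label 0 is reserved for "unassigned" and cannot be painted.
    """
    label = int(label)
    if not 1 <= label <= 255:
        raise ValueError("brush label must be in [1, 255] (0 is reserved)")
    if radius <= 0:
        raise ValueError("brush radius must be positive")
    if mask.dims != volume.dims:
        raise ValueError("mask and volume dims differ")
    pose = pose or AffinePose.identity()
    center_local = transform_point(pose, np.asarray(center, dtype=np.float64), inverse=True)
    spacing = np.asarray(volume.spacing)
    center_vox = center_local / spacing

    # only iterate the voxel box that can possibly be inside the brush;
    # a world sphere maps to a local ellipsoid bounded by radius * ||M^-1||
    rad_vox = radius * np.linalg.norm(pose.inverse_matrix[:3, :3], 2) / spacing
    lo = np.maximum(0, np.floor(center_vox - rad_vox).astype(int) - 1)
    hi = np.minimum(np.array(volume.dims) - 1, np.ceil(center_vox + rad_vox).astype(int) + 1)
    if np.any(lo > hi):
        return mask
    ii, jj, kk = np.meshgrid(
        *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
    )
    pts_local = np.stack([ii, jj, kk], axis=-1) * spacing
    pts_world = transform_point(pose, pts_local.reshape(-1, 3)).reshape(pts_local.shape)
    d2 = np.sum((pts_world - np.asarray(center)) ** 2, axis=-1)
    inside = d2 <= radius * radius
    region = mask.labels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    region[inside] = label
    return mask


def segment_aabb(mask: SegmentationMask, label: int) -> VoxelAABB:
    """Tight inclusive voxel bounds of all voxels carrying ``label``."""
    label = int(label)
    if not 1 <= label <= 255:
        raise ValueError("segment label must be in [1, 255]")
    where = mask.labels == label
    if not where.any():
        raise ValueError(f"label {label} not present in mask: nothing to extract")
    idx = np.nonzero(where)
    lo = tuple(int(a.min()) for a in idx)
    hi = tuple(int(a.max()) for a in idx)
    return VoxelAABB(lo, hi)


def extract_segment(
    scene: Scene, node: VolumeNode, label: int, pad: int = 1
) -> VolumeNode:
    """Extract a labelled segment of ``node`` into a new scene node.

    The segment's padded AABB of intensity data is copied into a new volume
    (padding, clamped at the source extent, gives trilinear sampling support
    at the segment boundary).  The new node keeps only the segment's own
    voxels visible: its mask is the source labels restricted to ``label``
    and its transfer function — a copy of the source's, visualization
    settings included — hides unassigned voxels.  Its pose composes the
    source pose with the AABB offset so the extracted piece initially
    renders exactly in place.  The source node hides the segment by setting
    its segment opacity to 0 and the new node is appended to the scene with
    the next creation index.
    """
    if node.mask is None:
        raise ValueError("node has no segmentation mask")
    if pad < 0:
        raise ValueError("pad must be >= 0")
    box = segment_aabb(node.mask, label).padded(pad, node.volume.dims)
    sl = box.slices()

    data = node.volume.data[sl].copy()
    labels = node.mask.labels[sl].copy()
    labels[labels != label] = 0

    new_tf = node.tf.copy()
    new_tf.set_segment_opacity(0, 0.0)  # only the segment itself is visible
    new_tf.set_segment_opacity(label, 1.0)

    offset_mm = np.asarray(box.lo) * np.asarray(node.volume.spacing)
    new_pose = node.pose.compose(AffinePose.from_translation(offset_mm))

    new_node = VolumeNode(
        volume=ScalarVolume(
            data, node.volume.spacing, name=f"{node.volume.name}_seg{label}"
        ),
        mask=SegmentationMask(labels),
        tf=new_tf,
        pose=new_pose,
        visible=True,
        creation_index=scene.next_creation_index(),
    )
    node.tf.set_segment_opacity(label, 0.0)  # hide the segment in the source
    scene.add(new_node)
    return new_node
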