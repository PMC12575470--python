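"""Shared domain types, coordinate transforms, and point sampling/classification.

Conventions used throughout the package:

* A volume's *voxel coordinates* place voxel centers at integer positions
  ``0 .. dim-1`` per axis.  The renderable local box extends half a voxel
  beyond the outermost centers, i.e. ``[-0.5, dim-0.5] * spacing`` in local
  millimetres, so trilinear interpolation is defined everywhere inside the
  box via clamping.
* A node's :class:`AffinePose` maps local millimetre coordinates
  (``voxel_index * spacing``) to world millimetres.
* Intensities are sampled trilinearly; segmentation labels are looked up
  nearest-neighbour so interpolation can never invent a label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ScalarVolume",
    "SegmentationMask",
    "TransferFunction",
    "AffinePose",
    "Camera",
    "VolumeNode",
    "Scene",
    "transform_point",
    "transform_vector",
    "sample_intensity",
    "sample_label",
    "classify",
    "binary_tf",
    "ramp_tf",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ScalarVolume:
    """A 3D scalar intensity grid (CT-style, e.g. Hounsfield units).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel intensities, indexed ``data[ix, iy, iz]``.
    spacing : tuple of 3 floats
        Millimetres per voxel along each axis; strictly positive.
    name : str
        Identifier used in logs and scene configs.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = "volume"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if any(d < 1 for d in self.data.shape):
            raise ValueError("volume dims must be >= 1 per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 positive values")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class SegmentationMask:
    """An 8-bit label grid co-registered with a volume; 0 means unassigned."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError("mask labels must be 3D")
        if labels.dtype != np.uint8:
            if labels.min(initial=0) < 0 or labels.max(initial=0) > 255:
                raise ValueError("mask labels must lie in [0, 255]")
            labels = labels.astype(np.uint8)
        self.labels = labels

    @property
    def dims(self) -> Tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]


class TransferFunction:
    """Piecewise-linear intensity -> RGBA lookup with per-segment opacity.

    Parameters
    ----------
    control_points : sequence of (intensity, r, g, b, alpha)
        Strictly increasing in intensity; at least two points; alpha in [0,1].
        Evaluation outside the intensity domain clamps to the end values.
    segment_opacity : mapping label -> multiplier in [0, 1]
        Per-label opacity multiplier; labels not listed default to 1.
        Setting a label's multiplier to 0 hides that segment.
    reference_step : float
        Step length (mm) at which the stored alphas are calibrated; sampled
        alphas are rescaled for other step sizes via exponential
        transmittance: ``a' = 1 - (1 - a) ** (step / reference_step)``.
    """

    def __init__(
        self,
        control_points: Sequence[Sequence[float]],
        segment_opacity: Optional[Mapping[int, float]] = None,
        reference_step: float = 1.0,
    ) -> None:
        pts = np.asarray(control_points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 5 or pts.shape[0] < 2:
            raise ValueError("need >= 2 control points of (intensity, r, g, b, alpha)")
        if not np.all(np.diff(pts[:, 0]) > 0):
            raise ValueError("control point intensities must be strictly increasing")
        if pts[:, 4].min() < 0 or pts[:, 4].max() > 1:
            raise ValueError("control point alphas must lie in [0, 1]")
        if reference_step <= 0:
            raise ValueError("reference_step must be positive")
        self.control_points = pts
        self.reference_step = float(reference_step)
        self.segment_opacity = np.ones(256, dtype=np.float64)
        if segment_opacity:
            for label, mult in segment_opacity.items():
                label = int(label)
                if not 0 <= label <= 255:
                    raise ValueError(f"segment label {label} outside [0, 255]")
                if not 0.0 <= mult <= 1.0:
                    raise ValueError(f"segment opacity {mult} outside [0, 1]")
                self.segment_opacity[label] = float(mult)

    def copy(self) -> "TransferFunction":
        tf = TransferFunction(self.control_points.copy(), None, self.reference_step)
        tf.segment_opacity = self.segment_opacity.copy()
        return tf

    def set_segment_opacity(self, label: int, mult: float) -> None:
        if not 0 <= int(label) <= 255:
            raise ValueError("label outside [0, 255]")
        if not 0.0 <= mult <= 1.0:
            raise ValueError("opacity multiplier outside [0, 1]")
        self.segment_opacity[int(label)] = float(mult)

    def lookup(self, intensity: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Raw piecewise-linear RGBA at ``intensity`` (no segment/step terms)."""
        x = self.control_points[:, 0]
        intensity = np.asarray(intensity, dtype=np.float64)
        rgb = np.stack(
            [np.interp(intensity, x, self.control_points[:, 1 + c]) for c in range(3)],
            axis=-1,
        )
        alpha = np.interp(intensity, x, self.control_points[:, 4])
        return rgb, alpha

    def max_alpha_in_range(self, lo: float, hi: float) -> float:
        """Largest raw alpha attained for any intensity in ``[lo, hi]``.

        Used by the empty-space-skipping grid: the maximum of a piecewise
        linear function on an interval occurs at the interval ends or at an
        interior control point.
        """
        if hi < lo:
            lo, hi = hi, lo
        x = self.control_points[:, 0]
        a = self.control_points[:, 4]
        cand = [float(np.interp(lo, x, a)), float(np.interp(hi, x, a))]
        inside = (x >= lo) & (x <= hi)
        if inside.any():
            cand.append(float(a[inside].max()))
        return max(cand)


@dataclass
class AffinePose:
    """A 4x4 homogeneous local-mm -> world-mm transform."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (4, 4):
            raise ValueError("pose matrix must be 4x4")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("pose bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("pose matrix is singular")
        self.matrix = m
        self._inverse = np.linalg.inv(m)

    @classmethod
    def identity(cls) -> "AffinePose":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t: Sequence[float]) -> "AffinePose":
        m = np.eye(4)
        m[:3, 3] = np.asarray(t, dtype=np.float64)
        return cls(m)

    @classmethod
    def from_rotation_translation(
        cls, rotation_deg: Sequence[float], translation: Sequence[float]
    ) -> "AffinePose":
        """Pose from XYZ-intrinsic Euler angles (degrees) and a translation (mm)."""
        rx, ry, rz = (np.deg2rad(a) for a in rotation_deg)
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        mx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        my = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        mz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        m = np.eye(4)
        m[:3, :3] = mz @ my @ mx
        m[:3, 3] = np.asarray(translation, dtype=np.float64)
        return cls(m)

    def compose(self, other: "AffinePose") -> "AffinePose":
        """``self @ other`` — apply ``other`` first, then ``self``."""
        return AffinePose(self.matrix @ other.matrix)

    @property
    def inverse_matrix(self) -> np.ndarray:
        return self._inverse


@dataclass
class Camera:
    """Perspective pinhole camera with orthonormal axes.

    ``forward`` points into the scene; pixel (0, 0) is the top-left corner
    and rays pass through pixel centers.
    """

    eye: np.ndarray
    right: np.ndarray
    up: np.ndarray
    forward: np.ndarray
    vfov: float = 40.0
    image_size: Tuple[int, int] = (256, 256)
    near: float = 1.0
    far: float = 1000.0

    def __post_init__(self) -> None:
        self.eye = np.asarray(self.eye, dtype=np.float64)
        self.right = np.asarray(self.right, dtype=np.float64)
        self.up = np.asarray(self.up, dtype=np.float64)
        self.forward = np.asarray(self.forward, dtype=np.float64)
        if not (0.0 < self.near < self.far):
            raise ValueError("require 0 < near < far")
        if not (0.0 < self.vfov < 180.0):
            raise ValueError("require 0 < vfov < 180")
        axes = np.stack([self.right, self.up, self.forward])
        if not np.allclose(axes @ axes.T, np.eye(3), atol=1e-8):
            raise ValueError("camera axes must be orthonormal")
        w, h = self.image_size
        if w < 1 or h < 1:
            raise ValueError("image size must be positive")
        self.image_size = (int(w), int(h))

    @classmethod
    def look_at(
        cls,
        eye: Sequence[float],
        target: Sequence[float],
        up_hint: Sequence[float] = (0.0, 0.0, 1.0),
        **kwargs,
    ) -> "Camera":
        eye = np.asarray(eye, dtype=np.float64)
        fwd = np.asarray(target, dtype=np.float64) - eye
        n = np.linalg.norm(fwd)
        if n == 0:
            raise ValueError("eye and target coincide")
        fwd = fwd / n
        up_hint = np.asarray(up_hint, dtype=np.float64)
        right = np.cross(fwd, up_hint)
        rn = np.linalg.norm(right)
        if rn < 1e-12:
            right = np.cross(fwd, np.array([1.0, 0.0, 0.0]))
            rn = np.linalg.norm(right)
        right = right / rn
        up = np.cross(right, fwd)
        up = up / np.linalg.norm(up)
        return cls(eye=eye, right=right, up=up, forward=fwd, **kwargs)


@dataclass
class VolumeNode:
    """A volume placed in the scene with its mask, transfer function and pose."""

    volume: ScalarVolume
    tf: TransferFunction
    mask: Optional[SegmentationMask] = None
    pose: AffinePose = field(default_factory=AffinePose.identity)
    visible: bool = True
    creation_index: int = 0

    def __post_init__(self) -> None:
        if self.mask is not None and self.mask.dims != self.volume.dims:
            raise ValueError(
                f"mask dims {self.mask.dims} != volume dims {self.volume.dims}"
            )

    @property
    def name(self) -> str:
        return self.volume.name

    def local_box(self) -> Tuple[np.ndarray, np.ndarray]:
        """Renderable box in local mm: ``[-0.5, dim-0.5] * spacing`` per axis."""
        dims = np.asarray(self.volume.dims, dtype=np.float64)
        sp = np.asarray(self.volume.spacing, dtype=np.float64)
        return -0.5 * sp, (dims - 0.5) * sp

    def world_corners(self) -> np.ndarray:
        """The 8 world-space corners of the local box, shape (8, 3)."""
        lo, hi = self.local_box()
        corners = np.array(
            [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
        )
        return transform_point(self.pose, corners)


@dataclass
class Scene:
    """An ordered collection of volume nodes plus camera-independent state."""

    nodes: list = field(default_factory=list)
    background: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    light: Optional[object] = None  # multivolume.Light
    opaque_layer: Optional[Tuple[np.ndarray, np.ndarray]] = None  # (color HxWx3, z-depth HxW)

    def add(self, node: VolumeNode) -> VolumeNode:
        existing = {n.creation_index for n in self.nodes}
        if node.creation_index in existing:
            node.creation_index = self.next_creation_index()
        self.nodes.append(node)
        return node

    def next_creation_index(self) -> int:
        return 1 + max((n.creation_index for n in self.nodes), default=-1)

    def visible_nodes(self, order: str = "creation") -> list:
        nodes = [n for n in self.nodes if n.visible]
        if order == "creation":
            return sorted(nodes, key=lambda n: n.creation_index)
        raise ValueError(f"unknown node order {order!r}")

    def world_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        if not self.nodes:
            raise ValueError("empty scene has no bounds")
        corners = np.concatenate([n.world_corners() for n in self.nodes])
        return corners.min(axis=0), corners.max(axis=0)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def transform_point(pose: AffinePose, point: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Apply the pose (or its inverse) to point(s) of shape ``(..., 3)``."""
    m = pose.inverse_matrix if inverse else pose.matrix
    p = np.asarray(point, dtype=np.float64)
    return p @ m[:3, :3].T + m[:3, 3]


def transform_vector(pose: AffinePose, vec: np.ndarray, inverse: bool = False) -> np.ndarray:
    """Apply only the linear part of the pose to direction vector(s)."""
    m = pose.inverse_matrix if inverse else pose.matrix
    return np.asarray(vec, dtype=np.float64) @ m[:3, :3].T


def sample_intensity(volume: ScalarVolume, p: np.ndarray) -> np.ndarray:
    """Trilinear intensity at continuous voxel coordinates ``p`` of shape (..., 3).

    Coordinates outside ``[0, dim-1]`` clamp to the boundary voxel, so the
    whole local sampling box ``[-0.5, dim-0.5]`` is covered.
    """
    p = np.asarray(p, dtype=np.float64)
    data = volume.data
    nx, ny, nz = data.shape
    dims = np.array([nx, ny, nz], dtype=np.float64)
    pc = np.clip(p, 0.0, dims - 1.0)
    i0 = np.floor(pc).astype(np.int64)
    # keep i0+1 in range; at the upper boundary the fraction is then exactly 1
    i0 = np.minimum(i0, np.maximum(data.shape, 2) - 2)
    i0 = np.maximum(i0, 0)
    f = pc - i0
    i1 = np.minimum(i0 + 1, np.array(data.shape) - 1)
    x0, y0, z0 = i0[..., 0], i0[..., 1], i0[..., 2]
    x1, y1, z1 = i1[..., 0], i1[..., 1], i1[..., 2]
    fx, fy, fz = f[..., 0], f[..., 1], f[..., 2]
    d = data.astype(np.float64, copy=False)
    c00 = d[x0, y0, z0] * (1 - fx) + d[x1, y0, z0] * fx
    c10 = d[x0, y1, z0] * (1 - fx) + d[x1, y1, z0] * fx
    c01 = d[x0, y0, z1] * (1 - fx) + d[x1, y0, z1] * fx
    c11 = d[x0, y1, z1] * (1 - fx) + d[x1, y1, z1] * fx
    c0 = c00 * (1 - fy) + c10 * fy
    c1 = c01 * (1 - fy) + c11 * fy
    return c0 * (1 - fz) + c1 * fz


def sample_label(mask: Optional[SegmentationMask], p: np.ndarray) -> np.ndarray:
    """Nearest-neighbour label at continuous voxel coordinates (0 outside)."""
    p = np.asarray(p, dtype=np.float64)
    if mask is None:
        return np.zeros(p.shape[:-1], dtype=np.uint8)
    idx = np.floor(p + 0.5).astype(np.int64)
    dims = np.array(mask.labels.shape)
    outside = ((idx < 0) | (idx >= dims)).any(axis=-1)
    idx = np.clip(idx, 0, dims - 1)
    out = mask.labels[idx[..., 0], idx[..., 1], idx[..., 2]]
    return np.where(outside, 0, out).astype(np.uint8)


def classify(
    tf: TransferFunction,
    intensity: np.ndarray,
    label: np.ndarray,
    step: float,
) -> np.ndarray:
    """Map intensity + label to RGBA with step-size-corrected opacity.

    The stored alpha is multiplied by the segment-opacity multiplier of
    ``label`` and rescaled from the transfer function's reference step to
    ``step``: ``a' = 1 - (1 - a) ** (step / reference_step)``.  Returns an
    array of shape ``intensity.shape + (4,)`` (alpha not premultiplied).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    rgb, alpha = tf.lookup(intensity)
    alpha = alpha * tf.segment_opacity[np.asarray(label, dtype=np.int64)]
    alpha = 1.0 - (1.0 - alpha) ** (step / tf.reference_step)
    return np.concatenate([rgb, alpha[..., None]], axis=-1)


# ---------------------------------------------------------------------------
# Transfer-function presets
# ---------------------------------------------------------------------------


def binary_tf(
    threshold: float,
    color: Sequence[float] = (1.0, 1.0, 1.0),
    reference_step: float = 1.0,
) -> TransferFunction:
    """An effectively binary transfer function: fully transparent at or below
    ``threshold``, fully opaque above it.

    The opaque ramp is only 1e-6 intensity units wide, so interpolated
    sample intensities land on exact alpha 0 or exact alpha 1 in practice;
    this is the preset used for hard-surface (bone) rendering and for
    occlusion tests that rely on every sample being opaque or empty.
    """
    r, g, b = color
    return TransferFunction(
        [(threshold, r, g, b, 0.0), (threshold + 1e-6, r, g, b, 1.0)],
        reference_step=reference_step,
    )


def ramp_tf(
    lo: float,
    hi: float,
    color: Sequence[float] = (1.0, 1.0, 1.0),
    max_alpha: float = 1.0,
    reference_step: float = 1.0,
) -> TransferFunction:
    """A linear opacity ramp from 0 at ``lo`` to ``max_alpha`` at ``hi``."""
    if hi <= lo:
        raise ValueError("require hi > lo")
    r, g, b = color
    return TransferFunction(
        [(lo, r, g, b, 0.0), (hi, r, g, b, max_alpha)],
        reference_step=reference_step,
    )
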