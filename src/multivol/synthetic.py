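"""Deterministic procedural phantoms for testing the renderer end to end.

Three CT-like phantoms mirror the renderer's target use cases:

* ``spine`` — a curved stack of bright ellipsoidal vertebral bodies with
  posterior protrusions in a dim soft-tissue noise field; one label per
  vertebra (C6, C7, T1-T12, L1-L5) plus one combined shoulder-girdle
  segment, 20 labels in all.
* ``keyhole_skull`` — a bright spherical shell (skull) with a single
  labelled circular through-disk segment on one side (a keyhole
  craniotomy).
* ``fracture`` — the same shell partitioned into ``k`` labelled fragments
  by directional Voronoi cells (whose boundaries are planes through the
  shell centre).

Intensities sit on a CT-like scale — soft tissue around 40 HU with noise,
bone around 700 HU — so a hard transfer-function threshold at 300 isolates
bone.  All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .core import (
    AffinePose,
    Camera,
    ScalarVolume,
    Scene,
    SegmentationMask,
    TransferFunction,
    VolumeNode,
    binary_tf,
)

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "phantom_scene",
    "random_opaque_scene",
    "fit_camera",
    "SPINE_SEGMENTS",
    "SOFT_TISSUE_HU",
    "BONE_HU",
    "BONE_THRESHOLD",
]

SOFT_TISSUE_HU = 40.0
SOFT_TISSUE_NOISE = 10.0
BONE_HU = 700.0
BONE_NOISE = 20.0
#: a binary transfer function at this threshold isolates bone in all phantoms
BONE_THRESHOLD = 300.0

#: the default spine label list: 19 vertebrae + combined clavicles/scapulae
SPINE_SEGMENTS: Tuple[str, ...] = (
    "C6", "C7",
    "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "shoulder_girdle",
)


@dataclass
class PhantomSpec:
    """Parameters of one procedural phantom.

    ``kind`` is one of ``spine``, ``keyhole_skull``, ``fracture``; ``seed``
    fixes all randomness (geometry jitter and the noise fields); the
    remaining fields are kind-specific geometry knobs expressed as
    fractions of the grid size.
    """

    kind: str
    dims: Tuple[int, int, int] = (64, 64, 64)
    seed: int = 0
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    # keyhole_skull / fracture
    shell_radius_frac: float = 0.40
    shell_thickness_frac: float = 0.08
    keyhole_radius_frac: float = 0.11
    n_fragments: int = 5
    # spine
    segments: Sequence[str] = SPINE_SEGMENTS

    def __post_init__(self) -> None:
        if self.kind not in ("spine", "keyhole_skull", "fracture"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if any(d < 32 for d in self.dims):
            raise ValueError("phantom dims must be >= 32 per axis")
        if self.kind == "fracture" and not 2 <= self.n_fragments <= 255:
            raise ValueError("n_fragments must be in [2, 255]")
        if self.kind == "spine" and not 1 <= len(self.segments) <= 255:
            raise ValueError("need 1..255 spine segments")


def _index_grids(dims: Tuple[int, int, int]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    return np.meshgrid(*(np.arange(d, dtype=np.float64) for d in dims), indexing="ij")


def _base_tissue(rng: np.random.Generator, dims: Tuple[int, int, int]) -> np.ndarray:
    return SOFT_TISSUE_HU + SOFT_TISSUE_NOISE * rng.standard_normal(dims)


def _shell(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean shell mask plus centre and radial-distance field."""
    dims = spec.dims
    c = (np.asarray(dims, dtype=np.float64) - 1.0) / 2.0
    xx, yy, zz = _index_grids(dims)
    r = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
    r_out = spec.shell_radius_frac * min(dims)
    r_in = r_out - spec.shell_thickness_frac * min(dims)
    return (r >= r_in) & (r <= r_out), c, r


def _spine(spec: PhantomSpec, rng: np.random.Generator):
    nx, ny, nz = spec.dims
    names = list(spec.segments)
    girdle = names and names[-1] == "shoulder_girdle"
    n_vert = len(names) - 1 if girdle else len(names)

    # seed-dependent scoliotic curve
    amp = nx * (0.08 + 0.04 * rng.uniform())
    phase = rng.uniform(0.0, np.pi)
    z_lo, z_hi = 0.08 * nz, 0.86 * nz
    centers_z = np.linspace(z_lo, z_hi, n_vert)
    dz = (z_hi - z_lo) / max(1, n_vert - 1)

    xx, yy, zz = _index_grids(spec.dims)
    intensity = _base_tissue(rng, spec.dims)
    labels = np.zeros(spec.dims, dtype=np.uint8)

    rx, ry, rz = 0.13 * nx, 0.10 * ny, 0.42 * dz
    for i, z0 in enumerate(centers_z):
        cx = nx / 2.0 + amp * np.sin(np.pi * z0 / nz + phase) * 0.5
        cy = ny * 0.42
        body = (
            ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - z0) / rz) ** 2
        ) <= 1.0
        # posterior protrusion (spinous-process analogue), overlapping the body
        py = cy + ry + 1.5
        prot = (
            ((xx - cx) / (0.05 * nx)) ** 2
            + ((yy - py) / (0.06 * ny)) ** 2
            + ((zz - z0) / (0.30 * dz)) ** 2
        ) <= 1.0
        labels[body | prot] = i + 1

    if girdle:
        zg = 0.93 * nz
        bar = (
            ((yy - ny * 0.42) / (0.09 * ny)) ** 2 + ((zz - zg) / (0.35 * dz)) ** 2 <= 1.0
        ) & (xx >= 0.15 * nx) & (xx <= 0.85 * nx)
        labels[bar] = len(names)

    bone = labels > 0
    intensity[bone] = BONE_HU + BONE_NOISE * rng.standard_normal(int(bone.sum()))
    return intensity, labels


def _keyhole_skull(spec: PhantomSpec, rng: np.random.Generator):
    shell, c, _ = _shell(spec)
    xx, yy, zz = _index_grids(spec.dims)
    rel = np.stack([xx - c[0], yy - c[1], zz - c[2]], axis=-1)

    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    along = rel @ axis
    radial2 = np.sum(rel * rel, axis=-1) - along**2
    kh_r = spec.keyhole_radius_frac * min(spec.dims)
    # one-sided circular through-disk: inside the cylinder, on one side only
    keyhole = shell & (radial2 <= kh_r**2) & (along > 0)

    intensity = _base_tissue(rng, spec.dims)
    intensity[shell] = BONE_HU + BONE_NOISE * rng.standard_normal(int(shell.sum()))
    labels = np.zeros(spec.dims, dtype=np.uint8)
    labels[keyhole] = 1
    return intensity, labels


def _enforce_connected_fragments(labels: np.ndarray, region: np.ndarray) -> None:
    """Reassign stray sliver components so every label is one 6-connected
    piece (in place).

    Directional Voronoi cells are geodesically convex, but on the discrete
    grid a cell can pinch into diagonal-only slivers at its boundary.  Any
    non-largest component of a label is merged into the most common
    6-adjacent neighbouring label until all labels are single components.
    """
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)
    for _ in range(64):  # converges in one or two sweeps in practice
        changed = False
        for lab in np.unique(labels[labels > 0]):
            comp, n = ndimage.label(labels == lab, structure=struct)
            if n <= 1:
                continue
            sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=range(1, n + 1))
            keep = int(np.argmax(sizes)) + 1
            for ci in range(1, n + 1):
                if ci == keep:
                    continue
                sliver = comp == ci
                ring = ndimage.binary_dilation(sliver, structure=struct) & region & ~sliver
                neigh = labels[ring]
                neigh = neigh[(neigh > 0) & (neigh != lab)]
                if neigh.size:
                    labels[sliver] = np.bincount(neigh).argmax()
                    changed = True
        if not changed:
            return
    raise RuntimeError("fragment connectivity cleanup did not converge")


def _fracture(spec: PhantomSpec, rng: np.random.Generator):
    shell, c, _ = _shell(spec)
    xx, yy, zz = _index_grids(spec.dims)
    rel = np.stack([xx - c[0], yy - c[1], zz - c[2]], axis=-1)

    k = spec.n_fragments
    seeds = rng.standard_normal((k, 3))
    seeds /= np.linalg.norm(seeds, axis=1, keepdims=True)
    # directional Voronoi: nearest seed direction; cell boundaries are the
    # bisector planes through the shell centre
    idx = np.nonzero(shell)
    dirs = rel[idx]
    dirs = dirs / np.maximum(np.linalg.norm(dirs, axis=1, keepdims=True), 1e-12)
    cell = np.argmax(dirs @ seeds.T, axis=1)

    intensity = _base_tissue(rng, spec.dims)
    intensity[shell] = BONE_HU + BONE_NOISE * rng.standard_normal(int(shell.sum()))
    labels = np.zeros(spec.dims, dtype=np.uint8)
    labels[idx] = (cell + 1).astype(np.uint8)
    _enforce_connected_fragments(labels, shell)
    return intensity, labels


def generate_phantom(spec: PhantomSpec) -> Tuple[ScalarVolume, SegmentationMask]:
    """Generate the phantom described by ``spec``; fully seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "spine":
        intensity, labels = _spine(spec, rng)
    elif spec.kind == "keyhole_skull":
        intensity, labels = _keyhole_skull(spec, rng)
    else:
        intensity, labels = _fracture(spec, rng)
    vol = ScalarVolume(
        intensity.astype(np.float32), spec.spacing, name=f"{spec.kind}_{spec.seed}"
    )
    return vol, SegmentationMask(labels)


def phantom_scene(
    spec: PhantomSpec,
    tf: Optional[TransferFunction] = None,
    background: Tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> Scene:
    """A single-node scene holding the phantom with a bone transfer function."""
    vol, mask = generate_phantom(spec)
    tf = tf or binary_tf(BONE_THRESHOLD, (0.92, 0.88, 0.80))
    scene = Scene(background=background)
    scene.add(VolumeNode(volume=vol, mask=mask, tf=tf, creation_index=0))
    return scene


# ---------------------------------------------------------------------------
# Randomized multi-volume test scenes
# ---------------------------------------------------------------------------


def random_opaque_scene(
    n_volumes: int,
    seed: int = 0,
    *,
    grid: int = 24,
    sphere_radius_mm: float = 7.0,
    region_mm: float = 60.0,
    min_gap_mm: float = 4.0,
    threshold: float = BONE_THRESHOLD,
) -> Scene:
    """A scene of ``n_volumes`` independently posed opaque sphere blobs.

    Each node is a ``grid``^3 volume containing one bright sphere on a zero
    background, rendered with a hard (binary) transfer function.  Poses are
    random rotations + translations inside a cube of side ``region_mm``;
    node *bounding boxes* may overlap freely but sphere centres are kept at
    least ``2 * sphere_radius_mm + min_gap_mm`` apart, so the opaque voxel
    sets are pairwise disjoint — the regime in which sequential depth-buffer
    passes are exact.
    """
    if n_volumes < 1:
        raise ValueError("need at least one volume")
    rng = np.random.default_rng(seed)
    half = grid / 2.0

    centers: list = []
    scene = Scene(background=(0.05, 0.05, 0.08))
    palette = [
        (0.9, 0.3, 0.25), (0.3, 0.8, 0.35), (0.3, 0.45, 0.95), (0.95, 0.85, 0.3),
        (0.85, 0.4, 0.85), (0.35, 0.85, 0.85), (0.95, 0.6, 0.3), (0.7, 0.7, 0.7),
    ]
    for i in range(n_volumes):
        for _ in range(1000):
            c = rng.uniform(-region_mm / 2, region_mm / 2, size=3)
            if all(
                np.linalg.norm(c - p) >= 2 * sphere_radius_mm + min_gap_mm
                for p in centers
            ):
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place disjoint spheres; reduce n or radius")

        xx, yy, zz = _index_grids((grid, grid, grid))
        ctr = (grid - 1) / 2.0
        inside = (xx - ctr) ** 2 + (yy - ctr) ** 2 + (zz - ctr) ** 2 <= sphere_radius_mm**2
        data = np.zeros((grid, grid, grid), dtype=np.float32)
        data[inside] = BONE_HU

        rot = rng.uniform(0.0, 360.0, size=3)
        pose = AffinePose.from_rotation_translation(rot, (0.0, 0.0, 0.0))
        # translate so the rotated volume centre lands on the chosen point
        center_local = np.full(3, ctr)
        offset = centers[-1] - pose.matrix[:3, :3] @ center_local
        m = pose.matrix.copy()
        m[:3, 3] = offset
        node = VolumeNode(
            volume=ScalarVolume(data, name=f"blob{i}"),
            tf=binary_tf(threshold, palette[i % len(palette)]),
            pose=AffinePose(m),
            creation_index=i,
        )
        scene.add(node)
    return scene


def fit_camera(
    scene: Scene,
    image_size: Tuple[int, int] = (128, 128),
    direction: Sequence[float] = (1.0, -0.7, 0.45),
    vfov: float = 40.0,
) -> Camera:
    """A camera looking at the scene centre from ``direction``, pulled back
    far enough to frame the whole bounding sphere."""
    lo, hi = scene.world_bounds()
    center = (lo + hi) / 2.0
    radius = float(np.linalg.norm(hi - lo)) / 2.0
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    dist = 1.3 * radius / np.tan(np.deg2rad(vfov) / 2.0)
    eye = center + d * dist
    near = max(0.5, dist - 1.8 * radius)
    far = dist + 1.8 * radius
    return Camera.look_at(
        eye, center, vfov=vfov, image_size=image_size, near=near, far=far
    )
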