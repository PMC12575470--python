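import numpy as np
import pytest

from multivol.core import (
    AffinePose,
    Camera,
    ScalarVolume,
    Scene,
    SegmentationMask,
    VolumeNode,
    binary_tf,
)
from multivol.synthetic import BONE_HU


def sphere_volume(grid: int = 24, radius: float = 8.0, value: float = BONE_HU) -> np.ndarray:
    """A bright sphere on a zero background, centered in a grid^3 volume."""
    idx = np.arange(grid, dtype=np.float64)
    xx, yy, zz = np.meshgrid(idx, idx, idx, indexing="ij")
    c = (grid - 1) / 2.0
    data = np.zeros((grid, grid, grid), dtype=np.float32)
    data[(xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius**2] = value
    return data


def blob_node(
    center_mm,
    color=(1.0, 1.0, 1.0),
    grid: int = 24,
    radius: float = 8.0,
    threshold: float = 300.0,
    creation_index: int = 0,
    mask: np.ndarray = None,
) -> VolumeNode:
    """An opaque sphere blob posed so its centre sits at ``center_mm``."""
    data = sphere_volume(grid, radius)
    c = (grid - 1) / 2.0
    pose = AffinePose.from_translation(np.asarray(center_mm, dtype=float) - c)
    return VolumeNode(
        volume=ScalarVolume(data, name=f"blob@{tuple(center_mm)}"),
        mask=SegmentationMask(mask) if mask is not None else None,
        tf=binary_tf(threshold, color),
        pose=pose,
        creation_index=creation_index,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def overlap_scene():
    """Two overlapping opaque volumes, the red one nearer to the camera.

    Their 24 mm boxes overlap (centres 14 mm apart) but the opaque spheres
    are disjoint; the camera looks along +x so red occludes blue.
    """
    scene = Scene(background=(0.0, 0.0, 0.0))
    scene.add(blob_node((0.0, 0.0, 0.0), (1.0, 0.2, 0.2), creation_index=0))
    scene.add(blob_node((14.0, 0.0, 0.0), (0.2, 0.2, 1.0), creation_index=1))
    camera = Camera.look_at(
        (-90.0, 0.0, 0.0), (7.0, 0.0, 0.0), image_size=(96, 96), near=10.0, far=300.0
    )
    return scene, camera
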