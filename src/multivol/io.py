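"""Readers and writers for volumes, masks, rendered images and scene configs.

Volumes travel as NIfTI (``.nii``/``.nii.gz``, via nibabel), NRRD
(``.nrrd``, raw-encoded, written and parsed by a small codec in this
module) or raw arrays with a ``.json`` sidecar.  The file's voxel-to-world
transform is taken as given — no reorientation to a canonical axis order is
performed, so round trips are bit-exact; the renderer's axis convention is
simply "index * spacing in the node's local frame" (see README).

Rendered colour goes to 8-bit PNG (linear -> sRGB) or binary PPM; depth
goes to 32-bit float PFM holding ray distances in mm (far where empty), so
depth files are comparable across resolutions and far planes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import imageio.v3 as iio
import numpy as np
import yaml

from .core import (
    AffinePose,
    Camera,
    ScalarVolume,
    Scene,
    SegmentationMask,
    TransferFunction,
    VolumeNode,
    binary_tf,
    ramp_tf,
)
from .multivolume import FrameBuffer, Light
from .raymarch import RenderParams

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_image",
    "read_pfm",
    "write_pfm",
    "load_scene_config",
    "compare_images",
]


# ---------------------------------------------------------------------------
# Volume IO
# ---------------------------------------------------------------------------

_NRRD_TYPES: Dict[str, np.dtype] = {
    "uint8": np.dtype(np.uint8),
    "int16": np.dtype(np.int16),
    "uint16": np.dtype(np.uint16),
    "int32": np.dtype(np.int32),
    "float": np.dtype(np.float32),
    "double": np.dtype(np.float64),
}
_NRRD_NAMES = {v: k for k, v in _NRRD_TYPES.items()}


def _spacing_pose_to_affine(spacing, pose: AffinePose) -> np.ndarray:
    aff = pose.matrix.copy()
    aff[:3, :3] = aff[:3, :3] * np.asarray(spacing)[None, :]
    return aff


def _affine_to_spacing_pose(affine: np.ndarray, spacing) -> AffinePose:
    m = np.asarray(affine, dtype=np.float64).copy()
    m[:3, :3] = m[:3, :3] / np.asarray(spacing)[None, :]
    return AffinePose(m)


def write_volume(
    volume: ScalarVolume,
    path: Union[str, Path],
    pose: Optional[AffinePose] = None,
) -> Path:
    """Write a volume (data + spacing + voxel-to-world affine) to ``path``.

    The extension selects the container: ``.nii``/``.nii.gz``, ``.nrrd`` or
    ``.raw`` (with a ``<path>.json`` sidecar).  The data dtype is preserved.
    """
    path = Path(path)
    pose = pose or AffinePose.identity()
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = _spacing_pose_to_affine(volume.spacing, pose)
        img = nib.Nifti1Image(volume.data, affine)
        img.header.set_zooms(volume.spacing)
        nib.save(img, str(path))
    elif name.endswith(".nrrd"):
        _write_nrrd(volume, path, pose)
    elif name.endswith(".raw"):
        volume.data.tofile(path)
        sidecar = {
            "dtype": volume.data.dtype.name,
            "dims": list(volume.data.shape),
            "spacing": list(volume.spacing),
            "affine": _spacing_pose_to_affine(volume.spacing, pose).tolist(),
            "name": volume.name,
        }
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unknown volume extension in {path.name!r}")
    return path


def read_volume(path: Union[str, Path]) -> Tuple[ScalarVolume, AffinePose]:
    """Read a volume; returns ``(ScalarVolume, AffinePose)`` where the pose
    maps local mm (``index * spacing``) to the file's world frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path.name}: expected 3D data, got shape {data.shape}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if any(s <= 0 for s in spacing):
            raise ValueError(f"{path.name}: non-positive spacing (pixdim) {spacing}")
        pose = _affine_to_spacing_pose(img.affine, spacing)
        return ScalarVolume(data, spacing, name=path.stem.replace(".nii", "")), pose
    if name.endswith(".nrrd"):
        return _read_nrrd(path)
    if name.endswith(".raw"):
        side = Path(str(path) + ".json")
        if not side.exists():
            raise FileNotFoundError(f"{path.name}: missing sidecar {side.name}")
        meta = json.loads(side.read_text())
        data = np.fromfile(path, dtype=np.dtype(meta["dtype"])).reshape(meta["dims"])
        spacing = tuple(meta["spacing"])
        pose = _affine_to_spacing_pose(np.asarray(meta["affine"]), spacing)
        return ScalarVolume(data, spacing, name=meta.get("name", path.stem)), pose
    raise ValueError(f"unknown volume extension in {path.name!r}")


def write_mask(
    mask: Union[SegmentationMask, np.ndarray],
    path: Union[str, Path],
    pose: Optional[AffinePose] = None,
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> Path:
    """Write a segmentation mask as an 8-bit volume.

    Labels outside ``[0, 255]`` are an error: the mask contract is a single
    8-bit channel per voxel.
    """
    if isinstance(mask, SegmentationMask):
        labels = mask.labels
    else:
        labels = np.asarray(mask)
        if labels.min(initial=0) < 0 or labels.max(initial=0) > 255:
            raise ValueError(
                f"mask labels span [{labels.min()}, {labels.max()}] "
                "but must fit a single 8-bit channel [0, 255]"
            )
        labels = labels.astype(np.uint8)
    vol = ScalarVolume(labels, spacing, name="mask")
    # ScalarVolume requires finite data; uint8 always is
    return write_volume(vol, path, pose)


def read_mask(path: Union[str, Path]) -> Tuple[SegmentationMask, AffinePose]:
    vol, pose = read_volume(path)
    data = vol.data
    if data.dtype != np.uint8:
        if data.min() < 0 or data.max() > 255 or not np.allclose(data, np.round(data)):
            raise ValueError(f"{Path(path).name}: not an 8-bit label volume")
        data = data.astype(np.uint8)
    return SegmentationMask(data), pose


# -- minimal NRRD codec (text header + raw little-endian data) --------------


def _write_nrrd(volume: ScalarVolume, path: Path, pose: AffinePose) -> None:
    if volume.data.dtype not in _NRRD_NAMES:
        raise ValueError(f"unsupported NRRD dtype {volume.data.dtype}")
    dirs = pose.matrix[:3, :3] * np.asarray(volume.spacing)[None, :]
    origin = pose.matrix[:3, 3]
    lines = [
        "NRRD0004",
        "# written by multivol",
        f"type: {_NRRD_NAMES[volume.data.dtype]}",
        "dimension: 3",
        "space dimension: 3",
        "sizes: {} {} {}".format(*volume.data.shape),
        "space directions: "
        + " ".join("({},{},{})".format(*dirs[:, ax]) for ax in range(3)),
        "space origin: ({},{},{})".format(*origin),
        "endian: little",
        "encoding: raw",
        # exact spacing as a key/value pair so round trips do not depend on
        # recovering it from direction-vector norms
        "spacing:=" + " ".join(repr(s) for s in volume.spacing),
    ]
    data = volume.data
    if data.dtype.byteorder == ">":
        data = data.astype(data.dtype.newbyteorder("<"))
    with open(path, "wb") as f:
        f.write(("\n".join(lines) + "\n\n").encode("ascii"))
        f.write(data.flatten(order="F").tobytes())


def _read_nrrd(path: Path) -> Tuple[ScalarVolume, AffinePose]:
    with open(path, "rb") as f:
        raw = f.read()
    head_end = raw.find(b"\n\n")
    if not raw.startswith(b"NRRD") or head_end < 0:
        raise ValueError(f"{path.name}: not a raw-encoded NRRD file")
    fields: Dict[str, str] = {}
    keyvals: Dict[str, str] = {}
    for line in raw[:head_end].decode("ascii").splitlines()[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            k, v = line.split(":=", 1)
            keyvals[k.strip()] = v.strip()
        elif ":" in line:
            k, v = line.split(":", 1)
            fields[k.strip().lower()] = v.strip()
    for req in ("type", "sizes", "encoding"):
        if req not in fields:
            raise ValueError(f"{path.name}: NRRD header missing field {req!r}")
    if fields["encoding"] != "raw":
        raise ValueError(f"{path.name}: only raw encoding supported")
    if fields.get("endian", "little") != "little":
        raise ValueError(f"{path.name}: only little-endian NRRD supported")
    if fields["type"] not in _NRRD_TYPES:
        raise ValueError(f"{path.name}: unsupported NRRD type {fields['type']!r}")
    dims = tuple(int(s) for s in fields["sizes"].split())
    if len(dims) != 3:
        raise ValueError(f"{path.name}: sizes must be 3D, got {fields['sizes']!r}")
    dtype = _NRRD_TYPES[fields["type"]]
    body = raw[head_end + 2 :]
    expected = int(np.prod(dims)) * dtype.itemsize
    if len(body) != expected:
        raise ValueError(
            f"{path.name}: data size {len(body)} does not match sizes field "
            f"({expected} bytes expected)"
        )
    data = np.frombuffer(body, dtype=dtype).reshape(dims, order="F").copy()

    def _vecs(s: str) -> np.ndarray:
        parts = s.replace("(", " ").replace(")", " ").replace(",", " ").split()
        return np.asarray([float(p) for p in parts]).reshape(3, 3).T

    if "spacing" in keyvals:
        spacing = tuple(float(s) for s in keyvals["spacing"].split())
    elif "space directions" in fields:
        spacing = tuple(
            float(np.linalg.norm(_vecs(fields["space directions"])[:, ax]))
            for ax in range(3)
        )
    else:
        spacing = (1.0, 1.0, 1.0)
    m = np.eye(4)
    if "space directions" in fields:
        m[:3, :3] = _vecs(fields["space directions"]) / np.asarray(spacing)[None, :]
    if "space origin" in fields:
        parts = fields["space origin"].replace("(", " ").replace(")", " ").replace(",", " ").split()
        m[:3, 3] = [float(p) for p in parts]
    return ScalarVolume(data, spacing, name=path.stem), AffinePose(m)


# ---------------------------------------------------------------------------
# Image IO
# ---------------------------------------------------------------------------


def _linear_to_srgb(c: np.ndarray) -> np.ndarray:
    c = np.clip(c, 0.0, 1.0)
    return np.where(c <= 0.0031308, 12.92 * c, 1.055 * c ** (1.0 / 2.4) - 0.055)


def write_image(
    fb: Union[FrameBuffer, np.ndarray],
    color_path: Union[str, Path],
    depth_path: Optional[Union[str, Path]] = None,
) -> None:
    """Write a frame buffer: colour as 8-bit PNG (or binary PPM), depth as
    32-bit float PFM of ray distances."""
    rgb = fb.resolve() if isinstance(fb, FrameBuffer) else np.asarray(fb)
    img8 = np.round(_linear_to_srgb(rgb) * 255.0).astype(np.uint8)
    color_path = Path(color_path)
    if color_path.suffix.lower() == ".ppm":
        with open(color_path, "wb") as f:
            f.write(f"P6\n{img8.shape[1]} {img8.shape[0]}\n255\n".encode())
            f.write(img8.tobytes())
    elif color_path.suffix.lower() == ".png":
        iio.imwrite(color_path, img8)
    else:
        raise ValueError(f"unsupported colour image extension {color_path.suffix!r}")
    if depth_path is not None:
        if not isinstance(fb, FrameBuffer):
            raise ValueError("depth output requires a FrameBuffer")
        write_pfm(fb.depth, depth_path)


def write_pfm(data: np.ndarray, path: Union[str, Path]) -> None:
    """Greyscale PFM (little-endian, rows bottom-to-top per the format)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("PFM writer expects a 2D array")
    with open(path, "wb") as f:
        f.write(f"Pf\n{data.shape[1]} {data.shape[0]}\n-1.0\n".encode())
        f.write(np.flipud(data).tobytes())


def read_pfm(path: Union[str, Path]) -> np.ndarray:
    with open(path, "rb") as f:
        if f.readline().strip() != b"Pf":
            raise ValueError("not a greyscale PFM file")
        w, h = (int(x) for x in f.readline().split())
        scale = float(f.readline())
        dt = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(f.read(w * h * 4), dtype=dt).reshape(h, w)
    return np.flipud(data).astype(np.float32)


def compare_images(path_a: Union[str, Path], path_b: Union[str, Path]) -> Dict[str, float]:
    """Per-channel difference statistics between two colour images."""
    a = iio.imread(path_a).astype(np.float64)
    b = iio.imread(path_b).astype(np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    per_pixel = diff.reshape(a.shape[0] * a.shape[1], -1).max(axis=1)
    return {
        "max_diff": float(diff.max()),
        "mean_diff": float(diff.mean()),
        "differing_pixels": int((per_pixel > 0).sum()),
        "total_pixels": int(a.shape[0] * a.shape[1]),
    }


# ---------------------------------------------------------------------------
# Scene configuration
# ---------------------------------------------------------------------------

_TF_PRESET_KEYS = {"preset", "threshold", "color", "lo", "hi", "max_alpha", "reference_step"}
_TF_KEYS = _TF_PRESET_KEYS | {"points"}
_NODE_KEYS = {
    "path", "mask", "name", "tf", "segment_opacity",
    "translation", "rotation_deg", "visible",
}
_CAMERA_KEYS = {"eye", "look_at", "up", "vfov", "size", "near", "far"}
_PARAM_KEYS = {
    "step", "alpha_threshold", "align_global_grid", "shading",
    "skip_grid", "use_rect", "shadow_bias",
}
_LIGHT_KEYS = {"position", "shadow_size"}
_TOP_KEYS = {"camera", "background", "params", "light", "volumes", "opaque_layer"}


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def _build_tf(block: dict) -> TransferFunction:
    _check_keys(block, _TF_KEYS, "tf")
    if "points" in block:
        return TransferFunction(
            block["points"], reference_step=block.get("reference_step", 1.0)
        )
    preset = block.get("preset", "binary")
    color = tuple(block.get("color", (1.0, 1.0, 1.0)))
    ref = block.get("reference_step", 1.0)
    if preset in ("binary", "bone"):
        return binary_tf(block.get("threshold", 300.0), color, reference_step=ref)
    if preset == "ramp":
        return ramp_tf(
            block.get("lo", 100.0), block.get("hi", 500.0), color,
            max_alpha=block.get("max_alpha", 1.0), reference_step=ref,
        )
    raise ValueError(f"unknown tf preset {preset!r}")


def load_scene_config(path: Union[str, Path]) -> Tuple[Scene, Camera, RenderParams]:
    """Load a YAML scene description; see README for the schema.

    Relative volume paths resolve against the config file's directory.
    Unknown keys are rejected with the offending key named.
    """
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ValueError(f"{path.name}: top level must be a mapping")
    _check_keys(cfg, _TOP_KEYS, path.name)
    base = path.parent

    cam_block = dict(cfg.get("camera", {}))
    _check_keys(cam_block, _CAMERA_KEYS, "camera")
    camera = Camera.look_at(
        cam_block.get("eye", (200.0, 120.0, 90.0)),
        cam_block.get("look_at", (0.0, 0.0, 0.0)),
        cam_block.get("up", (0.0, 0.0, 1.0)),
        vfov=cam_block.get("vfov", 40.0),
        image_size=tuple(cam_block.get("size", (256, 256))),
        near=cam_block.get("near", 1.0),
        far=cam_block.get("far", 1000.0),
    )

    par_block = dict(cfg.get("params", {}))
    _check_keys(par_block, _PARAM_KEYS, "params")
    params = RenderParams(**par_block)

    scene = Scene(background=tuple(cfg.get("background", (0.0, 0.0, 0.0))))

    if "light" in cfg:
        light_block = dict(cfg["light"])
        _check_keys(light_block, _LIGHT_KEYS, "light")
        scene.light = Light(
            position=np.asarray(light_block["position"], dtype=np.float64),
            shadow_size=int(light_block.get("shadow_size", 256)),
        )

    vols = cfg.get("volumes", [])
    if not isinstance(vols, list):
        raise ValueError("'volumes' must be a list")
    for i, block in enumerate(vols):
        _check_keys(block, _NODE_KEYS, f"volumes[{i}]")
        if "path" not in block:
            raise ValueError(f"volumes[{i}]: missing 'path'")
        vol, pose = read_volume(base / block["path"])
        if "name" in block:
            vol.name = block["name"]
        mask = None
        if block.get("mask"):
            mask, _ = read_mask(base / block["mask"])
        tf = _build_tf(dict(block.get("tf", {})))
        for label, mult in dict(block.get("segment_opacity", {})).items():
            tf.set_segment_opacity(int(label), float(mult))
        extra = AffinePose.from_rotation_translation(
            block.get("rotation_deg", (0.0, 0.0, 0.0)),
            block.get("translation", (0.0, 0.0, 0.0)),
        )
        scene.add(
            VolumeNode(
                volume=vol,
                mask=mask,
                tf=tf,
                pose=extra.compose(pose),
                visible=bool(block.get("visible", True)),
                creation_index=i,
            )
        )

    if "opaque_layer" in cfg:
        layer = dict(cfg["opaque_layer"])
        _check_keys(layer, {"color", "depth"}, "opaque_layer")
        color = iio.imread(base / layer["color"]).astype(np.float64) / 255.0
        depth = read_pfm(base / layer["depth"]).astype(np.float64)
        scene.opaque_layer = (color[..., :3], depth)

    return scene, camera, params
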