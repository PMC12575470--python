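"""Single-volume ray marching with front-to-back compositing.

The marcher works on *batches* of rays (vectorized over pixels); the
single-ray :func:`march_single` is a batch of one.  The one-pass reference
renderer reuses the same sampling and compositing helpers
(:func:`node_local_ray`, :func:`node_rgba_at`, :func:`composite_into`) so
that, where the two algorithms are mathematically equivalent, they are also
bit-identical in floating point.

Distances along a ray are Euclidean millimetres from the eye (the ray
parameter of a unit-length world direction), not perspective z; this makes
depth clamping across passes exact because all passes share the same rays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import (
    Camera,
    ScalarVolume,
    TransferFunction,
    VolumeNode,
    classify,
    sample_intensity,
    sample_label,
    transform_point,
    transform_vector,
)

__all__ = [
    "Ray",
    "RenderParams",
    "SkipGrid",
    "generate_ray",
    "generate_rays",
    "intersect_ray_aabb",
    "march_single",
    "march_rays",
    "build_skip_grid",
    "shade",
    "shade_points",
    "node_local_ray",
    "node_rgba_at",
    "composite_into",
    "aligned_first_index",
]

# Conventional lighting constants (see docs/methods.md).
AMBIENT = 0.3
DIFFUSE = 0.7


@dataclass
class Ray:
    """A world-space ray with clip distances in millimetres."""

    origin: np.ndarray
    direction: np.ndarray
    t_near: float
    t_far: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("ray direction must be unit length")
        if not self.t_near < self.t_far:
            raise ValueError("require t_near < t_far")


@dataclass
class RenderParams:
    """Tunable marching parameters.

    step : float or None
        Sampling interval in mm; ``None`` means 0.5 x the smallest voxel
        spacing among the volumes being rendered.
    alpha_threshold : float
        Accumulated opacity at which a ray terminates early and its hit
        distance is recorded; in (0, 1].
    align_global_grid : bool
        Sample at global multiples ``t = k * step`` measured from the eye
        instead of half-step offsets from each volume's entry point.  Every
        pass of a multi-volume render then shares one sample lattice, which
        is what makes exact agreement with the one-pass reference possible.
    shading : bool
        Gradient-based diffuse shading with the scene light.
    skip_grid : bool
        Consult a min/max block grid to skip classification in provably
        empty space (never changes the image).
    use_rect : bool
        Restrict each volume pass to its screen-space bounding rectangle
        (never changes the image).
    shadow_bias : float
        Depth tolerance (mm) when testing a point against the shadow map.
    """

    step: Optional[float] = None
    alpha_threshold: float = 0.99
    align_global_grid: bool = False
    shading: bool = False
    skip_grid: bool = True
    use_rect: bool = True
    shadow_bias: float = 1.0

    def __post_init__(self) -> None:
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if not 0.0 < self.alpha_threshold <= 1.0:
            raise ValueError("alpha_threshold must be in (0, 1]")

    def resolved_step(self, *volumes: ScalarVolume) -> float:
        if self.step is not None:
            return float(self.step)
        if not volumes:
            raise ValueError("cannot resolve default step without volumes")
        return 0.5 * min(min(v.spacing) for v in volumes)


@dataclass
class SkipGrid:
    """Per-block intensity min/max (block dilated by one voxel so trilinear
    support is covered) plus a conservative contains-any-segment flag."""

    block_size: int
    vmin: np.ndarray
    vmax: np.ndarray
    has_label: np.ndarray

    def skippable(self, tf: TransferFunction) -> np.ndarray:
        """Blocks whose classified alpha is provably zero for ``tf``.

        A block is skippable when the transfer function's raw alpha is zero
        over the block's whole (dilated) intensity range; blocks containing
        any labelled voxel are conservatively kept, so per-segment opacity
        edits can never create a false skip.
        """
        nb = self.vmin.shape
        out = np.zeros(nb, dtype=bool)
        for b in np.ndindex(*nb):
            if self.has_label[b]:
                continue
            out[b] = tf.max_alpha_in_range(float(self.vmin[b]), float(self.vmax[b])) == 0.0
        return out


# ---------------------------------------------------------------------------
# Ray generation and intersection
# ---------------------------------------------------------------------------


def generate_rays(camera: Camera, ix: np.ndarray, iy: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Unit world directions through pixel centers; returns (origins, dirs)."""
    w, h = camera.image_size
    ix = np.asarray(ix, dtype=np.float64)
    iy = np.asarray(iy, dtype=np.float64)
    tan_v = np.tan(np.deg2rad(camera.vfov) / 2.0)
    tan_h = tan_v * w / h
    u = ((ix + 0.5) / w) * 2.0 - 1.0
    v = 1.0 - ((iy + 0.5) / h) * 2.0
    d = (
        camera.forward[None, :]
        + (u * tan_h)[:, None] * camera.right[None, :]
        + (v * tan_v)[:, None] * camera.up[None, :]
    )
    d = d / np.linalg.norm(d, axis=-1, keepdims=True)
    o = np.broadcast_to(camera.eye, d.shape).copy()
    return o, d


def generate_ray(camera: Camera, pixel: Tuple[int, int]) -> Ray:
    """The ray through the center of ``pixel`` = (ix, iy), (0,0) top-left."""
    ix, iy = pixel
    w, h = camera.image_size
    if not (0 <= ix < w and 0 <= iy < h):
        raise ValueError(f"pixel {pixel} outside {w}x{h} image")
    o, d = generate_rays(camera, np.array([ix]), np.array([iy]))
    return Ray(o[0], d[0], camera.near, camera.far)


def _intersect_aabb_batch(
    o: np.ndarray,
    d: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    t_near: float,
    t_far: float,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slab intersection for ray batches; returns (t_enter, t_exit, hit)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
        t1 = (lo - o) * inv
        t2 = (hi - o) * inv
    zero = d == 0.0
    tmin = np.where(zero, -np.inf, np.minimum(t1, t2))
    tmax = np.where(zero, np.inf, np.maximum(t1, t2))
    parallel_miss = (zero & ((o < lo) | (o > hi))).any(axis=-1)
    t_enter = np.maximum(tmin.max(axis=-1), t_near)
    t_exit = np.minimum(tmax.min(axis=-1), t_far)
    hit = ~parallel_miss & (t_enter < t_exit)
    return t_enter, t_exit, hit


def intersect_ray_aabb(
    ray: Ray, lo: np.ndarray, hi: np.ndarray
) -> Optional[Tuple[float, float]]:
    """Slab-method ray/box interval intersected with ``[t_near, t_far]``.

    The entry distance is clamped to ``t_near`` (a ray starting inside the
    box enters at ``t_near``); returns ``None`` on a miss.
    """
    t_enter, t_exit, hit = _intersect_aabb_batch(
        ray.origin[None, :],
        ray.direction[None, :],
        np.asarray(lo, dtype=np.float64),
        np.asarray(hi, dtype=np.float64),
        ray.t_near,
        ray.t_far,
    )
    if not hit[0]:
        return None
    return float(t_enter[0]), float(t_exit[0])


# ---------------------------------------------------------------------------
# Shared sampling / compositing helpers (also used by the one-pass oracle)
# ---------------------------------------------------------------------------


def node_local_ray(
    node: VolumeNode, origins: np.ndarray, dirs: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Express world rays in the node's local mm frame (direction unscaled,
    so the ray parameter stays world distance)."""
    o_l = transform_point(node.pose, origins, inverse=True)
    d_l = transform_vector(node.pose, dirs, inverse=True)
    return o_l, d_l


def node_rgba_at(node: VolumeNode, p_local: np.ndarray, step: float) -> np.ndarray:
    """Classified RGBA of the node at local-mm points ``p_local`` (..., 3)."""
    vox = p_local / np.asarray(node.volume.spacing)
    intensity = sample_intensity(node.volume, vox)
    label = sample_label(node.mask, vox)
    return classify(node.tf, intensity, label, step)


def composite_into(
    C: np.ndarray,
    A: np.ndarray,
    sub: np.ndarray,
    rgb: Optional[np.ndarray],
    alpha: np.ndarray,
) -> None:
    """One front-to-back step scattered into rows ``sub`` of (C, A):
    ``C += (1-A) * a * c``, ``A += (1-A) * a``.  ``rgb=None`` skips the
    colour work (depth-only passes)."""
    a_prev = A[sub]
    w = (1.0 - a_prev) * alpha
    if rgb is not None:
        C[sub] += w[:, None] * rgb
    A[sub] = a_prev + w


# ---------------------------------------------------------------------------
# Sampling lattice
# ---------------------------------------------------------------------------


def aligned_first_index(t_enter: np.ndarray, step: float) -> np.ndarray:
    """Smallest integer k with ``k * step >= t_enter`` (robust to fp in ceil)."""
    k = np.ceil(np.asarray(t_enter) / step).astype(np.int64)
    k = np.where(k * step < t_enter, k + 1, k)
    k = np.where((k - 1) * step >= t_enter, k - 1, k)
    return k


# ---------------------------------------------------------------------------
# The marcher
# ---------------------------------------------------------------------------


def march_rays(
    node: VolumeNode,
    origins: np.ndarray,
    dirs: np.ndarray,
    t_near: float,
    t_far: float,
    t_clamp: np.ndarray,
    params: RenderParams,
    *,
    skip: Optional[SkipGrid] = None,
    light=None,
    shadow=None,
    depth_only: bool = False,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """March a batch of rays through one volume node.

    Parameters
    ----------
    origins, dirs : (N, 3)
        World-space rays (unit directions).
    t_near, t_far : float
        Clip distances shared by the batch (mm).
    t_clamp : (N,) or scalar
        Per-ray clamp distance; samples at ``t >= t_clamp`` are excluded
        (this is how earlier passes' depths occlude this one).
    skip : SkipGrid, optional
        Empty-space acceleration for this node (used when
        ``params.skip_grid``).
    light, shadow : optional
        Light + shadow map for gradient shading.
    depth_only : bool
        Skip all colour work (used by the shadow-map pass).

    Returns
    -------
    C : (N, 3) premultiplied accumulated colour.
    A : (N,) accumulated opacity.
    hit : (N,) distance at which A first reached ``alpha_threshold``
        (+inf where it never did).
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    dirs = np.atleast_2d(np.asarray(dirs, dtype=np.float64))
    n = origins.shape[0]
    step = params.resolved_step(node.volume)
    thresh = params.alpha_threshold

    C = np.zeros((n, 3))
    A = np.zeros(n)
    hit = np.full(n, np.inf)

    o_l, d_l = node_local_ray(node, origins, dirs)
    lo, hi = node.local_box()
    t_enter, t_exit, inbox = _intersect_aabb_batch(o_l, d_l, lo, hi, t_near, t_far)
    t_end = np.minimum(t_exit, np.broadcast_to(np.asarray(t_clamp, dtype=np.float64), (n,)))

    aligned = params.align_global_grid
    if aligned:
        k = aligned_first_index(t_enter, step)
    else:
        k = np.zeros(n, dtype=np.int64)

    skippable = None
    if params.skip_grid and skip is not None:
        skippable = skip.skippable(node.tf)
        nb = np.array(skippable.shape)
        bs = float(skip.block_size)
    spacing = np.asarray(node.volume.spacing)

    alive = inbox.copy()
    while True:
        t = k * step if aligned else t_enter + (k + 0.5) * step
        act = alive & (t < t_end)
        if not act.any():
            break
        idx = np.flatnonzero(act)
        p_l = o_l[idx] + t[idx, None] * d_l[idx]

        sub, p_sub = idx, p_l
        if skippable is not None:
            b = np.clip((np.floor(p_l / spacing / bs)).astype(np.int64), 0, nb - 1)
            keep = ~skippable[b[:, 0], b[:, 1], b[:, 2]]
            sub, p_sub = idx[keep], p_l[keep]

        if sub.size:
            rgba = node_rgba_at(node, p_sub, step)
            alpha = rgba[:, 3]
            rgb = None
            if not depth_only:
                rgb = rgba[:, :3]
                if params.shading and light is not None:
                    lit = alpha > 0.0
                    if lit.any():
                        p_world = origins[sub[lit]] + t[sub[lit], None] * dirs[sub[lit]]
                        rgb = rgb.copy()
                        rgb[lit] = shade_points(
                            node, p_sub[lit], p_world, rgb[lit], light, shadow,
                            bias=params.shadow_bias,
                        )
            composite_into(C, A, sub, rgb, alpha)
            done = sub[A[sub] >= thresh]
            if done.size:
                hit[done] = t[done]
                alive[done] = False
        k = k + act.astype(np.int64)
    return C, A, hit


def march_single(
    ray: Ray,
    node: VolumeNode,
    params: RenderParams,
    t_clamp: Optional[float] = None,
    *,
    skip: Optional[SkipGrid] = None,
) -> Tuple[Tuple[float, float, float, float], Optional[float]]:
    """March one ray; returns ``((r, g, b, a) premultiplied, hit-or-None)``.

    ``t_clamp`` defaults to the ray's far clip; it must not exceed it.
    """
    if t_clamp is None:
        t_clamp = ray.t_far
    if t_clamp > ray.t_far:
        raise ValueError("t_clamp must be <= ray.t_far")
    C, A, hit = march_rays(
        node,
        ray.origin[None, :],
        ray.direction[None, :],
        ray.t_near,
        ray.t_far,
        np.array([t_clamp]),
        params,
        skip=skip,
    )
    h = None if np.isinf(hit[0]) else float(hit[0])
    return (float(C[0, 0]), float(C[0, 1]), float(C[0, 2]), float(A[0])), h


# ---------------------------------------------------------------------------
# Empty-space skipping
# ---------------------------------------------------------------------------


def build_skip_grid(node: VolumeNode, block_size: int = 8) -> SkipGrid:
    """Min/max intensity per block of ``block_size``^3 voxels.

    Each block's statistics cover the block dilated by one voxel, so any
    trilinear sample whose containing block is "empty" provably draws only
    on voxels inside the dilated extent.  Blocks containing any labelled
    voxel are flagged so hiding or showing segments never invalidates the
    grid.
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    data = node.volume.data
    dims = data.shape
    nb = tuple(-(-d // block_size) for d in dims)
    vmin = np.empty(nb)
    vmax = np.empty(nb)
    has_label = np.zeros(nb, dtype=bool)
    labels = node.mask.labels if node.mask is not None else None
    for b in np.ndindex(*nb):
        sl = tuple(
            slice(max(0, bi * block_size - 1), min(d, (bi + 1) * block_size + 1))
            for bi, d in zip(b, dims)
        )
        blk = data[sl]
        vmin[b] = blk.min()
        vmax[b] = blk.max()
        if labels is not None and labels[sl].any():
            has_label[b] = True
    return SkipGrid(block_size, vmin, vmax, has_label)


# ---------------------------------------------------------------------------
# Shading
# ---------------------------------------------------------------------------


def _world_normals(node: VolumeNode, p_local: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Surface normals from the central-difference intensity gradient.

    Returns (normals, defined) where ``defined`` is False at zero-gradient
    points (the normal there is meaningless and shading falls back to fully
    lit).
    """
    spacing = np.asarray(node.volume.spacing)
    grad_l = np.empty_like(p_local)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = spacing[ax]  # one-voxel offset in local mm
        vp = (p_local + e) / spacing
        vm = (p_local - e) / spacing
        grad_l[:, ax] = (
            sample_intensity(node.volume, vp) - sample_intensity(node.volume, vm)
        ) / (2.0 * spacing[ax])
    # gradients transform by the inverse linear map (covariant)
    grad_w = grad_l @ node.pose.inverse_matrix[:3, :3]
    norm = np.linalg.norm(grad_w, axis=-1)
    defined = norm > 0.0
    n = np.zeros_like(grad_w)
    n[defined] = -grad_w[defined] / norm[defined, None]
    return n, defined


def shade_points(
    node: VolumeNode,
    p_local: np.ndarray,
    p_world: np.ndarray,
    base: np.ndarray,
    light,
    shadow=None,
    *,
    ambient: float = AMBIENT,
    diffuse: float = DIFFUSE,
    bias: float = 1.0,
) -> np.ndarray:
    """Lambertian shading: ``base * (ambient + diffuse * max(0, n.l) * vis)``.

    Zero-gradient points (homogeneous regions) are treated as fully lit.
    ``vis`` comes from the shadow map when one is supplied, else 1.
    """
    normals, defined = _world_normals(node, np.atleast_2d(p_local))
    p_world = np.atleast_2d(p_world)
    to_light = np.asarray(light.position, dtype=np.float64) - p_world
    dist = np.linalg.norm(to_light, axis=-1)
    ldir = to_light / np.maximum(dist, 1e-12)[:, None]
    ndotl = np.maximum(0.0, np.sum(normals * ldir, axis=-1))
    ndotl[~defined] = 1.0  # fully lit fallback
    vis = np.ones(len(p_world))
    if shadow is not None:
        vis = shadow.visibility(p_world, bias=bias)
    factor = ambient + diffuse * ndotl * vis
    return np.atleast_2d(base) * factor[:, None]


def shade(
    node: VolumeNode,
    p: np.ndarray,
    base: Tuple[float, float, float],
    light,
    shadow=None,
    *,
    ambient: float = AMBIENT,
    diffuse: float = DIFFUSE,
    bias: float = 1.0,
) -> Tuple[float, float, float]:
    """Scalar convenience wrapper around :func:`shade_points`.

    ``p`` is a point in the node's local mm frame.
    """
    p = np.asarray(p, dtype=np.float64)
    p_world = transform_point(node.pose, p)
    out = shade_points(
        node, p[None, :], p_world[None, :], np.asarray(base)[None, :],
        light, shadow, ambient=ambient, diffuse=diffuse, bias=bias,
    )
    return (float(out[0, 0]), float(out[0, 1]), float(out[0, 2]))
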