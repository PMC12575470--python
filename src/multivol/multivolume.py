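"""Multi-volume rendering via sequential per-volume passes and a shared
hit-distance depth buffer.

Each visible volume is rendered in its own pass, restricted to its
screen-space bounding rectangle.  A pass clamps every ray to the depth
recorded by earlier passes (so already-occluded space is never marched),
composites its premultiplied colour *over* the existing colour, and then
blits its own hit distances into the shared depth buffer with a strict
less-than depth test.  Rendering order is the order of node creation by
default; an optional front-to-back ordering by node-centre distance is
available.  Opaque geometry can be injected up front as a colour + depth
layer, which volumes then correctly occlude and are occluded by.

The scheme is exact for transfer functions whose visible voxels are opaque;
heavily semi-transparent volumes that interleave in depth are not blended
correctly across passes (the price of sequential passes), which the
one-pass reference renderer in :mod:`multivol.oracle` makes measurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .core import Camera, Scene, VolumeNode
from .raymarch import (
    RenderParams,
    SkipGrid,
    build_skip_grid,
    generate_rays,
    march_rays,
)

__all__ = [
    "FrameBuffer",
    "ScreenRect",
    "Light",
    "ShadowMap",
    "project_screen_rect",
    "render_volume_pass",
    "blit_depth",
    "render_scene",
    "render_scene_naive",
    "render_shadow_map",
    "init_framebuffer",
]

log = logging.getLogger(__name__)


@dataclass
class FrameBuffer:
    """Colour + hit-distance depth shared across volume passes.

    ``color`` holds premultiplied RGB accumulated by the passes; ``alpha``
    the matching accumulated opacity; ``depth`` the per-pixel nearest hit
    distance in mm (initialized to the far plane, or to the opaque layer's
    converted depth).  ``resolve()`` returns displayable RGB with the
    remaining transparency filled by ``backdrop`` (background colour or the
    opaque layer's colour).
    """

    color: np.ndarray
    alpha: np.ndarray
    depth: np.ndarray
    backdrop: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.depth.shape  # (H, W)

    def resolve(self) -> np.ndarray:
        return self.color + (1.0 - self.alpha)[..., None] * self.backdrop

    def copy(self) -> "FrameBuffer":
        return FrameBuffer(
            self.color.copy(), self.alpha.copy(), self.depth.copy(), self.backdrop.copy()
        )


@dataclass(frozen=True)
class ScreenRect:
    """Half-open integer pixel bounds ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x0 > self.x1 or self.y0 > self.y1:
            raise ValueError("rect bounds out of order")

    @property
    def empty(self) -> bool:
        return self.x0 >= self.x1 or self.y0 >= self.y1

    @property
    def area(self) -> int:
        return max(0, self.x1 - self.x0) * max(0, self.y1 - self.y0)

    @classmethod
    def full(cls, camera: Camera) -> "ScreenRect":
        w, h = camera.image_size
        return cls(0, 0, w, h)

    def pixel_grid(self) -> Tuple[np.ndarray, np.ndarray]:
        """Flat (ix, iy) arrays of all pixels inside the rect."""
        xs = np.arange(self.x0, self.x1)
        ys = np.arange(self.y0, self.y1)
        gx, gy = np.meshgrid(xs, ys)
        return gx.ravel(), gy.ravel()


@dataclass
class ShadowMap:
    """First-opaque-hit distances from the light, plus the light camera."""

    camera: Camera
    dist: np.ndarray  # (H, W) ray distances from the light, far where none

    def visibility(self, p_world: np.ndarray, bias: float = 1.0) -> np.ndarray:
        """1 where the light reaches ``p_world`` (within ``bias`` mm), 0 where
        an opaque hit lies strictly closer to the light."""
        p = np.atleast_2d(np.asarray(p_world, dtype=np.float64))
        cam = self.camera
        rel = p - cam.eye
        z = rel @ cam.forward
        d = np.linalg.norm(rel, axis=-1)
        px, py = _project_pixels(cam, rel, z)
        h, w = self.dist.shape
        ix = np.floor(px + 0.5).astype(np.int64)
        iy = np.floor(py + 0.5).astype(np.int64)
        inside = (z > 0) & (ix >= 0) & (ix < w) & (iy >= 0) & (iy < h)
        vis = np.ones(len(p))
        ii = np.flatnonzero(inside)
        occluded = d[ii] > self.dist[iy[ii], ix[ii]] + bias
        vis[ii[occluded]] = 0.0
        return vis


@dataclass
class Light:
    """A point light; its shadow map is produced by a depth-only render pass
    from ``camera`` (built automatically to cover the scene when omitted)."""

    position: np.ndarray
    camera: Optional[Camera] = None
    shadow_map: Optional[ShadowMap] = None
    shadow_size: int = 256

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.float64)


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def _project_pixels(camera: Camera, rel: np.ndarray, z: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Pixel-center coordinates of camera-relative points (callers must
    ensure z > 0)."""
    w, h = camera.image_size
    tan_v = np.tan(np.deg2rad(camera.vfov) / 2.0)
    tan_h = tan_v * w / h
    x = rel @ camera.right
    y = rel @ camera.up
    u = (x / z) / tan_h
    v = (y / z) / tan_v
    px = (u + 1.0) / 2.0 * w - 0.5
    py = (1.0 - v) / 2.0 * h - 0.5
    return px, py


def project_screen_rect(camera: Camera, node: VolumeNode) -> ScreenRect:
    """The minimum screen-space bounding rectangle of a node's box.

    Projects the eight world-space corners of the node's local box and takes
    the padded min/max pixel bounds, clipped to the viewport.  If any corner
    lies at or behind the near plane the perspective bounds are unreliable
    and the full viewport is returned (a safe over-approximation); a box
    entirely outside the frustum yields an empty rect.
    """
    w, h = camera.image_size
    corners = node.world_corners()
    rel = corners - camera.eye
    z = rel @ camera.forward
    if np.all(z <= camera.near):
        return ScreenRect(0, 0, 0, 0)  # entirely behind the near plane
    if np.any(z <= camera.near):
        return ScreenRect.full(camera)
    px, py = _project_pixels(camera, rel, z)
    x0 = int(np.floor(px.min())) - 1
    x1 = int(np.ceil(px.max())) + 2
    y0 = int(np.floor(py.min())) - 1
    y1 = int(np.ceil(py.max())) + 2
    x0, x1 = max(0, x0), min(w, x1)
    y0, y1 = max(0, y0), min(h, y1)
    if x0 >= x1 or y0 >= y1:
        return ScreenRect(0, 0, 0, 0)
    return ScreenRect(x0, y0, x1, y1)


# ---------------------------------------------------------------------------
# Frame-buffer initialization (shared with the one-pass oracle)
# ---------------------------------------------------------------------------


def init_framebuffer(scene: Scene, camera: Camera) -> FrameBuffer:
    """Fresh frame buffer: empty premultiplied colour, depth at the far
    plane, backdrop = background colour — or the opaque layer's colour and
    its camera-space z converted to per-pixel ray distance."""
    w, h = camera.image_size
    color = np.zeros((h, w, 3))
    alpha = np.zeros((h, w))
    depth = np.full((h, w), float(camera.far))
    backdrop = np.broadcast_to(np.asarray(scene.background, dtype=np.float64), (h, w, 3)).copy()
    if scene.opaque_layer is not None:
        layer_color, layer_z = scene.opaque_layer
        layer_color = np.asarray(layer_color, dtype=np.float64)
        layer_z = np.asarray(layer_z, dtype=np.float64)
        if layer_color.shape[:2] != (h, w) or layer_z.shape != (h, w):
            raise ValueError("opaque layer shape does not match camera image size")
        backdrop = layer_color[..., :3].copy()
        ix, iy = ScreenRect.full(camera).pixel_grid()
        _, d = generate_rays(camera, ix, iy)
        cos = (d @ camera.forward).reshape(h, w)
        t = layer_z / cos  # camera-space z -> distance along each pixel's ray
        depth = np.where(layer_z < camera.far, np.minimum(t, camera.far), camera.far)
    return FrameBuffer(color, alpha, depth, backdrop)


# ---------------------------------------------------------------------------
# Passes
# ---------------------------------------------------------------------------


def render_volume_pass(
    fb: FrameBuffer,
    node: VolumeNode,
    camera: Camera,
    params: RenderParams,
    *,
    skip: Optional[SkipGrid] = None,
    light: Optional[Light] = None,
    shadow: Optional[ShadowMap] = None,
    rect: Optional[ScreenRect] = None,
    clamp_to_depth: bool = True,
) -> Tuple[np.ndarray, ScreenRect]:
    """Render one volume into ``fb`` (in place).

    Only pixels inside the node's screen rect are touched.  Each ray is
    clamped to the depth already in ``fb`` (set ``clamp_to_depth=False`` for
    the naive, occlusion-free renderer), the pass colour is composited over
    the existing colour, and the per-pixel hit distances are returned as a
    pass-depth image (far where no hit) for :func:`blit_depth`.
    """
    h, w = fb.shape
    pass_depth = np.full((h, w), float(camera.far))
    if rect is None:
        rect = project_screen_rect(camera, node) if params.use_rect else ScreenRect.full(camera)
    if rect.empty:
        return pass_depth, rect
    if params.skip_grid and skip is None:
        skip = build_skip_grid(node)
    ix, iy = rect.pixel_grid()
    o, d = generate_rays(camera, ix, iy)
    t_clamp = fb.depth[iy, ix] if clamp_to_depth else np.full(len(ix), float(camera.far))
    C, A, hit = march_rays(
        node, o, d, camera.near, camera.far, t_clamp, params,
        skip=skip, light=light, shadow=shadow,
    )
    # composite this pass OVER the existing colour: every ray was clamped at
    # the existing depth, so the existing colour summarizes what lies behind
    w1 = 1.0 - A
    fb.color[iy, ix] = C + w1[:, None] * fb.color[iy, ix]
    fb.alpha[iy, ix] = A + w1 * fb.alpha[iy, ix]
    pass_depth[iy, ix] = np.where(np.isinf(hit), float(camera.far), hit)
    if log.isEnabledFor(logging.INFO):
        n_hit = int(np.isfinite(hit).sum())
        log.info(
            "pass %-16s rect=(%d,%d)-(%d,%d) pixels=%d early-term=%.1f%%",
            node.name, rect.x0, rect.y0, rect.x1, rect.y1, rect.area,
            100.0 * n_hit / max(1, rect.area),
        )
    return pass_depth, rect


def blit_depth(fb: FrameBuffer, pass_depth: np.ndarray, rect: Optional[ScreenRect] = None) -> FrameBuffer:
    """Depth-test blit: within ``rect``, take ``pass_depth`` where it is
    strictly smaller (ties keep the earlier pass's value)."""
    if pass_depth.shape != fb.depth.shape:
        raise ValueError(
            f"pass depth shape {pass_depth.shape} != framebuffer {fb.depth.shape}"
        )
    if rect is None:
        sl = (slice(None), slice(None))
    else:
        if rect.empty:
            return fb
        sl = (slice(rect.y0, rect.y1), slice(rect.x0, rect.x1))
    region = fb.depth[sl]
    fb.depth[sl] = np.where(pass_depth[sl] < region, pass_depth[sl], region)
    return fb


def _ordered_nodes(scene: Scene, camera: Camera, order: str) -> List[VolumeNode]:
    nodes = scene.visible_nodes()
    if order == "creation":
        return nodes
    if order == "front-to-back":
        def dist(n: VolumeNode) -> float:
            lo, hi = n.local_box()
            center = np.asarray(n.pose.matrix[:3, :3] @ ((lo + hi) / 2.0) + n.pose.matrix[:3, 3])
            return float(np.linalg.norm(center - camera.eye))
        return sorted(nodes, key=dist)
    raise ValueError(f"unknown render order {order!r}")


def render_scene(
    scene: Scene,
    camera: Camera,
    params: Optional[RenderParams] = None,
    *,
    order: str = "creation",
    collect_pass_depths: bool = False,
):
    """Render a scene with per-volume passes and depth-buffer occlusion.

    Volumes are rendered in creation order (or nearest-first when
    ``order="front-to-back"``); after every pass its hit distances are
    blitted into the shared depth buffer so later passes march only
    unoccluded space.  Returns the :class:`FrameBuffer`; with
    ``collect_pass_depths=True`` returns ``(fb, [per-pass depth images])``.
    """
    params = params or RenderParams()
    fb = init_framebuffer(scene, camera)
    nodes = _ordered_nodes(scene, camera, order)
    if nodes and params.step is None:
        params = replace(params, step=params.resolved_step(*[n.volume for n in nodes]))
    shadow = None
    if params.shading and scene.light is not None:
        shadow = scene.light.shadow_map
        if shadow is None:
            shadow = render_shadow_map(scene, scene.light, params)
    depths = []
    for node in nodes:
        skip = build_skip_grid(node) if params.skip_grid else None
        pass_depth, rect = render_volume_pass(
            fb, node, camera, params, skip=skip, light=scene.light, shadow=shadow
        )
        blit_depth(fb, pass_depth, rect)
        if collect_pass_depths:
            depths.append(pass_depth)
    if collect_pass_depths:
        return fb, depths
    return fb


def render_scene_naive(
    scene: Scene,
    camera: Camera,
    params: Optional[RenderParams] = None,
    *,
    order: str = "creation",
) -> FrameBuffer:
    """Occlusion-free comparator: every volume rendered independently over
    the full ray range and alpha-blended new-over-existing, with no depth
    clamping or testing.  Deliberately wrong for overlapping volumes; used
    to demonstrate why the depth buffer is needed.
    """
    params = params or RenderParams()
    fb = init_framebuffer(scene, camera)
    nodes = _ordered_nodes(scene, camera, order)
    if nodes and params.step is None:
        params = replace(params, step=params.resolved_step(*[n.volume for n in nodes]))
    for node in nodes:
        skip = build_skip_grid(node) if params.skip_grid else None
        render_volume_pass(
            fb, node, camera, params, skip=skip, clamp_to_depth=False
        )
    return fb


# ---------------------------------------------------------------------------
# Shadow pass
# ---------------------------------------------------------------------------


def _light_camera(scene: Scene, light: Light) -> Camera:
    """A perspective camera at the light covering the scene bounds."""
    lo, hi = scene.world_bounds()
    center = (lo + hi) / 2.0
    radius = float(np.linalg.norm(hi - lo)) / 2.0
    dist = float(np.linalg.norm(center - light.position))
    if dist <= radius:
        raise ValueError("light inside the scene bounds: cannot build shadow camera")
    vfov = np.rad2deg(2.0 * np.arcsin(min(0.999, radius / dist))) * 1.1
    near = max(1e-3, dist - radius * 1.05)
    far = dist + radius * 1.05
    return Camera.look_at(
        light.position, center,
        vfov=min(178.0, vfov),
        image_size=(light.shadow_size, light.shadow_size),
        near=near, far=far,
    )


def render_shadow_map(scene: Scene, light: Light, params: RenderParams) -> ShadowMap:
    """Depth-only multi-pass render from the light's point of view.

    Runs the same per-volume pass + depth-blit machinery with all colour
    work disabled; the resulting depth buffer holds the first-opaque-hit
    distance to the light per texel (far where the light escapes).
    """
    cam = light.camera or _light_camera(scene, light)
    nodes = scene.visible_nodes()
    if nodes and params.step is None:
        params = replace(params, step=params.resolved_step(*[n.volume for n in nodes]))
    fb = FrameBuffer(
        color=np.zeros((cam.image_size[1], cam.image_size[0], 3)),
        alpha=np.zeros((cam.image_size[1], cam.image_size[0])),
        depth=np.full((cam.image_size[1], cam.image_size[0]), float(cam.far)),
        backdrop=np.zeros((cam.image_size[1], cam.image_size[0], 3)),
    )
    for node in nodes:
        skip = build_skip_grid(node) if params.skip_grid else None
        rect = project_screen_rect(cam, node) if params.use_rect else ScreenRect.full(cam)
        if rect.empty:
            continue
        ix, iy = rect.pixel_grid()
        o, d = generate_rays(cam, ix, iy)
        _, _, hit = march_rays(
            node, o, d, cam.near, cam.far, fb.depth[iy, ix], params,
            skip=skip, depth_only=True,
        )
        pass_depth = np.full(fb.depth.shape, float(cam.far))
        pass_depth[iy, ix] = np.where(np.isinf(hit), float(cam.far), hit)
        blit_depth(fb, pass_depth, rect)
    return ShadowMap(camera=cam, dist=fb.depth)
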