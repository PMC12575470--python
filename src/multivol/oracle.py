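"""One-pass reference renderer: sample every volume at every marching step.

This is the straightforward (and, on a GPU, slow) alternative to the
multi-pass depth-buffer renderer: a single front-to-back march per pixel on
a global sample lattice ``t = k * step`` from the eye, classifying the
sample of *every* volume that contains the point and compositing the
contributions in node-list order before advancing.  It needs no screen
rectangles, no skip grids and no depth buffer, which makes it the natural
correctness oracle for the multi-pass renderer:

* for opaque transfer functions on the shared (aligned) sample lattice the
  two renderers agree bit-exactly, because they execute the identical
  sampling, classification and compositing arithmetic on the identical
  sample set;
* for semi-transparent volumes that interleave in depth they genuinely
  differ — the documented limitation of sequential per-volume passes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Camera, Scene
from .multivolume import FrameBuffer, ScreenRect, init_framebuffer
from .raymarch import (
    _intersect_aabb_batch,
    aligned_first_index,
    composite_into,
    generate_rays,
    node_local_ray,
    node_rgba_at,
)

__all__ = ["OracleParams", "render_onepass"]


@dataclass
class OracleParams:
    """Marching parameters of the one-pass renderer.

    ``step`` is the global sampling interval from the eye (mm; ``None``
    means 0.5 x the smallest voxel spacing in the scene) and
    ``alpha_threshold`` the early-termination opacity, as in
    :class:`multivol.raymarch.RenderParams`.
    """

    step: Optional[float] = None
    alpha_threshold: float = 0.99

    def __post_init__(self) -> None:
        if self.step is not None and self.step <= 0:
            raise ValueError("step must be positive")
        if not 0.0 < self.alpha_threshold <= 1.0:
            raise ValueError("alpha_threshold must be in (0, 1]")


def render_onepass(
    scene: Scene, camera: Camera, params: Optional[OracleParams] = None
) -> FrameBuffer:
    """Render ``scene`` with a single all-volumes-per-step march per pixel.

    Per pixel: march ``t = k * step`` over ``[near, far)``; at each step
    classify the sample of every volume whose box contains the point and
    composite front-to-back in node-list order; terminate when the
    accumulated opacity reaches the threshold and record that distance as
    depth (far where never reached).  Background / opaque-layer handling is
    identical to the multi-pass renderer (rays are clamped at the opaque
    layer's depth and the remaining transparency resolves over it).
    """
    params = params or OracleParams()
    fb = init_framebuffer(scene, camera)
    nodes = scene.visible_nodes()
    if not nodes:
        return fb
    step = params.step
    if step is None:
        step = 0.5 * min(min(n.volume.spacing) for n in nodes)
    thresh = params.alpha_threshold

    h, w = fb.shape
    ix, iy = ScreenRect.full(camera).pixel_grid()
    origins, dirs = generate_rays(camera, ix, iy)
    n_pix = len(ix)
    init_depth = fb.depth[iy, ix]

    # Per-node local rays and march intervals (the same slab routine the
    # multi-pass renderer uses, so containment decisions agree exactly).
    locals_, k0s, t_ends, inboxes = [], [], [], []
    for node in nodes:
        o_l, d_l = node_local_ray(node, origins, dirs)
        lo, hi = node.local_box()
        t_enter, t_exit, inbox = _intersect_aabb_batch(
            o_l, d_l, lo, hi, camera.near, camera.far
        )
        locals_.append((o_l, d_l))
        k0s.append(aligned_first_index(t_enter, step))
        t_ends.append(np.minimum(t_exit, init_depth))
        inboxes.append(inbox)

    C = np.zeros((n_pix, 3))
    A = np.zeros(n_pix)
    hit = np.full(n_pix, np.inf)

    any_box = np.logical_or.reduce(inboxes)
    if any_box.any():
        t_max = np.full(n_pix, -np.inf)
        for t_end, inbox in zip(t_ends, inboxes):
            t_max = np.where(inbox, np.maximum(t_max, t_end), t_max)
        k = int(min(k0s[i][inboxes[i]].min() for i in range(len(nodes)) if inboxes[i].any()))
        alive = any_box.copy()
        while True:
            t = k * step
            if not (alive & (t < t_max)).any():
                break
            for i, node in enumerate(nodes):
                m = alive & inboxes[i] & (k >= k0s[i]) & (t < t_ends[i])
                sub = np.flatnonzero(m)
                if sub.size:
                    o_l, d_l = locals_[i]
                    p_l = o_l[sub] + t * d_l[sub]
                    rgba = node_rgba_at(node, p_l, step)
                    composite_into(C, A, sub, rgba[:, :3], rgba[:, 3])
            newly = alive & (A >= thresh)
            if newly.any():
                hit[newly] = t
                alive[newly] = False
            k += 1

    fb.color[iy, ix] = C
    fb.alpha[iy, ix] = A
    fb.depth[iy, ix] = np.where(np.isinf(hit), init_depth, hit)
    return fb
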