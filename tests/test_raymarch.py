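"""Ray generation, box intersection, the marcher, skipping and shading."""

import numpy as np
import pytest

from conftest import blob_node
from multivol.core import (
    AffinePose,
    Camera,
    ScalarVolume,
    SegmentationMask,
    TransferFunction,
    VolumeNode,
    binary_tf,
    ramp_tf,
)
from multivol.multivolume import Light, render_scene
from multivol.raymarch import (
    Ray,
    RenderParams,
    build_skip_grid,
    generate_ray,
    generate_rays,
    intersect_ray_aabb,
    march_single,
    shade,
)
from multivol.synthetic import PhantomSpec, fit_camera, phantom_scene


def slab_node(thickness_mm=10.0, intensity=50.0, alpha=0.5, ref_step=1.0, nx=11):
    """A homogeneous slab along x with a constant-alpha transfer function."""
    data = np.full((nx, 5, 5), intensity, dtype=np.float64)
    tf = TransferFunction(
        [(0.0, 1, 1, 1, alpha), (100.0, 1, 1, 1, alpha)], reference_step=ref_step
    )
    return VolumeNode(volume=ScalarVolume(data), tf=tf)


def axis_ray(t_near=0.1, t_far=1000.0):
    return Ray(np.array([-20.0, 2.0, 2.0]), np.array([1.0, 0.0, 0.0]), t_near, t_far)


class TestGenerateRay:
    def test_center_pixel_is_forward(self):
        cam = Camera.look_at((0, 0, 0), (0, 1, 0), image_size=(65, 65))
        ray = generate_ray(cam, (32, 32))
        assert np.allclose(ray.direction, cam.forward, atol=1e-12)

    def test_directions_are_unit(self):
        cam = Camera.look_at((5, -3, 2), (0, 0, 0), image_size=(17, 9), vfov=55.0)
        ix, iy = np.meshgrid(np.arange(17), np.arange(9))
        _, d = generate_rays(cam, ix.ravel(), iy.ravel())
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)

    def test_top_center_angle_closed_form(self):
        h = 33
        cam = Camera.look_at((0, 0, 0), (1, 0, 0), image_size=(h, h), vfov=40.0)
        ray = generate_ray(cam, (h // 2, 0))
        angle = np.arccos(np.clip(ray.direction @ cam.forward, -1, 1))
        # top-row pixel center sits (h-1)/h of the way to the frustum edge
        expected = np.arctan(np.tan(np.deg2rad(20.0)) * (h - 1) / h)
        assert angle == pytest.approx(expected, abs=1e-12)

    def test_pixel_out_of_range(self):
        cam = Camera.look_at((0, 0, 0), (1, 0, 0), image_size=(8, 8))
        with pytest.raises(ValueError, match="outside"):
            generate_ray(cam, (8, 0))


class TestIntersectRayAABB:
    def test_basic_interval(self):
        ray = Ray(np.zeros(3), np.array([1.0, 0.0, 0.0]), 0.1, 100.0)
        hit = intersect_ray_aabb(ray, np.array([2.0, -1, -1]), np.array([3.0, 1, 1]))
        assert hit == (2.0, 3.0)

    def test_miss(self):
        ray = Ray(np.zeros(3), np.array([1.0, 0.0, 0.0]), 0.1, 100.0)
        assert intersect_ray_aabb(ray, np.array([2.0, 2, -1]), np.array([3.0, 3, 1])) is None

    def test_origin_inside_clamps_to_near(self):
        ray = Ray(np.zeros(3), np.array([1.0, 0.0, 0.0]), 0.25, 100.0)
        hit = intersect_ray_aabb(ray, np.array([-5.0, -1, -1]), np.array([5.0, 1, 1]))
        assert hit == (0.25, 5.0)

    def test_behind_ray_misses(self):
        ray = Ray(np.zeros(3), np.array([1.0, 0.0, 0.0]), 0.1, 100.0)
        assert intersect_ray_aabb(ray, np.array([-3.0, -1, -1]), np.array([-2.0, 1, 1])) is None


class TestMarchSingle:
    def test_transparent_tf_yields_nothing(self):
        node = slab_node(alpha=0.0)
        rgba, hit = march_single(axis_ray(), node, RenderParams(step=0.5))
        assert rgba == (0.0, 0.0, 0.0, 0.0)
        assert hit is None

    def test_opaque_hit_at_first_sample(self):
        node = blob_node((0.0, 0.0, 0.0))
        ray = Ray(np.array([-60.0, 0.0, 0.0]), np.array([1.0, 0.0, 0.0]), 1.0, 300.0)
        params = RenderParams(step=0.5)
        rgba, hit = march_single(ray, node, params)
        assert hit is not None
        assert rgba[3] == 1.0
        assert rgba[:3] == (1.0, 1.0, 1.0)
        # hit lies on the sampling lattice t_enter + (k + 1/2) * step
        lo, hi = node.local_box()
        o, d = ray.origin - node.pose.matrix[:3, 3], ray.direction
        t_enter = (lo[0] - o[0]) / d[0]
        assert (hit - t_enter - 0.25) % 0.5 == pytest.approx(0.0, abs=1e-9)

    def test_clamp_at_near_yields_nothing(self):
        node = slab_node(alpha=0.9)
        ray = axis_ray()
        rgba, hit = march_single(ray, node, RenderParams(step=0.5), t_clamp=ray.t_near)
        assert rgba == (0.0, 0.0, 0.0, 0.0) and hit is None

    @pytest.mark.parametrize("alpha,step", [(0.5, 1.0), (0.2, 0.5), (0.9, 0.25)])
    def test_homogeneous_slab_transmittance_closed_form(self, alpha, step):
        """Accumulated opacity of n constant-alpha samples is 1-(1-a')^n."""
        node = slab_node(alpha=alpha, ref_step=1.0)
        params = RenderParams(step=step, alpha_threshold=1.0)
        ray = axis_ray()
        (_, _, _, A), _ = march_single(ray, node, params)
        lo, hi = node.local_box()
        t_enter = lo[0] - ray.origin[0]
        t_exit = hi[0] - ray.origin[0]
        n = int(np.ceil((t_exit - t_enter) / step - 0.5))  # midpoint samples
        a_corr = 1.0 - (1.0 - alpha) ** step
        assert A == pytest.approx(1.0 - (1.0 - a_corr) ** n, abs=1e-9)

    def test_accumulation_bounds_and_premultiplied(self, rng):
        node = VolumeNode(
            volume=ScalarVolume(rng.uniform(0, 100, size=(9, 9, 9))),
            tf=ramp_tf(0.0, 100.0, (0.8, 0.5, 0.2), max_alpha=0.7),
        )
        for _ in range(10):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            ray = Ray(np.array([4.0, 4.0, 4.0]) - 30 * d, d, 0.5, 200.0)
            (r, g, b, A), _ = march_single(ray, node, RenderParams(step=0.7))
            assert 0.0 <= A <= 1.0
            assert max(r, g, b) <= A + 1e-12

    def test_step_refinement_converges(self):
        """Opacity-corrected accumulation approaches the continuous
        transmittance limit as the step shrinks."""
        L, a = 11.0, 0.4  # the 11-voxel slab box spans [-0.5, 10.5] mm
        analytic = 1.0 - (1.0 - a) ** L  # reference_step 1 mm, slab L mm
        results = []
        for step in (1.0, 0.5, 0.25):
            node = slab_node(alpha=a)
            (_, _, _, A), _ = march_single(
                axis_ray(), node, RenderParams(step=step, alpha_threshold=1.0)
            )
            results.append(A)
        errs = [abs(A - analytic) for A in results]
        assert errs[2] < 0.05
        assert abs(results[0] - results[1]) < 0.05  # halving changes little


class TestSkipGrid:
    def test_all_zero_volume_fully_skippable(self):
        node = VolumeNode(
            volume=ScalarVolume(np.zeros((16, 16, 16))), tf=binary_tf(300.0)
        )
        grid = build_skip_grid(node, block_size=4)
        assert grid.skippable(node.tf).all()

    def test_single_bright_voxel_dilated(self):
        data = np.zeros((16, 16, 16))
        data[8, 8, 8] = 1000.0
        node = VolumeNode(volume=ScalarVolume(data), tf=binary_tf(300.0))
        grid = build_skip_grid(node, block_size=4)
        sk = grid.skippable(node.tf)
        # voxel (8,8,8) sits at a block corner; it and the three lower
        # neighbours along each axis see it through their 1-voxel dilation
        not_skippable = np.argwhere(~sk)
        assert set(map(tuple, not_skippable)) == {
            (bx, by, bz) for bx in (1, 2) for by in (1, 2) for bz in (1, 2)
        }

    def test_labelled_blocks_conservatively_kept(self):
        labels = np.zeros((8, 8, 8), dtype=np.uint8)
        labels[0, 0, 0] = 1
        node = VolumeNode(
            volume=ScalarVolume(np.zeros((8, 8, 8))),
            mask=SegmentationMask(labels),
            tf=binary_tf(300.0),
        )
        sk = build_skip_grid(node, block_size=4).skippable(node.tf)
        assert not sk[0, 0, 0] and sk[1, 1, 1]

    def test_skipping_never_changes_the_image(self):
        scene = phantom_scene(PhantomSpec(kind="fracture", dims=(48, 48, 48), seed=2))
        cam = fit_camera(scene, (64, 64))
        on = render_scene(scene, cam, RenderParams(skip_grid=True))
        off = render_scene(scene, cam, RenderParams(skip_grid=False))
        assert np.array_equal(on.resolve(), off.resolve())
        assert np.array_equal(on.depth, off.depth)

    def test_block_size_validated(self):
        node = slab_node()
        with pytest.raises(ValueError, match="block_size"):
            build_skip_grid(node, block_size=1)


class TestShade:
    def ramp_node(self):
        # intensity grows along +x -> gradient +x -> surface normal -x
        data = np.tile(np.arange(9.0)[:, None, None] * 100.0, (1, 9, 9))
        return VolumeNode(volume=ScalarVolume(data), tf=binary_tf(300.0))

    def test_normal_facing_light_fully_lit(self):
        node = self.ramp_node()
        light = Light(position=np.array([-100.0, 4.0, 4.0]))  # along -x: n.l = 1
        out = shade(node, np.array([4.0, 4.0, 4.0]), (1.0, 0.5, 0.25), light)
        assert np.allclose(out, np.array([1.0, 0.5, 0.25]) * (0.3 + 0.7))

    def test_normal_perpendicular_to_light(self):
        node = self.ramp_node()
        light = Light(position=np.array([4.0, 100.0, 4.0]))  # along +y: n.l = 0
        out = shade(node, np.array([4.0, 4.0, 4.0]), (1.0, 1.0, 1.0), light)
        assert np.allclose(out, (0.3, 0.3, 0.3))

    def test_zero_gradient_fully_lit_fallback(self):
        node = slab_node(intensity=42.0)
        light = Light(position=np.array([0.0, 100.0, 0.0]))
        out = shade(node, np.array([5.0, 2.0, 2.0]), (0.5, 0.5, 0.5), light)
        assert np.allclose(out, np.array([0.5, 0.5, 0.5]) * (0.3 + 0.7))
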