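# Methods

This note documents the rendering model, the numerical choices, the
synthetic phantoms and the limits of what the test suite demonstrates.

## Scene and sampling model

A volume node couples a scalar grid (`data[ix, iy, iz]`, spacing in mm per
axis), an optional 8-bit segmentation mask of identical dims (0 =
unassigned, so up to 255 segments), a transfer function and a 4×4 affine
pose.  Voxel centers sit at integer voxel coordinates; the renderable box
is `[-0.5, dim-0.5] · spacing` per axis, so trilinear interpolation is
defined over the whole box via clamping to boundary voxels.  This
half-voxel convention makes ray/box intersection unambiguous: the slab
interval is intersected with the camera's `[near, far]` and the entry
distance clamped to `near` for rays starting inside.

Intensity is sampled trilinearly; labels are nearest-neighbour (rounding
each coordinate, halves up; outside the grid → 0).  Interpolating
labels would fabricate segments that exist nowhere in the data, which is
why the two samplers differ.

The transfer function is a piecewise-linear RGBA lookup over strictly
increasing intensity control points, clamped to its end values outside the
domain (standard DVR practice; extrapolation produces artefacts).  The
stored alpha is calibrated at a reference step (default 1 mm) and rescaled
to the marching step via exponential transmittance,
`α' = 1 − (1 − α)^(Δt/Δt_ref)`; per-segment opacity multiplies the raw
alpha before the rescale, so a multiplier of 0 hides a segment exactly.
A "binary" preset places the 0→1 opacity ramp in a 1e-6-wide intensity
interval: sampled intensities land on exact 0 or exact 1, which is what
makes opaque-scene renders exactly reproducible across renderers.

## The multi-pass renderer

Each visible node is rendered in creation order (the default ordering rule;
nearest-first ordering is available as a performance option, as depth
testing then rejects more work).  A pass:

1. restricts itself to the screen rectangle spanned by the projected box
   corners, padded 1 px and clipped to the viewport.  The projection of a
   convex box with all corners in front of the near plane lies inside the
   corner bounds, so the rect is exact; if any corner is at or behind the
   near plane the full viewport is used (safe over-approximation), and a
   box entirely behind the near plane is skipped;
2. marches each ray over its box interval **clamped to the shared depth
   buffer** (strict `t < depth`), compositing front-to-back in
   premultiplied colour, terminating when accumulated opacity reaches the
   threshold (default 0.99) and recording the hit distance;
3. composites the pass image **over** the frame-buffer colour.  This is
   correct because the clamp guarantees the existing colour summarizes only
   content at or behind every sample of this pass — it is also the step
   that breaks down for interleaved semi-transparency (see Limitations);
4. blits the pass's hit distances into the depth buffer with a strict
   less-than test, so ties keep the earlier pass, matching the one-pass
   renderer's node-order compositing at a shared sample.

Depth is the Euclidean distance along the ray, not perspective z: all
passes share identical per-pixel rays, so per-ray distance makes the clamp
exact, and depth images remain comparable across resolutions and far
planes.  An opaque layer supplied in camera-space z is converted per pixel
(`t = z / (d · forward)`) on load.  Rays that hit nothing leave the far
plane in place, which the min-blit makes a no-op.

Sampling offsets: by default samples sit at `t_enter + (k + ½)Δt`
(midpoint, reduces boundary bias; no jitter — determinism is a feature
here).  With `align_global_grid` samples sit on the global lattice
`t = kΔt` from the eye, shared by every pass and by the one-pass renderer;
this mode exists so that the two renderers execute the *identical*
floating-point sample set.  The default step is half the smallest voxel
spacing of the scene's volumes, resolved once per render so every pass of
one frame uses the same step.

## The one-pass reference renderer

`render_onepass` marches every pixel over the global lattice and, at each
step, classifies the sample of every node whose box interval contains it
(the same slab routine decides containment), compositing contributions in
node-list order before advancing; it terminates at the same opacity
threshold and records the same ray-distance depth.  It shares the sampling,
classification and compositing helpers with the marcher, deliberately
omits every acceleration structure, and serves as ground truth: for opaque
transfer functions the two renderers agree bit-exactly, and the test suite
asserts exactly that, along with the constructed semi-transparent case
where they must differ.

## Acceleration structures (and why they are invisible)

*Empty-space skipping*: a block grid (default 8³ voxels) stores per-block
intensity min/max over the block dilated by one voxel, so any trilinear
sample whose containing block is flagged empty provably draws only on
voxels whose classified alpha is zero.  A block is skipped only when the
transfer function's alpha is zero over the whole dilated intensity range
*assuming opacity multiplier 1*, and blocks containing any labelled voxel
are conservatively never skipped — hiding or un-hiding segments can
therefore never create a false skip.  Skipped samples would have
contributed exactly `0.0` to the accumulators, so skipping cannot change a
single bit of the image; skipping operates at sample granularity (the
classification work is what dominates on a CPU).

*Screen rects*: pixels outside a volume's rect are untouched by its pass;
since no center ray of such a pixel can intersect the box, forcing
full-viewport rects is bit-identical too.  Both claims are asserted by
tests on all phantom scenes.

## Segmentation, extraction, shadows, shading

The sphere brush assigns a label to every voxel whose world-space center
lies within the brush radius (exact distance test; the iterated voxel range
is conservatively bounded through the pose inverse).  Extraction computes
the label's tight voxel AABB, pads it by 1 voxel (clamped at the source
extent) so the copied grid has trilinear support at the segment boundary,
copies intensities and the restricted mask, copies the transfer function,
hides unassigned voxels in the copy (`segment_opacity[0] = 0` — the
extracted node shows only its own segment) and hides the segment in the
source (`segment_opacity[label] = 0`, no data mutation, trivially
reversible).  The new node's pose composes the source pose with the AABB
offset, so the piece initially renders in place; the conservation test
verifies that a pre/post-extraction render differs on at most 1 % of
pixels, all within 1 px of the segment silhouette (trilinear mixing at the
label edge is the only possible difference).

The shadow pass runs the same multi-pass machinery from a light camera
(auto-fitted perspective camera covering the scene bounds; a single
frustum, not a cube map) with all colour work disabled, storing
first-opaque-hit distances.  Shading is Lambertian on the negated
central-difference intensity gradient (1-voxel offsets, transformed to
world by the inverse linear map), `base · (ambient 0.3 + diffuse 0.7 ·
max(0, n·l) · vis)`, with zero-gradient points treated as fully lit and
`vis` tested against the shadow map with a 1 mm default bias.

## Synthetic phantoms

The generator emulates the three target use cases at desk scale (default
64³–96 voxels; real scans are ~512×512×500, not needed for correctness):

* **spine** — 19 ellipsoidal vertebral bodies (C6–L5) with posterior
  protrusions along a seed-jittered scoliotic curve, plus one combined
  shoulder-girdle bar: 20 labels.
* **keyhole_skull** — a spherical shell with a one-sided circular
  through-disk segment (cylinder ∩ shell, one side of the centre), axis
  direction drawn from the seed: 1 label.
* **fracture** — the shell partitioned into k (default 5) fragments by
  directional Voronoi cells of k seed directions; cell boundaries are the
  bisector planes through the centre.  Discrete cells can pinch into
  diagonal-only slivers at boundaries, so a deterministic cleanup merges
  any non-largest 6-connected component into the adjacent fragment,
  guaranteeing exactly k single-component fragments.

Intensities are CT-like: soft tissue 40 ± 10 HU, bone 700 ± 20 HU, so a
hard threshold at 300 separates the modes with wide margin.  What the
phantoms do **not** emulate: anatomical shape realism, partial-volume
effects at real scanner resolution, metal/beam-hardening artefacts,
intensity inhomogeneity.  Passing tests demonstrate geometric and
compositing correctness of the renderer, not clinical image quality.

Random multi-volume test scenes (`random_opaque_scene`) place opaque
spheres with overlapping bounding boxes but pairwise-disjoint opaque voxel
sets (centre separation ≥ 2r + 4 mm) — the regime in which sequential
depth-buffer passes are provably exact, and the regime the acceptance
checks exercise at 128×128.

## Numerical choices

* `alpha_threshold` default 0.99; residual transmittance ≤ 0.01 bounds the
  cross-renderer colour difference for non-interleaving semi-transparent
  scenes (asserted as ≤ 0.011).
* Aligned-lattice index `k = ⌈t_enter/Δt⌉` is recomputed against the
  predicate `kΔt ≥ t_enter` in both directions to be robust to the ceil's
  floating-point error, so marcher and reference include exactly the same
  samples.
* Depth ties on the blit keep the earlier pass; the reference composites
  same-step contributions in node order — together these make tie pixels
  agree exactly.
* Degenerate inputs: rays parallel to a slab miss unless inside it;
  zero-length box intervals produce no samples; empty scenes resolve to the
  background at far depth; a volume behind the camera is skipped.

## Known limitations

* Interleaved semi-transparent volumes are composited in pass order, not
  depth order — wrong by design of the architecture, demonstrated by a
  dedicated test.  Transfer functions should keep visible voxels
  near-opaque.
* One perspective shadow frustum per light: a light inside the scene
  bounds (needing omnidirectional coverage) is rejected.
* NIfTI stores spacing and affine in 32-bit fields; round trips are exact
  for float32-representable values, and the NRRD writer carries exact
  spacing in a key/value pair.
* No foveated rendering, stereo cameras (render twice), mesh
  rasterization, pre-integrated transfer functions or curvilinear volumes.
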