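# Methods

This note records the model, the conventions, the tunable parameters and
the numerical choices behind `stereofix`, and what the synthetic-scene
tests do and do not establish.

## Binocular geometry

The head is a rigid body on a **Fick gimbal**: R_H = R_y(β_H)·R_x(α_H)
(vertical axis outermost), which by construction has no torsional
component.  Each camera is mounted on a **Helmholtz gimbal**:
R = R_x(α)·R_y(β) (horizontal axis outermost), the natural
parameterisation for verging pan-tilt cameras.  All frames are
right-handed with x to the right, y up, z toward the viewer; the
reference optical axis is −z; angles are degrees at every interface and
radians internally; translations are millimetres.

Fixation is *toe-in*: for a target F the per-camera Helmholtz angles are
the closed form β = arcsin(−g_x), α = atan2(g_y, −g_z) of the unit gaze
vector g = unit(F − T), verified against the forward rotation (the
residual is at the 1e-16 level).  Vergence and version are
ν = β_R − β_L and ξ = (β_L + β_R)/2.

**Sign conventions.** The left camera sits at (−b/2, 0, 0) and the right
at (+b/2, 0, 0) in the head frame, and positive β is leftward gaze.
These two choices make the two sign contracts of the field hold
simultaneously: ν > 0 for convergence, and crossed (nearer-than-fixation)
horizontal disparity positive.  Homogeneous image coordinates follow the
two-view relation x = X/λ with λ = z_eye < 0, i.e. the image x axis is
the mirror of the camera-frame x axis; this is the coordinate system in
which the reprojection and disparity formulas are exact as written, and
it is used consistently for rendering, disparity and warping.

**Torsion (L2).** During convergence the two Listing planes tilt
temporally and antisymmetrically,

    φ_L = −φ_R = (δ/2) · arcsin( sin ν / (2 cos(ξ/2)) ),

and the camera roll about its line of sight is

    tan(γ/2) = −tan(α/2) · (tan φ + tan β) / (1 + tan φ tan β),

applied as R_L2 = R_x(α) R_y(β) R_z(γ).  The gain δ ∈ [0, 1] trades the
monocular motor advantage of Listing's law (δ = 0) against the binocular
perceptual advantage of aligned horizontal meridians; the default is
δ = 0.8, the value commonly adopted in the oculomotor literature.  The
typography of the tilt formula is ambiguous in its printed source; the
reading above is kept behind the single function `listing_plane_tilt` so
it can be swapped, and the plausible alternative
(δ/2)·arcsin(sin(ν/2)/cos(ξ/2)) differs from it only at third order in ν.
Three torsion modes exist: `l2` (default), `ll` (tilt forced to zero —
pure Listing, which still needs the nonzero "false torsion" γ in
Helmholtz coordinates), and `none` (γ = 0).  The cyclopic camera, a
bookkeeping device at the baseline midpoint, never carries torsion.

The "parallel axes" (off-axis) comparison configuration gives both
cameras identical Helmholtz angles with β = 0, i.e. axes perpendicular to
the baseline: that is the configuration for which vertical disparity
vanishes identically, which is the property quoted for off-axis stereo.
(With β ≠ 0 the axes would still be parallel but the baseline acquires a
depth component and d_y ≠ 0.)

## Rendering

A deterministic pinhole ray caster: one primary ray per pixel centre, no
anti-aliasing, no lighting model — mesh textures are treated as baked
radiance, as appropriate for scanned/authored scenes, because the goal is
geometric fidelity of the ground truth rather than photorealism.  Pixels
are 0-based with half-pixel centres; the principal point is the image
centre ((W−1)/2, (H−1)/2); the image-plane half extent at unit focal
length is tan(HFOV/2) × tan(VFOV/2) (anisotropic pixels allowed,
square-pixel VFOV derived when omitted).  Depth is reported as eye-space
λ < 0 and additionally as the nonlinear z-buffer w ∈ [0, 1] through
λ = f·n/(w(f−n) − f), a bijection between [0,1] and [−f, −n].

Ray casting runs on numba-compiled kernels over a flat median-split BVH
(leaf size 4).  Equal-distance hits (shared edges) break deterministically
to the lowest triangle index, with a 1e-6 mm tie window; the BVH is
contract-tested to return exactly the brute-force nearest hit.  Default
working resolution is 480×270 (the published database's 1,921×1,081 is a
preset, not a hard-coded size).  Near/far planes default to 400/3,000 mm,
bracketing the protocol's viewing range.

## Ground truth

Disparity is derived, never estimated: each valid pixel of the reference
depth map (cyclopic for the symmetric maps, left for warp validation) is
back-projected to its 3-D point and re-projected into both eyes; the
difference of the two pixel positions is the vector disparity
d = (x_R − x_L, y_R − y_L) in pixels.  Points landing at or behind a
camera centre are flagged invalid.  Mirrored maps mirror the reference
depth map (and validity) about the middle vertical line (column
j → W−1−j, an involution for any width) before the same computation.

**Occlusions** are found by forward splatting: each pixel maps to
p + d(p), targets are binned on the integer grid (≈0.5 px radius), and
within a bin the largest crossed disparity (nearest surface) wins; a
pixel beaten by more than 0.05 px is occluded.  The map depends only on
geometry, not texture.  **Depth edges** are pixels whose disparity vector
differs from an 8-neighbour's by more than 1 px in Euclidean norm
(threshold and neighbourhood are package choices; comparisons against
background pixels are ignored so the silhouette-against-nothing boundary
is not an edge).  Occlusions are computed on the left-referenced map for
validation and on the cyclopic map for dataset export.

## Fixation protocol

Head vantage points orbit the scene centre at a configurable distance
(default 1,550 mm) over azimuths {−60, −30, 0, 30, 60}° × elevations
{30, 45}°, nose through the centre (the head's Fick elevation is the
negative of the orbit elevation — it looks down at the table).  From each
vantage point a grid of 9×15 tile-centre image points of the cyclopic
camera is cast onto the scene; each hit becomes a fixation, each fixation
is emitted plain and mirrored.  Grid columns map to gaze azimuth index
#h ∈ −7..7 and rows to gaze elevation #v ∈ −4..4 with +v up; emission
order is (scene, vantage, #v, #h, mirror) and the whole enumeration is
deterministic.  Rays that miss geometry are skipped with a log message —
synthetic scenes, unlike the scanned worlds, do not fill the field of
view.  The mm depth range observed while writing a dataset is checked
softly (logged, never fatal) against the protocol's nominal ≈500–2,200 mm.

The on-disk layout is one folder per vantage (`K_HP_-2_1`), files named
`<dataname>_HP_#a_#e_H_#h_V_#v.*`; images as 8-bit PNG, depth as 16-bit
PNG with a linear mm normalisation recorded in the info file (code 0
reserved for background; quantisation error < 0.02 mm over the working
range), disparity as raw little-endian float32, masks as 1-bit PNG, and
a line-oriented `key: values` info TXT (permissive parser, unknown keys
preserved).  Mirrored twins add only their mirrored cyclopic disparity
binaries (`mircycdispx/y`) — the images are unchanged by construction, so
they are not duplicated.

## Warp-based validation

The right gray image (Rec. 601 luma) is sampled with bilinear
interpolation at p + d(p) to reconstruct the left image.  Samples whose
2×2 interpolation support leaves the image or touches a background pixel
of the right view are invalid and excluded from every region.  Scores:

- **MAE** — mean absolute gray-level difference over the mask;
- **NCC** — global 2-D Pearson correlation over the mask (the global
  form was chosen; a windowed variant would be a different statistic);
- **SSIM** — standard constants K1 = 0.01, K2 = 0.03, dynamic range 255,
  11×11 Gaussian window σ = 1.5, averaged over window centres whose full
  window lies inside the mask.  Thin masks (occlusion bands) may fit no
  window; SSIM is then NaN and batch aggregation ignores it.

Regions: ORIG (valid mask, scored on the unwarped pair), WARP (same mask,
warped pair), NO-OCC (minus occlusions), NO-DE (minus occlusions and
depth edges) and OCC (only occlusions/edges).  Before subtraction the
excluded occlusion/edge set is dilated by a one-pixel guard ring: the
bilinear warp reads a 2×2 neighbourhood, so reconstruction artefacts
extend one pixel beyond the marked discontinuity, and scoring that ring
as "clean" would contaminate NO-DE with edge error (diagnostically, the
ring shows 3–5× the interior residual).  `guard_px=0` restores the
strict set difference; with any setting NO-DE and OCC partition ORIG.
Batch reports aggregate median, quartiles and range per index and region.

## Synthetic scenes

The generator emulates the cluttered tabletop worlds the protocol was
designed for: a textured table plane at y = 0 spanning 1 m × 1 m and
(default) 8 primitives — boxes, spheres, cylinders, cones, 80–350 mm in
size — placed by seeded rejection sampling so bounding boxes never
overlap and everything stays inside the workspace footprint.  Textures
are procedural and deliberately band-limited (smooth fractal value noise,
sinusoidal gratings, Gaussian-blurred checkers) to emulate the smoothness
of photographic object texture at the working resolution; point-sampled
rendering of texture with energy at the pixel scale would alias
view-dependently and contaminate the warp residual with an error source
the mimicked acquisition does not have.  Identical seeds give
bit-identical scenes.

What the synthetic scenes do **not** emulate: scanner noise and
registration error, photometric left/right differences (the two views
sample the same baked radiance), specularity and lighting variation,
texture richness of real scenes, and VRML-scale mesh density.  Passing
the warp thresholds here therefore certifies the geometry, the renderer
and the ground-truth derivation — not robustness to acquisition
artefacts.

## Problem sizes and numerical choices

- Warp-validation batches use 24 fixations at 480×270 (three head
  vantage points, every 9th grid hit), a size at which the batch medians
  are stable across generator seeds while the whole computation stays in
  the tens of seconds on one CPU.
- Geometry property checks draw 10⁴ random configurations; rotation
  orthonormality is enforced to 1e-12, axis-through-fixation to 1e-9
  (measured via the cross-product norm — arccos of a near-unit dot
  product is numerically meaningless at that scale).
- Ray-cast tie-break: lowest triangle index within a 1e-6 mm window;
  Möller–Trumbore determinant cutoff 1e-12; self-intersection guard
  t_min = 1e-6 mm.
- Occlusion splat: 0.5 px bin radius, 0.05 px z-test tie tolerance.
- Depth-PNG normalisation is per-map (min/max of the finite depths);
  constant maps get a unit span so decoding is exact.

## Known limitations

- The renderer is CPU-only and unshaded; no anti-aliasing by design.
- Occlusion detection is disparity-based (as in the mimicked pipeline),
  so sub-pixel occlusion boundaries are resolved only to the splat grid;
  against a ray-cast visibility oracle agreement is ≥99% with the
  disagreement confined to band borders.
- The info-file grammar is this package's own; a mapping table
  (`dataset_io.KEY_ALIASES`) is the hook for aligning it with an external
  archive's spelling.
- `parallel_axes_state` models the off-axis comparison geometry only; it
  has no fixation point and exists for the d_y ≡ 0 contrast.
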