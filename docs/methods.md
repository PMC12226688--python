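# Methods

## Feature space

An object is described by ten user-facing dimensions in three salience
groups: primary (body shape, body color, body pattern), secondary (head
shape, head color, head pattern), and minor accessory parts (arm, ear, beak,
fractal emblem), the accessories optional. Accessory dimensions are
composite: an arm has an angle (bent up / bent down / straight), a length
class (short 0.7×, regular 1.0×, long 1.3× the base length), and a tip
(pointy / blunt / flat); ears and beak carry analogous attributes, the
fractal an identity (seed), size, and placement. Arms and ears exist per
side. `catalogue.dimension()` resolves both dimension names ("arm") and
attribute names ("arm_angle").

For similarity scoring this vocabulary expands to **24 scored
sub-dimensions**: the six body/head dimensions map one-to-one, and each
accessory contributes one sub-dimension per attribute and per side (6 arm,
6 ear, 3 beak, 3 fractal). Weights are 2.0 (body shape), 1.5 (body color,
body pattern), 0.75 (each head dimension), and 0.25 (each accessory
sub-dimension), summing to the documented score maximum of 11.75. The
coarser alternative — one weight per user-facing dimension — cannot reach
that maximum (it sums to 8.25) and makes a pairwise floor of 8 infeasible
for non-identical accessory configurations, so the per-instance,
per-attribute expansion is used.

Scoring conventions: values match on exact equality; a part absent from both
objects matches in every one of its sub-dimensions (identical objects must
reach the maximum regardless of part presence); a part absent from exactly
one object mismatches in all of them.

## Object tables

Specs serialize as UTF-8 TSV with a header row, one column per scored
sub-dimension plus `object_id`, the sentinel `none` for absent parts, and
`#` comment lines. Parsing accepts any subset of known columns (shorthand
attribute columns such as `arm_angle` apply to both sides; missing optional
parts default to `none`, missing required dimensions to their first
catalogue value) and rejects unknown columns or values with the offending
row and dimension named. `parse(write(specs))` is an exact identity.

## Randomness

All stochastic operations use numpy's PCG64 generators seeded through
`SeedSequence((master_seed, object_index))`, so per-object streams are
independent of batch order and every output is a pure function of its seed.

## Constrained set sampling

`generate_set` supports a pairwise floor (`min_pairwise`) or ceiling
(`max_pairwise`).

* **High-similarity mode** clones a random seed object and perturbs only
  sub-dimensions within a per-object mutation budget of (Sₘₐₓ − s)/2 score
  units, spent lowest-weight-first; any two set members then differ from the
  clone parent by at most that budget each, so every pairwise score is at
  least s by construction. Candidates are re-checked and resampled until
  distinct.
* **Low-similarity mode** draws random objects and repairs violations by
  resampling one matching sub-dimension of the worst pair at a time, chosen
  with probability proportional to its weight. A purely greedy choice
  (always the heaviest matching sub-dimension) can deadlock when a heavy
  dimension's few values are exhausted across the set; the weighted random
  draw avoids this.

Both modes re-verify the finished set against an independently computed
pairwise matrix and raise an explicit infeasibility error after 10,000
candidate mutations per object rather than returning a near-miss. Floors
and ceilings are evaluated as ≥ / ≤; with the 0.25 score granularity a
strict "> 8" and "≥ 8" differ only at exactly 8.0.

`design_sequence_stimuli` composes a sequence-learning stimulus set: five
mutually dissimilar objects (pairwise ≤ 3.0 by default, configurable) plus a
distractor built by cloning the object at the designated serial position
(2 or 4) and perturbing 6–18 accessory sub-dimensions, accepted only when
its similarity to the target strictly exceeds its similarity to every other
sequence object.

## Textures

Colors live in CIE LCh. The neutral default is achromatic (L\* = 60,
c\* = 0); the hue wheel fixes L\* = 60, c\* = 40 with 30° steps (the color
design fixes only constant L\*/c\* and the 30° hue separation; these
particular values were chosen to keep most of the wheel inside the sRGB
gamut). Conversion goes LCh → Lab → XYZ (D65) → gamma-encoded sRGB with
out-of-gamut channels clipped; at L\* 60 / c\* 40 the 210° and 240° hues clip
slightly.

Patterns are hard-edged (no anti-aliasing, so band geometry is testable):
alternating 150-px bands of neutral gray and the secondary color on a
1200 × 1200 canvas; diagonal runs at 45°, grid is the union of the
horizontal and vertical secondary bands. Fractal emblems stack 6 filled
polygons (12–48 vertices total each, radii 10–45% of the canvas, seeded
RGBA colors), drawn back-to-front by size; every polygon is point-symmetric
about the canvas center, and exact 180° pixel invariance is enforced by
rendering the top half-plane and rotating it onto the bottom. Body textures
composite the fractal over the pattern through its alpha channel at the
body-center placement.

## Geometry

Right-handed coordinates, +z up, +y toward the viewer ("front"). Bodies are
lathe meshes: a superellipse cross-section (|x/r|ᵖ + |y/r|ᵖ = 1; p = 2
circle, p = 8 approximates a square for the cube body) swept along z with a
radius law that is linear in z (cylinder r_b = r_t, cone r_t = 0, inverted
cone r_b = 0) or a circular arc (sphere). Default resolution is 64 segments
× 32 rings (appendages use one third of each, minimum 8 × 4); collapsed
rings become single apex vertices so no zero-area triangles occur at default
resolution. Appendages are tubes swept along a circular-arc centerline
(straight = 0°, up/down = ±45°) with the tip cap — tapered cone, hemisphere,
or disc — contained within the requested length; mirroring the bend sign
mirrors the mesh in z exactly.

Assembly places the body at the origin (height 1, half-width 0.5), a head of
half the body's width on the top axis overlapping 10% of its height (to hide
the seam — attachment geometry is a reconstruction), arms at mid-height on
±x, ears on the head top at ±x, and the beak on the head front (+y). Parts
are separate labeled sub-meshes; the assembled mesh is not watertight at
junctions.

Morphing extracts a continuous parameter set per object (body profile radii
and exponent, per-part bend angle / length scale / tip sharpness, color hue
and chroma, stripe angle) and interpolates linearly; categorical leftovers
switch from the first to the second object at t = 0.5, and t = 0 / t = 1
reproduce the inputs exactly. The midpoint of cone → inverted cone is the
equal-radius cylinder profile. Continuous tip sharpness realizes as flat
below 0, hemispheric in the middle, pointed from 0.75 up.

Normalization centers the bounding box at the origin and scales the largest
extent to 2.0 model units; it is idempotent to floating-point precision.
The planar UV projection maps u = (x+1)/2, v = (z+1)/2 independent of y, so
front/back mirrored vertices share UVs and patterns apply symmetrically.

## Rendering and export

The preview renderer is an orthographic z-buffer rasterizer looking along
−y, with auto-framing (bounding sphere scaled to 0.8 of the frame by
default) so pre-normalization size never affects apparent size. Shading is
two-sided Lambertian — intensity = 0.25 + 0.75·max(0, n·l) with the fixed
light (−1, −1, 2)/√6 — with per-pixel nearest-neighbor texture lookup
through the UVs. Rendering is a pure function of its inputs; repeated runs
are byte-identical.

OBJ export writes v/vt/f records (1-based, faces grouped per part with one
material each) plus an MTL and per-part texture PNGs. glTF 2.0 export emits
a single JSON asset with data-URI buffers and embedded PNG textures, one
primitive per part, accessor min/max recomputed from the data, and axis
conversion to the format's +y-up convention. FBX is deliberately not
supported (closed binary format); OBJ and glTF cover interchange.

## Validation study

`similarity_vs_ssim_study` renders random objects, samples distinct pairs,
and regresses image similarity on the normalized score S/Σw. SSIM follows
the standard windowed formulation (11-tap Gaussian, σ = 1.5, K₁ = 0.01,
K₂ = 0.03, dynamic range 255, population statistics, mean over fully
interior windows). Because the color design holds lightness constant, a
grayscale reduction is nearly blind to hue and pattern differences; SSIM
therefore averages per-channel values over R, G, B by default
(`channels="gray"` is available). Any callable `metric(img_a, img_b)` can
replace SSIM, e.g. an embedding similarity. The regression is closed-form
OLS with r² the squared Pearson correlation.

Study defaults are desk-scale: 24 × 12 mesh resolution, 300-px textures with
75-px bands, 128-px previews. At 50 objects / 500 pairs the score–SSIM
correlation is reliably positive but weak (r² ≈ 0.1) — the score counts
shared features with salience weights, while SSIM sees silhouette and local
contrast, so only moderate agreement is expected. Exact regression
coefficients depend on the renderer and the random object sample and are not
a reproduction target.

## What the generator does and does not emulate

Synthetic objects cover the full preconfigured feature vocabulary with
uniform independent draws per active dimension, which is how stimulus sets
are sampled in practice. The preview renderer uses flat Lambertian shading
without shadows, gloss, or perspective, so preview images are not
pixel-comparable to images from a full 3D content pipeline; conclusions
drawn from the study harness concern the score's relationship to image
structure under this renderer, not any particular production renderer.

## Known limitations

* Meshes are not watertight across part junctions (parts are separate
  labeled sub-meshes); per-part lathe bodies are individually watertight.
* Exact body "molding" math, head proportions, and attachment coordinates
  are reconstructions; other implementations may differ in proportions.
* Out-of-gamut hues (210°, 240° at the default L\*/c\*) clip in sRGB, so
  their realized chroma is slightly reduced.
* The high-similarity sampler's per-object budget is conservative (it
  guarantees the floor pairwise via the triangle construction), so it never
  emits pairs just at the floor unless the budget allows exactly that.
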