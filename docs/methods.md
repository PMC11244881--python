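# Methods

## The measurement model

`invquant` quantifies how far cells invade from a multicellular spheroid
into a surrounding 3D matrix, working entirely at the pixel level of
binarized nuclear images. The assay images the same spheroid twice: at
embedding (Day 0) and after a culture period (Day 2). The package never
segments individual nuclei — clustered nuclei inside the spheroid bulk
cannot be split reliably — and instead treats every foreground pixel as
an equal-area sample `dA` of nuclear material.

The chain of operations per spheroid:

1. **Binarization.** Grayscale maximum z-projections are normalized to
   [0, 1] and thresholded globally (default threshold 0.16; foreground is
   strictly `intensity > threshold`). Optional background subtraction
   (morphological white top-hat, default radius 50 px) and contrast
   stretching (1st–99th percentile linear stretch) are off by default:
   both are stand-ins for unspecified vendor preprocessing, and applying
   them by default would silently change the effective threshold.
2. **Field-of-view masking.** An inscribed circular mask (pixel centre
   within `min(H, W)/2` of the image centre `((H−1)/2, (W−1)/2)`)
   removes the frame corners and long-axis overhang, which would
   otherwise admit more invasion area along those directions.
3. **Artifact correction.** Interactive clean-up is replaced by an
   optional per-spheroid *keep mask* file (`<id>_mask.png`), ANDed with
   both images: reproducible and scriptable where a GUI is not.
4. **Boundary segmentation.** The largest 8-connected Day-0 component
   (ties broken by top-left bounding-box corner) is taken as the
   spheroid; interior holes are filled so the boundary is the outer
   envelope; marching squares at the 0.5 level gives a sub-pixel closed
   contour, stable against pixelation direction.
5. **Registration.** The Day-0 boundary is translated so its centroid
   coincides with the centroid of the *largest Day-2 component* (the
   spheroid core, holes filled). Using the core rather than all Day-2
   pixels matters: invading cells are spatially asymmetric and would
   bias a whole-image centroid. Registration is translation-only; the
   assay has no meaningful inter-timepoint rotation.
6. **Outer pixels and distances.** Outer pixels are Day-2 foreground
   pixels whose centres lie strictly outside the registered polygon
   (centres exactly on the ring count as inside — they belong to the
   initial footprint). For each outer pixel p the ray from the spheroid
   centroid through p is intersected exactly with the polygon edges; the
   crossing (xb, yb) defines

       d = sqrt((xp − xb)² + (yp − yb)²) · pixel_size        [mm]
       θ = atan2(yp − y0, xp − x0) mod 360°

   With y pointing down (image convention) θ sweeps clockwise on
   screen. Non-convex boundaries can cross a ray several times; the
   outermost crossing at radius ≤ the pixel's radius is used, which
   guarantees d ≥ 0 and measures from the locally outermost spheroid
   edge.
7. **Summary metrics.**

       ΔA  = (N_day2 − N_day0) · dA                          [mm²]
       D̄   = mean(d),  D_max = max(d)                        [mm]
       Ir  = Σ_i d_i² · dA                                   [mm⁴]

   `Ir`, the radial area moment of inertia, is the integrative
   invasiveness metric: like the second moment of area in beam
   mechanics it weights area by the square of its distance from the
   reference boundary, so sparse far invasion and dense near invasion
   are placed on one scale. ΔA may be negative (spheroid compaction);
   it is reported as-is with a shrinkage flag, never clamped.
8. **Directionality.** PCA of the unweighted outer-pixel coordinates
   (equal-area samples, so this is area-weighted PCA of the invasion
   pattern) gives principal axes; coordinates are rotated onto them
   (about the cloud mean by default; the spheroid centroid is available
   via `pca_origin: centroid`) and

       I_x′ = Σ y′² dA ,  I_y′ = Σ x′² dA                    [mm⁴]
       mean |x′| , mean |y′|                                 [mm]

   are reported along with the max/min fold changes of both pairs
   (≥ 1 by construction; ≈ 1 means isotropic invasion). Principal
   angles are reported modulo 180° (axes are undirected). Clouds whose
   eigenvalue gap is below 1e-9 relative are flagged isotropic and
   assigned angle 0. PCA is run on pixel coordinates, not on (d, θ)
   values: it is the coordinate rotation that the directional moments
   consume, and it reproduces the rotate-axes behaviour exactly.

## Numerical choices

* **Ray casting.** Exact segment–segment intersection over all polygon
  edges, accelerated by bucketing edges into the angular intervals they
  subtend at the centroid (a segment not through the centre subtends
  < π, so the short arc between endpoint angles is the bucket range).
  Tolerances: edge parameter `s ∈ [−1e−9, 1+1e−9]` (duplicate hits at
  shared vertices are harmless because the maximum-radius crossing is
  taken), ray parameter `t ∈ (1e−9, 1+1e−9]`. Pixels missed by the
  bucketed pass (degenerate geometry) fall back to a full edge sweep.
* **Threshold comparison** is strict (`>`); an inclusive rule would
  differ only on measure-zero intensity ties.
* **Connectivity** is 8-connected for foreground components, the
  standard for binary biological images.
* **No sub-pixel area weighting** at the cloud's inner edge: distances
  are per pixel centre. The discretization error this induces falls off
  with resolution (verified: the annulus pipeline error decreases from
  20 → 10 → 5 μm/px and is < 1% at 5 μm/px).
* **Outlier handling.** The scaled-MAD rule (1.4826 · MAD, remove
  beyond k = 3) only *flags* rows in the consolidated table; a
  `--drop-outliers` switch removes them explicitly. Silent deletion
  would harm auditability, and downstream group statistics are out of
  scope here.
* **Determinism.** Every stochastic generator takes an explicit seed;
  batch runs with a fixed config are byte-identical across reruns.

## Synthetic phantoms and what they do (not) show

The `synthetic` module generates image pairs with analytically known
metrics; the expected values are computed from closed forms (verified
independently against numerical quadrature in the tests), never by the
measurement pipeline itself.

* **Annulus pair** — disk R0 → disk R1: a perfectly uniform, isotropic
  invasion front. With W = R1 − R0:
  ΔA = π(R1² − R0²), D̄ = 2(W³/3 + R0W²/2)/(R1² − R0²),
  Ir = 2π(W⁴/4 + R0W³/3). The benchmark configuration R0 = 1 mm,
  R1 = 2 mm at 10 μm/px (≈ 94 000 outer pixels) gives ΔA = 3π ≈
  9.4248 mm², D̄ = 5/9 ≈ 0.5556 mm, Ir = 7π/6 ≈ 3.6652 mm⁴, and the
  pipeline reproduces all three within a fraction of a percent.
* **Anisotropic pair** — disk R0 plus n single-pixel "nuclei" from a
  rotated bivariate Gaussian (σ_major, σ_major/axis_ratio), rejected
  inside the disk. Single-pixel nuclei make the PCA truth exact; a blob
  variant (disk nuclei, radius 3 px) exercises realistic clustering.
  The directionality benchmark uses R0 = 0.2 mm, σ_major = 0.5 mm, axis
  ratio 2.5, n = 2000 at 10 μm/px over 20 seeds — enough points that
  orientation recovery is limited by sampling, not by the pipeline.
* **Grayscale renderer** — two-level image (fg 0.8, bg 0.05) plus
  clipped Gaussian noise, for the binarization front end.

These phantoms validate the *measurement chain*: geometry, integration,
registration, directionality. They do not emulate optical blur, uneven
staining, z-projection artifacts, touching spheroids or debris, so
passing tests say nothing about segmentation quality on real
micrographs — there the global threshold and the correction mask remain
the user's responsibility.

## Problem sizes

The default validation suite runs the annulus benchmark at 10 μm/px
(424² px, ~94k outer pixels), three 720-vertex star boundaries with
500–700 probe pixels each against a 10⁴-point dense-sampled oracle, and
twenty 2000-point anisotropic clouds; the full suite completes in well
under a minute on one core. Higher resolutions sharpen the agreement
with the closed forms (see the convergence test) at quadratic cost in
pixel count.

## Known limitations

* Invasion is measured from the Day-0 boundary, so distance travelled by
  cells that started deep inside the spheroid is underestimated.
* Maximum projections collapse z: all metrics are 2D projections of a
  3D process.
* Centroid-only registration cannot correct rotation or drift-induced
  shear between timepoints.
* The distance from a pixel to the boundary is measured along the
  centroid ray, not the true nearest boundary point; for strongly
  non-convex Day-0 shapes the two can differ.
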