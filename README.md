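# invquant

Pixel-based quantification of multicellular spheroid invasion into 3D
matrices.

Spheroids embedded in a hydrogel (collagen, Matrigel, ...) are a standard
in vitro model of 3D cell invasion in wound healing, tumour metastasis
and scaffold repopulation studies. Quantifying that invasion is usually
done by tracing cell boundaries by hand or by segmenting individual
cells — both fail when nuclei are tightly clustered in the spheroid
bulk. `invquant` instead works on the *pixels* of binarized nuclear
images (e.g. maximum z-projections of Hoechst staining): it segments the
initial (Day-0) spheroid boundary, overlays it onto the final (Day-2)
image by centroid registration, and measures every foreground pixel that
lies beyond it.

For each spheroid, with dA the physical pixel area and d the distance
from an outer pixel to the Day-0 boundary along the ray from the
spheroid centroid:

* **Area change** ΔA = Area(Day 2) − Area(Day 0) — a proxy for the
  amount of invaded cell material;
* **Mean / max invasion distance** D̄ = mean(d), D_max = max(d);
* **Radial area moment of inertia** Ir = Σᵢ dᵢ² dA — an integrative
  invasiveness metric that, like the second moment of area in
  mechanics, weights area by the square of its distance from the
  reference boundary;
* **Directional metrics** — PCA of the outer-pixel cloud gives the axes
  of maximum/minimum invasion; directional moments I_x′ = Σ y′² dA,
  I_y′ = Σ x′² dA and directional mean distances mean|x′|, mean|y′| are
  computed in the rotated frame, and their max/min fold changes (≥ 1)
  quantify how anisotropic the invasion is (≈ 1: isotropic; e.g. a
  spheroid invading toward a stiff post via contact guidance shows
  fold changes well above 1).

A synthetic-phantom module generates image pairs (annular invasion
shells, anisotropic point clouds, noisy grayscale renders) with
analytically known metrics, so the whole pipeline is testable without
any microscope data.

## Worked example

Quantify a synthetic annular invasion (Day-0 disk of radius 1 mm,
Day-2 disk of radius 2 mm, imaged at 10 μm/px):

```python
from invquant import make_annulus_pair, process_images

day0, day2, truth = make_annulus_pair(r0_mm=1.0, r1_mm=2.0, pixel_size_um=10.0)
record, pixels = process_images(day0, day2, spheroid_id="demo")
print(f"dA   = {record['delta_area_mm2']:.4f} mm^2")
print(f"mean = {record['mean_distance_mm']:.4f} mm")
print(f"Ir   = {record['radial_moment_mm4']:.4f} mm^4")
print(f"fold = {record['fold_change_moment']:.3f}")
```

prints

```
dA   = 9.4248 mm^2
mean = 0.5555 mm
Ir   = 3.6645 mm^4
fold = 1.000
```

matching the closed forms ΔA = 3π ≈ 9.4248 mm², D̄ = 5/9 ≈ 0.5556 mm,
Ir = 7π/6 ≈ 3.6652 mm⁴ for the annulus, with fold change 1 (isotropic),
to within pixel discretization. `pixels` is a per-pixel table
(x, y, d, θ) ready for polar plotting.

From the shell, the same pipeline runs over folders of paired images
(`<id>_d0.png` / `<id>_d2.png`, also `_day0`/`_day2`, TIFF or PNG):

```sh
invquant binarize -i raw/ -o binarized/ --threshold 0.16 --pixel-size-um 0.7548
invquant quantify -i binarized/ -o results/ --pixel-size-um 0.7548
invquant consolidate results/metrics.csv -o all_spheroids.csv
invquant simulate --preset annulus --out phantom/
```

`quantify` writes `metrics.csv` and `directionality.csv` (one row per
spheroid, with scaled-MAD outlier flags), `pixels/<id>.csv`, a run log
and a JSON manifest. Failures on single images are recorded per row and
do not abort the batch.

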