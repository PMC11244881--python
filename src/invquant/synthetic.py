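"""Synthetic spheroid image pairs with analytically known invasion metrics.

These generators stand in for real nuclear image pairs: geometric
phantoms whose invasion metrics have closed forms, so the whole pipeline
can be validated without any microscope data.

* An *annulus pair* (disk R0 at Day 0, disk R1 > R0 at Day 2) models a
  perfectly uniform radial invasion front. With W = R1 - R0:

      delta A = pi (R1^2 - R0^2)
      mean d  = 2 (W^3/3 + R0 W^2/2) / (R1^2 - R0^2)
      Ir      = 2 pi (W^4/4 + R0 W^3/3)

  and the invasion is isotropic (directional fold changes ~ 1).
* An *anisotropic pair* (disk R0 plus point "nuclei" drawn from a rotated
  bivariate Gaussian, rejected inside the disk) models directional
  invasion toward a guidance cue; the generating orientation and axis
  ratio are the ground truth for the PCA analysis.
* A grayscale renderer turns any binary phantom into a noisy grayscale
  image to exercise the binarization front end.

Expected values are computed here from closed forms only — independent of
the measurement pipeline — so they serve as genuine oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .imaging_io import BinaryImage, GrayImage


@dataclass
class SyntheticTruth:
    """Generator parameters plus the analytically expected metrics."""

    generator: str
    parameters: dict
    expected: dict
    tolerances: dict = field(default_factory=dict)


def _disk_mask(shape: tuple[int, int], center_xy: tuple[float, float], radius_px: float) -> np.ndarray:
    h, w = shape
    yy, xx = np.ogrid[:h, :w]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius_px**2


def annulus_truth(r0_mm: float, r1_mm: float) -> dict:
    """Closed-form metrics for a uniform annular invasion shell."""
    w = r1_mm - r0_mm
    area = np.pi * (r1_mm**2 - r0_mm**2)
    return {
        "delta_area_mm2": area,
        "mean_distance_mm": 2.0 * (w**3 / 3.0 + r0_mm * w**2 / 2.0) / (r1_mm**2 - r0_mm**2),
        "max_distance_mm": w,
        "radial_moment_mm4": 2.0 * np.pi * (w**4 / 4.0 + r0_mm * w**3 / 3.0),
        "fold_change_moment": 1.0,
        "fold_change_distance": 1.0,
    }


def make_annulus_pair(
    r0_mm: float,
    r1_mm: float,
    pixel_size_um: float,
    image_size_px: int | None = None,
) -> tuple[BinaryImage, BinaryImage, SyntheticTruth]:
    """Disk R0 at Day 0, disk R1 at Day 2, both centred in the frame.

    The frame defaults to the smallest even size that keeps the Day-2
    disk inside the inscribed circular field of view with a 4% margin.
    """
    if not 0 < r0_mm < r1_mm:
        raise ValidationError("need 0 < R0 < R1")
    scale = pixel_size_um / 1000.0  # mm per px
    r0_px, r1_px = r0_mm / scale, r1_mm / scale
    if image_size_px is None:
        image_size_px = 2 * int(np.ceil(r1_px * 1.04)) + 8
    if image_size_px < 2 * r1_px:
        raise ValidationError(
            f"frame of {image_size_px} px cannot contain the Day-2 disk "
            f"({2 * r1_px:.0f} px across)"
        )
    c = ((image_size_px - 1) / 2.0, (image_size_px - 1) / 2.0)
    shape = (image_size_px, image_size_px)
    day0 = BinaryImage(_disk_mask(shape, c, r0_px), pixel_size_um, "Day0")
    day2 = BinaryImage(_disk_mask(shape, c, r1_px), pixel_size_um, "Day2")
    truth = SyntheticTruth(
        generator="annulus",
        parameters={
            "R0_mm": r0_mm,
            "R1_mm": r1_mm,
            "pixel_size_um": pixel_size_um,
            "image_size_px": image_size_px,
        },
        expected=annulus_truth(r0_mm, r1_mm),
        tolerances={
            "delta_area_mm2": 0.01,
            "mean_distance_mm": 0.02,
            "radial_moment_mm4": 0.02,
        },
    )
    return day0, day2, truth


def make_anisotropic_pair(
    r0_mm: float,
    sigma_major_mm: float,
    axis_ratio: float,
    orientation_deg: float,
    n_points: int,
    pixel_size_um: float,
    seed: int = 0,
    image_size_px: int | None = None,
    nucleus_radius_px: int = 0,
) -> tuple[BinaryImage, BinaryImage, SyntheticTruth]:
    """Disk R0 plus anisotropic Gaussian point "nuclei" outside the disk.

    Points are sampled from a bivariate Gaussian with standard deviations
    (sigma_major, sigma_major/axis_ratio) rotated to ``orientation_deg``
    (image convention: y down, angles clockwise on screen), rejection-
    sampled to lie outside the Day-0 disk and inside the frame. With
    ``nucleus_radius_px`` > 0 each point becomes a small disk, mimicking
    clustered real nuclei at the cost of exact point-mass PCA truth.
    """
    if axis_ratio < 1:
        raise ValidationError("axis_ratio must be >= 1")
    if n_points < 0:
        raise ValidationError("n_points must be >= 0")
    scale = pixel_size_um / 1000.0
    r0_px = r0_mm / scale
    sig_major_px = sigma_major_mm / scale
    if image_size_px is None:
        image_size_px = 2 * int(np.ceil(r0_px + 4.2 * sig_major_px)) + 8
    c = np.array([(image_size_px - 1) / 2.0] * 2)
    shape = (image_size_px, image_size_px)
    day0_mask = _disk_mask(shape, tuple(c), r0_px)

    rng = np.random.default_rng(seed)
    theta = np.radians(orientation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    sig = np.array([sig_major_px, sig_major_px / axis_ratio])
    accepted: list[np.ndarray] = []
    n_have = 0
    while n_have < n_points:
        batch = max(1024, 2 * (n_points - n_have))
        raw = rng.standard_normal((batch, 2)) * sig
        pts = raw @ rot.T + c
        r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        ok = (
            (r > r0_px)
            & (pts[:, 0] >= 0)
            & (pts[:, 0] <= image_size_px - 1)
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= image_size_px - 1)
        )
        take = pts[ok][: n_points - n_have]
        accepted.append(take)
        n_have += len(take)
    day2_mask = day0_mask.copy()
    if n_points:
        pts = np.vstack(accepted)
        cols = np.clip(np.round(pts[:, 0]).astype(int), 0, image_size_px - 1)
        rows = np.clip(np.round(pts[:, 1]).astype(int), 0, image_size_px - 1)
        day2_mask[rows, cols] = True
        if nucleus_radius_px > 0:
            yy, xx = np.ogrid[-nucleus_radius_px : nucleus_radius_px + 1,
                              -nucleus_radius_px : nucleus_radius_px + 1]
            stamp = xx**2 + yy**2 <= nucleus_radius_px**2
            sy, sx = np.nonzero(stamp)
            for r_, c_ in zip(rows, cols):
                rr = np.clip(r_ + sy - nucleus_radius_px, 0, image_size_px - 1)
                cc = np.clip(c_ + sx - nucleus_radius_px, 0, image_size_px - 1)
                day2_mask[rr, cc] = True

    day0 = BinaryImage(day0_mask, pixel_size_um, "Day0")
    day2 = BinaryImage(day2_mask, pixel_size_um, "Day2")
    truth = SyntheticTruth(
        generator="anisotropic",
        parameters={
            "R0_mm": r0_mm,
            "sigma_major_mm": sigma_major_mm,
            "axis_ratio": axis_ratio,
            "orientation_deg": orientation_deg,
            "n_points": n_points,
            "pixel_size_um": pixel_size_um,
            "seed": seed,
            "image_size_px": image_size_px,
            "nucleus_radius_px": nucleus_radius_px,
        },
        expected={
            "angle_max_deg": orientation_deg % 180.0,
            # for a pure Gaussian: var ratio = axis_ratio^2, mean-|coord|
            # ratio = axis_ratio; rejection inside R0 perturbs both
            "fold_change_moment_min": 1.0 if axis_ratio == 1 else axis_ratio,
            "fold_change_distance_min": 1.0,
            "isotropic": axis_ratio == 1,
        },
        tolerances={"angle_max_deg": 5.0},
    )
    return day0, day2, truth


def make_grayscale_from_binary(
    binary: BinaryImage,
    fg_level: float = 0.8,
    bg_level: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> GrayImage:
    """Render a binary phantom as a grayscale image with optional noise.

    Foreground pixels get ``fg_level``, background ``bg_level``, plus
    additive Gaussian noise clipped to [0, 1]. With ``noise_sd = 0`` any
    threshold strictly between the two levels recovers the mask exactly.
    """
    if not 0.0 <= bg_level < fg_level <= 1.0:
        raise ValidationError("need 0 <= bg_level < fg_level <= 1")
    img = np.where(binary.mask, fg_level, bg_level).astype(np.float64)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return GrayImage(np.clip(img, 0.0, 1.0))
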