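"""Directional invasion analysis via principal component analysis.

Invasion driven by a directional cue (a chemotactic gradient, contact
guidance toward a stiff post) is anisotropic: the outer-pixel cloud is
elongated along the cue direction. PCA of the unweighted outer-pixel
coordinates — pixels are equal-area samples, so this is area-weighted PCA
of the invasion pattern — gives the axes of maximum and minimum invasion.
Rotating the pixel coordinates onto those axes yields directional second
moments of area

    I_x' = sum_i y'_i^2 dA      (about the maximum-invasion axis)
    I_y' = sum_i x'_i^2 dA      (about the minimum-invasion axis)

and directional mean distances mean(|x'|), mean(|y'|). The ratio of the
maximum- to minimum-direction value (fold change, >= 1 by construction)
summarizes anisotropy: ~1 means isotropic invasion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .metrics import PixelCloud

#: relative eigenvalue gap below which the cloud is treated as isotropic
ISOTROPY_RTOL = 1e-9


@dataclass
class PrincipalAxes:
    """Principal axes of the outer-pixel cloud.

    Angles are reported modulo 180 degrees (axes are undirected), in the
    package's image convention (x right, y down; angles sweep clockwise
    on screen).
    """

    origin: tuple[float, float]  # (x-bar, y-bar) of the outer pixels, px
    angle_max_deg: float  # orientation of the maximum-variance axis, [0, 180)
    angle_min_deg: float  # angle_max + 90 (mod 180)
    eigenvalues: tuple[float, float]  # (var along max axis, var along min axis)
    isotropic: bool = False

    @property
    def angle_aliases_deg(self) -> tuple[float, float]:
        """The two axes as a +/- pair, e.g. 125 and -55 -> (125, -55)."""
        return (self.angle_max_deg, self.angle_max_deg - 180.0)


def principal_axes(
    cloud: PixelCloud | np.ndarray,
    origin: tuple[float, float] | None = None,
) -> PrincipalAxes:
    """Eigen-decomposition of the 2x2 covariance of outer-pixel coordinates.

    ``origin`` overrides the transform origin (e.g. the spheroid
    centroid); the covariance itself is always taken about the cloud
    mean. Equal eigenvalues (isotropic cloud) yield angle 0 with the
    ``isotropic`` flag set.
    """
    pts = cloud.points if isinstance(cloud, PixelCloud) else np.asarray(cloud, float)
    pts = pts.reshape(-1, 2)
    if len(pts) < 2:
        raise InsufficientDataError(
            f"PCA needs >= 2 outer pixels, got {len(pts)}"
        )
    mean = pts.mean(axis=0)
    x = pts - mean
    cov = (x.T @ x) / len(x)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    lam_min, lam_max = float(evals[0]), float(evals[1])
    if origin is None:
        origin = (float(mean[0]), float(mean[1]))
    if lam_max <= 0 or (lam_max - lam_min) <= ISOTROPY_RTOL * lam_max:
        return PrincipalAxes(
            origin=origin,
            angle_max_deg=0.0,
            angle_min_deg=90.0,
            eigenvalues=(lam_max, lam_min),
            isotropic=True,
        )
    v = evecs[:, 1]
    angle = float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
    return PrincipalAxes(
        origin=origin,
        angle_max_deg=angle,
        angle_min_deg=(angle + 90.0) % 180.0,
        eigenvalues=(lam_max, lam_min),
    )


def transform_coordinates(
    cloud: PixelCloud, axes: PrincipalAxes, angle_deg: float | None = None
) -> np.ndarray:
    """Rotate pixel coordinates onto the principal axes, in mm.

    Returns an (N, 2) array of (x', y'): x' along the maximum-invasion
    axis, y' along the minimum-invasion axis, both measured from the
    axes' origin. The map is a rigid rotation + translation, so pairwise
    distances are preserved. ``angle_deg`` overrides the rotation angle
    (used for moments about arbitrary axes, e.g. the image axes at 0).
    """
    theta = np.radians(axes.angle_max_deg if angle_deg is None else angle_deg)
    scale = cloud.pixel_size_um / 1000.0
    rel = (cloud.points - np.asarray(axes.origin)) * scale
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    xp = rel[:, 0] * cos_t + rel[:, 1] * sin_t
    yp = -rel[:, 0] * sin_t + rel[:, 1] * cos_t
    return np.column_stack([xp, yp])


def directional_moments(
    transformed_mm: np.ndarray, pixel_area_mm2: float
) -> tuple[float, float]:
    """Second moments of area about the rotated axes, (I_x', I_y') in mm^4.

    I_x' integrates the squared offsets *from* the x' axis (i.e. y'^2),
    and vice versa; with x' the maximum-invasion axis, I_y' >= I_x' for
    anisotropic invasion and I_max = max(I_x', I_y').
    """
    t = np.asarray(transformed_mm, dtype=np.float64).reshape(-1, 2)
    if len(t) == 0:
        return (0.0, 0.0)
    i_xp = float(np.sum(t[:, 1] ** 2) * pixel_area_mm2)
    i_yp = float(np.sum(t[:, 0] ** 2) * pixel_area_mm2)
    return (i_xp, i_yp)


def directional_mean_distances(transformed_mm: np.ndarray) -> tuple[float, float]:
    """Mean |x'| (max axis) and mean |y'| (min axis), in mm."""
    t = np.asarray(transformed_mm, dtype=np.float64).reshape(-1, 2)
    if len(t) == 0:
        return (0.0, 0.0)
    return (float(np.abs(t[:, 0]).mean()), float(np.abs(t[:, 1]).mean()))


def fold_change(
    moments: tuple[float, float], mean_distances: tuple[float, float]
) -> tuple[float, float]:
    """Max/min ratios for the moment pair and the mean-distance pair.

    Both ratios are >= 1 by construction; a zero minimum-direction value
    makes the ratio undefined.
    """
    folds = []
    for pair in (moments, mean_distances):
        lo, hi = sorted(pair)
        if lo <= 0:
            raise ValidationError("fold change undefined: minimum-direction value is 0")
        folds.append(hi / lo)
    return (folds[0], folds[1])


@dataclass
class DirectionalMetrics:
    """Per-spheroid directional invasion summary."""

    spheroid_id: str
    angle_max_deg: float
    angle_min_deg: float
    I_max_mm4: float
    I_min_mm4: float
    Ix_mm4: float  # moment about the image x-axis (identity rotation)
    Iy_mm4: float  # moment about the image y-axis
    mean_d_max_mm: float
    mean_d_min_mm: float
    fold_change_moment: float
    fold_change_distance: float
    isotropic: bool


def analyze_directionality(
    cloud: PixelCloud,
    spheroid_id: str = "",
    origin: tuple[float, float] | None = None,
) -> DirectionalMetrics:
    """Full directional analysis of an outer-pixel cloud.

    ``origin`` defaults to the cloud mean; pass the spheroid centroid to
    measure directional distances from the spheroid instead.
    """
    axes = principal_axes(cloud, origin=origin)
    t = transform_coordinates(cloud, axes)
    i_xp, i_yp = directional_moments(t, cloud.pixel_area_mm2)
    d_max, d_min = directional_mean_distances(t)
    # moments about the unrotated image axes, as standard outputs
    t0 = transform_coordinates(cloud, axes, angle_deg=0.0)
    ix, iy = directional_moments(t0, cloud.pixel_area_mm2)
    fold_m, fold_d = fold_change((i_xp, i_yp), (d_max, d_min))
    return DirectionalMetrics(
        spheroid_id=spheroid_id,
        angle_max_deg=axes.angle_max_deg,
        angle_min_deg=axes.angle_min_deg,
        I_max_mm4=max(i_xp, i_yp),
        I_min_mm4=min(i_xp, i_yp),
        Ix_mm4=ix,
        Iy_mm4=iy,
        mean_d_max_mm=d_max,
        mean_d_min_mm=d_min,
        fold_change_moment=fold_m,
        fold_change_distance=fold_d,
        isotropic=axes.isotropic,
    )
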