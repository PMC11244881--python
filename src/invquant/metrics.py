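"""Core invasion metrics.

All metrics are computed per pixel rather than per segmented object, which
sidesteps the impossibility of splitting tightly clustered nuclei inside
the spheroid bulk. Given the Day-2 binary image and the registered Day-0
boundary polygon:

* the *outer pixels* are Day-2 foreground pixels whose centres lie
  strictly outside the closed boundary (boundary-coincident centres count
  as inside — they belong to the initial footprint);
* each outer pixel's radial distance ``d`` is the Euclidean distance from
  the pixel centre (xp, yp) to the boundary crossing (xb, yb) of the ray
  from the spheroid centroid (x0, y0) through the pixel,
  ``d = sqrt((xp - xb)^2 + (yp - yb)^2)``;
* its angle is ``theta = atan2(yp - y0, xp - x0)`` mapped to [0, 360)
  (clockwise on screen, since y points down);
* the area change is ``dA_total = (N_day2 - N_day0) * dA`` with
  ``dA = pixel_area``;
* the radial area moment of inertia, the integrative invasiveness metric,
  is ``Ir = sum_i d_i^2 * dA`` — far-invading area is weighted by the
  square of its distance from the initial boundary, in analogy with the
  second moment of area in beam mechanics.

Distances are in mm, areas in mm^2, moments in mm^4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .boundary import BoundaryPolygon
from .errors import GeometryError, ValidationError
from .imaging_io import BinaryImage

_EPS = 1e-9


@dataclass
class PixelCloud:
    """Outer pixels of the Day-2 image with their radial measurements."""

    points: np.ndarray  # (N, 2) pixel-centre (x, y) coordinates
    distances_mm: np.ndarray  # per-pixel d (to boundary along the ray)
    angles_deg: np.ndarray  # per-pixel theta in [0, 360)
    pixel_area_mm2: float
    boundary_ref: BoundaryPolygon
    pixel_size_um: float
    centroid_distances_mm: np.ndarray = field(default=None)  # optional extra column

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        self.distances_mm = np.asarray(self.distances_mm, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if not (len(self.points) == len(self.distances_mm) == len(self.angles_deg)):
            raise ValidationError("points, distances and angles must align")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class InvasionMetrics:
    """Per-spheroid summary of the radially integrated invasion metrics."""

    spheroid_id: str
    delta_area_mm2: float
    mean_distance_mm: float
    max_distance_mm: float
    radial_moment_mm4: float
    n_outer_pixels: int
    shrinkage: bool = False  # Day-2 foreground smaller than Day-0


class _RayCaster:
    """Exact segment intersection of centroid->pixel rays with the polygon.

    Edges are bucketed by the angular interval they subtend at the
    centroid, so each pixel is only tested against the handful of edges
    that can cross its ray. An unbucketed full sweep is kept as a
    fallback for numerically marginal pixels.
    """

    def __init__(self, polygon: BoundaryPolygon):
        self.centroid = np.asarray(polygon.centroid, dtype=np.float64)
        v = polygon.vertices
        self.a = v
        self.d = np.roll(v, -1, axis=0) - v  # edge direction vectors
        rel = v - self.centroid
        ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        ang_b = np.roll(ang, -1)
        span = np.mod(ang_b - ang, 2 * np.pi)
        # a segment not through the centroid subtends < pi; take the short arc
        lo = np.where(span <= np.pi, ang, ang_b)
        width = np.where(span <= np.pi, span, 2 * np.pi - span)
        self.n_bins = int(min(4096, max(64, len(v))))
        bw = 2 * np.pi / self.n_bins
        self._bins: list[list[int]] = [[] for _ in range(self.n_bins)]
        first = np.floor(lo / bw).astype(int)
        count = np.floor((lo + width) / bw).astype(int) - first + 1
        for i in range(len(v)):
            for b in range(first[i], first[i] + count[i]):
                self._bins[b % self.n_bins].append(i)
        self._bin_edges = [np.array(b, dtype=int) for b in self._bins]

    def _intersect(
        self, pts: np.ndarray, edge_idx: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Best crossing parameter t in (0, 1] per point; NaN if none."""
        r = pts - self.centroid  # (m, 2) ray directions
        a = self.a[edge_idx]  # (k, 2)
        d = self.d[edge_idx]
        qa = a - self.centroid
        denom = r[:, 0, None] * d[None, :, 1] - r[:, 1, None] * d[None, :, 0]
        cross_qa_d = qa[:, 0] * d[:, 1] - qa[:, 1] * d[:, 0]  # (k,)
        cross_qa_r = qa[None, :, 0] * r[:, None, 1] - qa[None, :, 1] * r[:, None, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = cross_qa_d[None, :] / denom
            s = cross_qa_r / denom
        ok = (
            (np.abs(denom) > _EPS)
            & (s >= -_EPS)
            & (s <= 1 + _EPS)
            & (t > _EPS)
            & (t <= 1 + _EPS)
        )
        t = np.where(ok, t, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            best = np.nanmax(t, axis=1)
        return best, r

    def cast(self, pts: np.ndarray) -> np.ndarray:
        """Boundary crossing (xb, yb) for each outside point, (m, 2)."""
        pts = np.asarray(pts, dtype=np.float64).reshape(-1, 2)
        out = np.full_like(pts, np.nan)
        if len(pts) == 0:
            return out
        rel = pts - self.centroid
        phi = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
        bins = np.floor(phi / (2 * np.pi / self.n_bins)).astype(int) % self.n_bins
        order = np.argsort(bins, kind="stable")
        sorted_bins = bins[order]
        starts = np.searchsorted(sorted_bins, np.arange(self.n_bins), side="left")
        ends = np.searchsorted(sorted_bins, np.arange(self.n_bins), side="right")
        all_edges = np.arange(len(self.a))
        for b in range(self.n_bins):
            if starts[b] == ends[b]:
                continue
            idx = order[starts[b] : ends[b]]
            edges = self._bin_edges[b]
            if len(edges):
                best, r = self._intersect(pts[idx], edges)
            else:
                best = np.full(len(idx), np.nan)
                r = pts[idx] - self.centroid
            missed = np.isnan(best)
            if missed.any():  # fall back to the full edge sweep
                best2, _ = self._intersect(pts[idx[missed]], all_edges)
                best[missed] = best2
            out[idx] = self.centroid + best[:, None] * r
        if np.isnan(out).any():
            raise GeometryError(
                "ray from centroid found no boundary crossing; is the centroid "
                "inside the polygon?"
            )
        return out


def boundary_point_on_ray(
    boundary: BoundaryPolygon, pixel: tuple[float, float]
) -> tuple[float, float]:
    """Crossing (xb, yb) of the segment [centroid -> pixel] with the polygon.

    For non-convex boundaries with several crossings, the outermost one at
    radius <= the pixel's radius is returned, so ``d >= 0`` always holds
    and distance is measured from the locally outermost spheroid edge.
    """
    caster = _RayCaster(boundary)
    xb, yb = caster.cast(np.array([pixel], dtype=np.float64))[0]
    return (float(xb), float(yb))


def radial_distance(
    pixel: tuple[float, float], boundary_pt: tuple[float, float], pixel_size_um: float
) -> float:
    """Euclidean pixel-to-boundary distance, converted to mm."""
    dx = pixel[0] - boundary_pt[0]
    dy = pixel[1] - boundary_pt[1]
    return float(np.hypot(dx, dy)) * pixel_size_um / 1000.0


def pixel_angle(pixel: tuple[float, float], centroid: tuple[float, float]) -> float:
    """Angle of the pixel about the centroid, degrees in [0, 360).

    Two-argument arctangent of (yp - y0, xp - x0); with y pointing down,
    increasing angle sweeps clockwise on screen.
    """
    dx = pixel[0] - centroid[0]
    dy = pixel[1] - centroid[1]
    if dx == 0.0 and dy == 0.0:
        raise ValidationError("angle undefined: pixel coincides with centroid")
    return float(np.degrees(np.arctan2(dy, dx)) % 360.0)


def find_outer_pixels(
    day2: BinaryImage,
    boundary: BoundaryPolygon,
    centroid_tol_px: float | None = None,
) -> PixelCloud:
    """Day-2 foreground pixels strictly outside the registered boundary.

    Geometry only: distances and angles are left empty until
    :func:`compute_distances_angles` fills them. If ``centroid_tol_px``
    is given, the boundary centroid must lie within that distance of the
    Day-2 core centroid (registration sanity check).
    """
    if centroid_tol_px is not None:
        from .boundary import day2_centroid as _d2c

        cx, cy = _d2c(day2)
        off = np.hypot(boundary.centroid[0] - cx, boundary.centroid[1] - cy)
        if off > centroid_tol_px:
            raise ValidationError(
                f"boundary centroid is {off:.2f} px from the Day-2 core centroid "
                f"(tolerance {centroid_tol_px} px); register the boundary first"
            )
    rows, cols = np.nonzero(day2.mask)
    xs = cols.astype(np.float64)
    ys = rows.astype(np.float64)
    ring = np.vstack([boundary.vertices, boundary.vertices[:1]])
    poly = shapely.Polygon(ring)
    shapely.prepare(poly)
    touching = shapely.intersects_xy(poly, xs, ys)  # inside or on the ring
    outside = ~touching
    pts = np.column_stack([xs[outside], ys[outside]])
    return PixelCloud(
        points=pts,
        distances_mm=np.full(len(pts), np.nan),
        angles_deg=np.full(len(pts), np.nan),
        pixel_area_mm2=day2.pixel_area_mm2,
        boundary_ref=boundary,
        pixel_size_um=day2.pixel_size_um,
    )


def compute_distances_angles(cloud: PixelCloud) -> PixelCloud:
    """Fill per-pixel radial distances, angles and centroid distances."""
    scale = cloud.pixel_size_um / 1000.0
    c = np.asarray(cloud.boundary_ref.centroid)
    if len(cloud) == 0:
        cloud.centroid_distances_mm = np.zeros(0)
        return cloud
    crossings = _RayCaster(cloud.boundary_ref).cast(cloud.points)
    delta = cloud.points - crossings
    cloud.distances_mm = np.hypot(delta[:, 0], delta[:, 1]) * scale
    rel = cloud.points - c
    cloud.angles_deg = np.degrees(np.arctan2(rel[:, 1], rel[:, 0])) % 360.0
    cloud.centroid_distances_mm = np.hypot(rel[:, 0], rel[:, 1]) * scale
    return cloud


def build_pixel_cloud(
    day2: BinaryImage,
    boundary: BoundaryPolygon,
    centroid_tol_px: float | None = None,
) -> PixelCloud:
    """Outer-pixel extraction plus distance/angle computation in one step."""
    return compute_distances_angles(
        find_outer_pixels(day2, boundary, centroid_tol_px=centroid_tol_px)
    )


def area_change(day0: BinaryImage, day2: BinaryImage) -> float:
    """Foreground area difference (Day 2 - Day 0) in mm^2.

    Negative values (spheroid compaction) are returned as-is with a
    warning rather than clamped.
    """
    if not np.isclose(day0.pixel_size_um, day2.pixel_size_um):
        raise ValidationError(
            f"pixel size mismatch: {day0.pixel_size_um} vs {day2.pixel_size_um} um"
        )
    diff_px = day2.foreground_count - day0.foreground_count
    if diff_px < 0:
        warnings.warn(
            "Day-2 foreground is smaller than Day-0 (spheroid shrinkage); "
            "area change is negative",
            stacklevel=2,
        )
    return diff_px * day0.pixel_area_mm2


def radial_moment(cloud: PixelCloud) -> float:
    """Radial area moment of inertia: Ir = sum_i d_i^2 * dA, in mm^4."""
    if len(cloud) == 0:
        return 0.0
    return float(np.sum(cloud.distances_mm**2) * cloud.pixel_area_mm2)


def summarize_invasion(
    day0: BinaryImage,
    day2: BinaryImage,
    cloud: PixelCloud,
    spheroid_id: str = "",
) -> InvasionMetrics:
    """Assemble the per-spheroid invasion record."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        da = area_change(day0, day2)
    n = len(cloud)
    return InvasionMetrics(
        spheroid_id=spheroid_id,
        delta_area_mm2=da,
        mean_distance_mm=float(cloud.distances_mm.mean()) if n else 0.0,
        max_distance_mm=float(cloud.distances_mm.max()) if n else 0.0,
        radial_moment_mm4=radial_moment(cloud),
        n_outer_pixels=n,
        shrinkage=da < 0,
    )
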