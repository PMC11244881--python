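"""Day-0 spheroid segmentation, boundary extraction and registration.

The initial (Day-0) spheroid footprint is the reference from which every
invasion distance is measured. The largest 8-connected foreground
component is taken as the spheroid, interior holes are filled so the
boundary is the outer envelope, a sub-pixel contour is traced at the 0.5
level, and the contour is registered onto the later-timepoint image by
translating its centroid onto the centroid of the Day-2 spheroid core.
Registration is a pure translation — the assay has no meaningful rotation
between timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours, label

from .errors import ValidationError
from .imaging_io import BinaryImage


@dataclass
class SpheroidMask:
    """The filled single-component spheroid footprint.

    ``centroid`` is (x0, y0): the arithmetic mean of member pixel
    coordinates (x = col, y = row), possibly fractional.
    """

    mask: np.ndarray
    area_px: int
    centroid: tuple[float, float]


@dataclass
class BoundaryPolygon:
    """Closed outer contour of the spheroid at sub-pixel resolution.

    ``vertices`` is an (N, 2) array of (x, y) points tracing the contour
    once, without a repeated end point; the ring closes implicitly.
    ``centroid`` is the spheroid centroid (x0, y0), the origin of every
    radial ray.
    """

    vertices: np.ndarray
    centroid: tuple[float, float]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3:
            raise ValidationError("boundary polygon needs >= 3 vertices")

    @property
    def signed_area_px2(self) -> float:
        """Shoelace signed area in the (x, y, y-down) frame."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area_px2(self) -> float:
        return abs(self.signed_area_px2)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            self.vertices,
            delimiter=",",
            header="x_px,y_px",
            comments="",
            fmt="%.6f",
        )

    def to_ring(self) -> dict:
        """GeoJSON-style representation for the run manifest."""
        ring = np.vstack([self.vertices, self.vertices[:1]])
        return {
            "type": "Polygon",
            "coordinates": [ring.tolist()],
            "centroid": list(self.centroid),
        }


def _largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component; ties broken by top-left bounding box."""
    labels = label(mask, connectivity=2)
    n = labels.max()
    if n == 0:
        raise ValidationError("no spheroid found: image has no foreground pixels")
    sizes = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(sizes == sizes.max()) + 1
    if len(best) > 1:
        corners = []
        for lab in best:
            rows, cols = np.nonzero(labels == lab)
            corners.append((rows.min(), cols.min()))
        best = [best[int(np.lexsort(np.array(corners).T[::-1])[0])]]
    return labels == best[0]


def extract_spheroid_mask(day0: BinaryImage) -> SpheroidMask:
    """Segment the spheroid: largest component, holes filled, centroid."""
    comp = _largest_component(day0.mask)
    filled = ndimage.binary_fill_holes(comp)
    rows, cols = np.nonzero(filled)
    return SpheroidMask(
        mask=filled,
        area_px=int(filled.sum()),
        centroid=(float(cols.mean()), float(rows.mean())),
    )


def extract_boundary(mask: SpheroidMask) -> BoundaryPolygon:
    """Trace the outer contour of the filled component at the 0.5 level.

    Marching squares on a zero-padded copy guarantees a closed ring even
    when the component touches the frame edge. The ring is normalized to
    positive shoelace orientation in the y-down frame.
    """
    if mask.area_px < 1:
        raise ValidationError("mask is empty")
    padded = np.pad(mask.mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValidationError("no contour found")
    # keep the contour enclosing the largest area (the outer envelope)
    def ring_area(c: np.ndarray) -> float:
        y, x = c[:, 0], c[:, 1]
        return abs(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    contour = max(contours, key=ring_area)
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    verts = np.column_stack([contour[:, 1] - 1.0, contour[:, 0] - 1.0])  # (x, y)
    poly = BoundaryPolygon(vertices=verts, centroid=mask.centroid)
    if poly.signed_area_px2 < 0:
        poly = BoundaryPolygon(vertices=verts[::-1].copy(), centroid=mask.centroid)
    return poly


def day2_centroid(day2: BinaryImage) -> tuple[float, float]:
    """Centroid of the Day-2 spheroid core.

    Uses the largest connected component only (holes filled) so that
    scattered invading pixels, which are spatially asymmetric, do not
    drag the registration off the spheroid body.
    """
    comp = _largest_component(day2.mask)
    filled = ndimage.binary_fill_holes(comp)
    rows, cols = np.nonzero(filled)
    return (float(cols.mean()), float(rows.mean()))


def register_boundary(
    boundary: BoundaryPolygon, day2_centroid_xy: tuple[float, float]
) -> BoundaryPolygon:
    """Translate the Day-0 boundary so its centroid overlays the Day-2 core."""
    dx = day2_centroid_xy[0] - boundary.centroid[0]
    dy = day2_centroid_xy[1] - boundary.centroid[1]
    return BoundaryPolygon(
        vertices=boundary.vertices + np.array([dx, dy]),
        centroid=(float(day2_centroid_xy[0]), float(day2_centroid_xy[1])),
    )
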