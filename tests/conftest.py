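import numpy as np
import pytest

from invquant import BoundaryPolygon, make_annulus_pair


def star_polygon(
    r_mean: float, amplitude: float, n_lobes: int, n_vertices: int = 720,
    center=(0.0, 0.0),
) -> BoundaryPolygon:
    """Non-convex star r(phi) = r_mean * (1 + amplitude * cos(n_lobes * phi))."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = r_mean * (1.0 + amplitude * np.cos(n_lobes * phi))
    verts = np.column_stack(
        [center[0] + r * np.cos(phi), center[1] + r * np.sin(phi)]
    )
    return BoundaryPolygon(verts, centroid=center)


def dense_ray_oracle(
    polygon: BoundaryPolygon, pixels: np.ndarray, n_samples: int = 10_000
) -> np.ndarray:
    """Brute-force ray/boundary crossings via dense polyline resampling.

    Independent of the package's ray caster: the polygon ring is
    resampled to ``n_samples`` points by arc length and every tiny
    segment is intersected with the centroid->pixel segment; the
    outermost crossing not beyond the pixel is returned per pixel.
    """
    ring = np.vstack([polygon.vertices, polygon.vertices[:1]])
    seg = np.diff(ring, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.linspace(0.0, cum[-1], n_samples, endpoint=False)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seglen[idx]
    pts = ring[idx] + seg[idx] * frac[:, None]
    dense = np.vstack([pts, pts[:1]])
    a, b = dense[:-1], dense[1:]
    d = b - a
    c = np.asarray(polygon.centroid, dtype=float)
    qa = a - c
    out = np.empty((len(pixels), 2))
    for i, p in enumerate(np.asarray(pixels, dtype=float)):
        r = p - c
        denom = r[0] * d[:, 1] - r[1] * d[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (qa[:, 0] * d[:, 1] - qa[:, 1] * d[:, 0]) / denom
            u = (qa[:, 0] * r[1] - qa[:, 1] * r[0]) / denom
        ok = (
            (np.abs(denom) > 1e-12)
            & (u >= -1e-9)
            & (u <= 1 + 1e-9)
            & (t > 1e-12)
            & (t <= 1 + 1e-9)
        )
        out[i] = c + t[ok].max() * r
    return out


@pytest.fixture(scope="session")
def annulus_pair_10um():
    """Disk R0 = 1 mm -> disk R1 = 2 mm at 10 um/px, with analytic truth."""
    return make_annulus_pair(1.0, 2.0, 10.0)
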