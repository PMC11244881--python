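"""Image input/output and binarization.

Grayscale nuclear images (maximum z-projections of Hoechst-stained
spheroids) are normalized to [0, 1], optionally background-subtracted and
contrast-stretched, binarized with a single global threshold, and cropped
to an inscribed circular field of view so that the frame corners and long
axis do not bias radially symmetric metrics.

Coordinate convention used package-wide: 0-based (row, col) array indices
with x = col, y = row; y increases downward (image convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
from skimage.morphology import disk, white_tophat

from .errors import ValidationError

# ITU-R BT.709 luminance weights, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


@dataclass
class GrayImage:
    """A single-channel image with intensities normalized to [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError(
                f"expected a non-empty 2D image, got shape {self.pixels.shape}"
            )
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValidationError("intensities must lie in [0, 1] after normalization")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryImage:
    """A boolean foreground mask with physical pixel calibration.

    ``pixel_size_um`` is the side length of one pixel in micrometres; the
    area of a single pixel, ``pixel_area_mm2``, is the ``dA`` element that
    all area and moment metrics integrate over.
    """

    mask: np.ndarray
    pixel_size_um: float
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.size == 0:
            raise ValidationError(
                f"expected a non-empty 2D mask, got shape {self.mask.shape}"
            )
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def height_px(self) -> int:
        return self.mask.shape[0]

    @property
    def width_px(self) -> int:
        return self.mask.shape[1]

    @property
    def pixel_area_mm2(self) -> float:
        return (self.pixel_size_um / 1000.0) ** 2

    @property
    def foreground_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class CorrectionMask:
    """Pixels to keep when scrubbing artifacts (debris, posts, bubbles).

    Replaces interactive manual clean-up with a reproducible, same-shape
    boolean mask: foreground pixels where ``keep`` is False are erased.
    """

    keep: np.ndarray = field()

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if self.keep.ndim != 2:
            raise ValidationError("correction mask must be 2D")


def _normalize(arr: np.ndarray) -> np.ndarray:
    """Scale an integer or float array to float64 intensities in [0, 1]."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    out = arr.astype(np.float64)
    if out.size and (out.min() < 0.0 or out.max() > 1.0):
        # float images are expected pre-normalized; rescale defensively
        lo, hi = out.min(), out.max()
        out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return out


def _to_single_channel(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValidationError(
            f"expected a single 2D frame, got shape {arr.shape}; "
            "use load_zstack for multi-page stacks"
        )
    return arr


def load_grayscale(path: str | Path) -> GrayImage:
    """Read an 8/16-bit TIFF or PNG as a normalized grayscale image.

    RGB input is converted to luminance; integer bit depth is handled by
    dividing by the dtype maximum (255 or 65535).
    """
    path = Path(path)
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    if raw.ndim == 3 and raw.shape[-1] not in (3, 4):
        raise ValidationError(
            f"{path} looks like a z-stack (shape {raw.shape}); use load_zstack"
        )
    gray = _to_single_channel(_normalize(np.asarray(raw)))
    return GrayImage(gray, source_path=str(path))


def load_zstack(path: str | Path) -> list[GrayImage]:
    """Read a multi-page TIFF as an ordered list of z-slices."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
    else:
        stack = iio.imread(path)
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim == 3 and stack.shape[-1] in (3, 4) and stack.shape[0] not in (3, 4):
        # single RGB frame, not a stack
        stack = stack[None]
    return [
        GrayImage(_to_single_channel(_normalize(frame)), source_path=str(path))
        for frame in stack
    ]


def max_z_projection(slices: list[GrayImage]) -> GrayImage:
    """Collapse a z-stack to 2D by taking the per-pixel maximum."""
    if not slices:
        raise ValidationError("need at least one slice")
    shapes = {s.pixels.shape for s in slices}
    if len(shapes) != 1:
        raise ValidationError(f"slice shapes differ: {sorted(shapes)}")
    proj = np.maximum.reduce([s.pixels for s in slices])
    return GrayImage(proj, source_path=slices[0].source_path)


def subtract_background(img: GrayImage, radius_px: int = 50) -> GrayImage:
    """Remove smooth background with a morphological white top-hat.

    The structuring element radius should exceed the largest foreground
    feature (a nucleus is typically ~10 px at 10x); default 50 px.
    """
    corrected = white_tophat(img.pixels, footprint=disk(radius_px))
    return GrayImage(np.clip(corrected, 0.0, 1.0), source_path=img.source_path)


def enhance_contrast(img: GrayImage, p_low: float = 1.0, p_high: float = 99.0) -> GrayImage:
    """Linearly stretch the [p_low, p_high] intensity percentiles to [0, 1]."""
    lo, hi = np.percentile(img.pixels, [p_low, p_high])
    if hi <= lo:
        return GrayImage(img.pixels.copy(), source_path=img.source_path)
    stretched = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return GrayImage(stretched, source_path=img.source_path)


def binarize_global(
    img: GrayImage,
    threshold: float = 0.16,
    subtract_background_flag: bool = False,
    enhance_contrast_flag: bool = False,
    pixel_size_um: float = 1.0,
    timepoint_label: str = "",
    background_radius_px: int = 50,
) -> BinaryImage:
    """Binarize with a single global threshold: foreground = intensity > threshold.

    The 0.16 default (on the normalized [0, 1] range) works well for
    maximum-projected Hoechst nuclear images. Optional pre-processing
    (background subtraction, percentile contrast stretch) is off by
    default; the operation is deterministic.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    work = img
    if subtract_background_flag:
        work = subtract_background(work, radius_px=background_radius_px)
    if enhance_contrast_flag:
        work = enhance_contrast(work)
    return BinaryImage(
        work.pixels > threshold,
        pixel_size_um=pixel_size_um,
        timepoint_label=timepoint_label,
    )


def apply_circular_mask(img: BinaryImage) -> BinaryImage:
    """Blank pixels outside the inscribed circle centred on the image.

    A pixel survives iff the Euclidean distance from its centre to the
    image centre ((H-1)/2, (W-1)/2) is <= min(H, W)/2. This removes the
    frame corners and the long axis overhang, which would otherwise bias
    radial metrics toward those directions.
    """
    h, w = img.mask.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = min(h, w) / 2.0
    yy, xx = np.ogrid[:h, :w]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return BinaryImage(
        img.mask & inside,
        pixel_size_um=img.pixel_size_um,
        timepoint_label=img.timepoint_label,
    )


def apply_correction_mask(img: BinaryImage, correction: CorrectionMask) -> BinaryImage:
    """Erase foreground pixels flagged as artifacts (logical AND with keep)."""
    if correction.keep.shape != img.mask.shape:
        raise ValidationError(
            f"correction mask shape {correction.keep.shape} != image shape {img.mask.shape}"
        )
    return BinaryImage(
        img.mask & correction.keep,
        pixel_size_um=img.pixel_size_um,
        timepoint_label=img.timepoint_label,
    )


def load_binary(
    path: str | Path, pixel_size_um: float, timepoint_label: str = ""
) -> BinaryImage:
    """Read a pre-binarized image (any nonzero pixel is foreground)."""
    img = load_grayscale(path)
    return BinaryImage(
        img.pixels > 0, pixel_size_um=pixel_size_um, timepoint_label=timepoint_label
    )


def save_binary(img: BinaryImage, path: str | Path) -> None:
    """Write a binary mask as an 8-bit image (0/255)."""
    out = (img.mask.astype(np.uint8)) * 255
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def load_correction_mask(path: str | Path) -> CorrectionMask:
    """Read a keep-mask image (nonzero = keep)."""
    img = load_grayscale(path)
    return CorrectionMask(img.pixels > 0)
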