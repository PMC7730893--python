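"""Deterministic background-cropping pipeline for single-fruit photographs.

The chain is: 11x11 Gaussian smoothing, luminance grayscale, adaptive
mean-threshold binarisation (holes filled so the object is solid), Laplacian
filtering, Canny edge extraction,
minimal axis-aligned bounding rectangle of the largest connected edge
component, and a bilinear crop-resize to 100x100 RGB.

Binarisation marks as foreground the pixels *brighter* than their local mean
by more than ``offset`` grey levels — the lit fruit against the dark
background — so a constant image yields an empty mask and a large negative
offset marks everything.

All coordinates are 0-based; boxes are half-open (columns [x, x+w), rows
[y, y+h)).  Borders are handled by reflection in every filter.  The chain is
fully deterministic: identical input bytes give identical output bytes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import canny as _sk_canny
from skimage.measure import label as _cc_label
from skimage.transform import resize as _sk_resize

__all__ = ["BoundingBox", "PreprocessParams", "NoObjectError",
           "gaussian_smooth", "to_grayscale", "adaptive_binarize",
           "laplacian", "canny_edges", "extract_fruit_box", "crop_resize",
           "preprocess_image"]

OUTPUT_SIZE = 100


class NoObjectError(RuntimeError):
    """No edge pixels survived the chain; names the stage that went empty."""

    def __init__(self, stage: str):
        super().__init__(f"no object found: stage {stage!r} produced an "
                         "empty result")
        self.stage = stage


@dataclass(frozen=True)
class BoundingBox:
    """Half-open axis-aligned box: columns [x, x+w), rows [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w < 1 or self.h < 1:
            raise ValueError("box extents must be >= 1")
        if self.x < 0 or self.y < 0:
            raise ValueError("box origin must be non-negative")


@dataclass
class PreprocessParams:
    """Stage parameters; only the 11x11 Gaussian kernel is canonical, the
    rest are chosen to segment fruit-on-dark-background imagery robustly."""

    gaussian_kernel: int = 11
    block_size: int = 51
    offset: float = 5.0
    canny_low: float = 50.0
    canny_high: float = 150.0


def _gaussian_kernel_1d(ksize: int) -> np.ndarray:
    # sigma from kernel size by the standard 0.3*((k-1)/2 - 1) + 0.8 rule
    sigma = 0.3 * ((ksize - 1) * 0.5 - 1.0) + 0.8
    r = (ksize - 1) / 2.0
    xs = np.arange(ksize) - r
    k = np.exp(-(xs ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def gaussian_smooth(img: np.ndarray, kernel_size: int = 11) -> np.ndarray:
    """Channel-wise separable Gaussian blur with reflective borders."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ValueError("kernel_size must be a positive odd integer")
    img = np.asarray(img)
    if kernel_size == 1:
        return img.copy()
    k = _gaussian_kernel_1d(kernel_size)
    out = img.astype(np.float64)
    for axis in (0, 1):
        out = ndimage.correlate1d(out, k, axis=axis, mode="reflect")
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(img.dtype)
    return out


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """8-bit luminance: round(0.299 R + 0.587 G + 0.114 B)."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got {img.shape}")
    y = img[..., 0] * 0.299 + img[..., 1] * 0.587 + img[..., 2] * 0.114
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def adaptive_binarize(gray: np.ndarray, block_size: int = 51,
                      offset: float = 5.0) -> np.ndarray:
    """Local-mean threshold: 255 where pixel > local_mean + offset, else 0.

    The mean is taken over a block_size x block_size neighbourhood with
    reflective borders, so with a positive offset the mask picks out regions
    locally *brighter* than their surroundings — for ring-lit fruit on a dark
    background, the band just inside the fruit contour.  A constant image
    yields an empty mask; offset = -256 marks everything.
    """
    if block_size < 3 or block_size % 2 == 0:
        raise ValueError("block_size must be an odd integer >= 3")
    gray = np.asarray(gray)
    if gray.ndim != 2:
        raise ValueError("adaptive_binarize expects a single-channel image")
    local_mean = ndimage.uniform_filter(gray.astype(np.float64),
                                        size=block_size, mode="reflect")
    mask = gray.astype(np.float64) > local_mean + offset
    return np.where(mask, 255, 0).astype(np.uint8)


def laplacian(img: np.ndarray) -> np.ndarray:
    """3x3 Laplacian (4-neighbour stencil), reflective borders, float output."""
    return ndimage.laplace(np.asarray(img, dtype=np.float64), mode="reflect")


def canny_edges(img: np.ndarray, low: float = 50.0,
                high: float = 150.0) -> np.ndarray:
    """Canny edge map (boolean) with absolute gradient-magnitude thresholds."""
    return _sk_canny(np.asarray(img, dtype=np.float64),
                     low_threshold=low, high_threshold=high,
                     use_quantiles=False)


def extract_fruit_box(img: np.ndarray,
                      params: PreprocessParams | None = None) -> BoundingBox:
    """Minimal bounding rectangle of the largest connected edge component.

    Runs the full gaussian -> gray -> adaptive threshold -> Laplacian ->
    Canny chain.  Ties between equally large components are broken by the
    smallest column, then the smallest row, of the component's extent.
    """
    p = params or PreprocessParams()
    smooth = gaussian_smooth(img, p.gaussian_kernel)
    gray = to_grayscale(smooth)
    mask = adaptive_binarize(gray, p.block_size, p.offset)
    if not mask.any():
        raise NoObjectError("adaptive_binarize")
    # local-mean thresholding marks a band along the object contour; filling
    # its holes leaves the solid object, whose only contour is the outer one
    filled = ndimage.binary_fill_holes(mask > 0)
    solid = np.where(filled, 255, 0).astype(np.uint8)
    # Canny expects a non-negative intensity image, so it sees the magnitude
    # of the Laplacian response (a thin ridge along every mask contour)
    lap = np.abs(laplacian(solid))
    edges = canny_edges(lap, p.canny_low, p.canny_high)
    if not edges.any():
        raise NoObjectError("canny")
    comp = _cc_label(edges, connectivity=2)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    best = None
    for cid in np.flatnonzero(sizes == sizes.max()):
        ys, xs = np.nonzero(comp == cid)
        key = (int(xs.min()), int(ys.min()))
        if best is None or key < best[0]:
            best = (key, ys, xs)
    _, ys, xs = best
    return BoundingBox(x=int(xs.min()), y=int(ys.min()),
                       w=int(xs.max() - xs.min() + 1),
                       h=int(ys.max() - ys.min() + 1))


def crop_resize(img: np.ndarray, box: BoundingBox,
                size: int = OUTPUT_SIZE) -> np.ndarray:
    """Crop the box from the RGB image and bilinearly resize to size x size.

    The box is stretched to a square; aspect ratio is not preserved.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if box.x + box.w > w or box.y + box.h > h:
        raise ValueError(f"box {box} exceeds image bounds {h}x{w}")
    crop = img[box.y: box.y + box.h, box.x: box.x + box.w]
    if crop.shape[0] == size and crop.shape[1] == size:
        return crop.copy()
    out = _sk_resize(crop.astype(np.float64), (size, size), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def preprocess_image(img: np.ndarray,
                     params: PreprocessParams | None = None) -> np.ndarray:
    """Full chain: locate the fruit and return the 100x100 RGB crop."""
    box = extract_fruit_box(img, params)
    return crop_resize(np.asarray(img), box)
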