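"""Tissue segmentation of a slide at a downsampled resolution.

Pipeline (order fixed): downsample by block averaging, RGB to HSV, take the
saturation channel, median filter, Otsu binarization, morphological closing,
then contour extraction with a tissue/hole hierarchy and minimum-area
filtering. Stained tissue is strongly saturated while the scanner background
(and holes in the section) are near-white, so saturation thresholding
separates them cleanly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters as skfilters
from skimage import measure as skmeasure

from .slide import SlideImage

__all__ = ["SegmentationParams", "TissueMask", "otsu_threshold", "segment_tissue"]


@dataclasses.dataclass
class SegmentationParams:
    downsample_factor: int = 32
    median_kernel_px: int = 7
    closing_kernel_px: int = 5
    min_tissue_area_px: int = 512   # at the downsampled resolution
    min_hole_area_px: int = 256     # at the downsampled resolution

    def validate(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        for k in (self.median_kernel_px, self.closing_kernel_px):
            if k < 1 or k % 2 == 0:
                raise ValueError("kernel sizes must be odd and >= 1")
        if self.min_tissue_area_px < 0 or self.min_hole_area_px < 0:
            raise ValueError("area minima must be >= 0")


@dataclasses.dataclass
class TissueMask:
    """Binary tissue mask at ``downsample_factor`` with its contours.

    ``mask`` is true exactly where a pixel lies inside a retained tissue
    contour and outside every retained hole contour. Contours are (row, col)
    polygons at the downsampled resolution.
    """

    mask: np.ndarray
    downsample_factor: int
    tissue_contours: list[np.ndarray]
    hole_contours: list[np.ndarray]
    otsu_threshold: int


def otsu_threshold(histogram: np.ndarray) -> int:
    """Otsu's threshold on a 256-bin histogram.

    Returns the bin index t maximizing the between-class variance of the
    split {0..t} vs {t+1..255}; the smallest such index on ties. If all mass
    sits in a single bin, that bin's index is returned.
    """
    counts = np.asarray(histogram, dtype=np.float64)
    if counts.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    if np.any(counts < 0):
        raise ValueError("histogram counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    bins = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(counts)
    s0 = np.cumsum(counts * bins)
    s_all = s0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():  # all mass in one bin
        return int(np.argmax(counts))
    # between-class variance: w0*w1*(mu0-mu1)^2, written to avoid 0/0
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (s0 * total - s_all * w0) ** 2 / (w0 * w1)
    var[~valid] = -np.inf
    return int(np.argmax(var))  # argmax takes the first (smallest) maximizer


def _downsample(img: np.ndarray, f: int) -> np.ndarray:
    h, w = img.shape[:2]
    h2, w2 = (h // f) * f, (w // f) * f
    trimmed = img[:h2, :w2].astype(np.float64)
    return trimmed.reshape(h2 // f, f, w2 // f, f, 3).mean(axis=(1, 3))


def segment_tissue(slide: SlideImage, params: SegmentationParams | None = None) -> TissueMask:
    """Segment tissue from background and holes; see module docstring."""
    params = params or SegmentationParams()
    params.validate()
    f = params.downsample_factor
    w, h = slide.dims
    if h // f < params.median_kernel_px or w // f < params.median_kernel_px:
        raise ValueError("downsampled slide smaller than the median kernel")

    small = _downsample(slide.image, f) / 255.0
    sat = skcolor.rgb2hsv(small)[:, :, 1]
    sat_u8 = np.clip(np.round(sat * 255.0), 0, 255).astype(np.uint8)
    med = skfilters.median(sat_u8, footprint=np.ones(
        (params.median_kernel_px, params.median_kernel_px), dtype=bool))
    hist = np.bincount(med.ravel(), minlength=256)[:256]
    t = otsu_threshold(hist)
    binary = med > t
    struct = np.ones((params.closing_kernel_px, params.closing_kernel_px), dtype=bool)
    closed = ndimage.binary_closing(binary, structure=struct)

    # keep sufficiently large tissue components
    cleaned = _drop_small(closed, params.min_tissue_area_px)
    # a hole is an enclosed background region inside a tissue component;
    # holes below the minimum area are absorbed into tissue
    filled = ndimage.binary_fill_holes(cleaned)
    holes = _drop_small(filled & ~cleaned, params.min_hole_area_px)
    mask = filled & ~holes

    tissue_contours = _contours(filled)
    hole_contours = _contours(holes)
    return TissueMask(mask=mask, downsample_factor=f,
                      tissue_contours=tissue_contours,
                      hole_contours=hole_contours, otsu_threshold=t)


def _drop_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Remove connected components with area below ``min_area`` pixels."""
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask)
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep != 0]
    return np.isin(labels, keep)


def _contours(mask: np.ndarray) -> list[np.ndarray]:
    if not mask.any():
        return []
    padded = np.pad(mask.astype(float), 1)
    return [c - 1.0 for c in skmeasure.find_contours(padded, 0.5)]
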