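"""Sliding-window patch extraction from segmented tissue.

Square windows tile the slide at full resolution starting from (0, 0); a
window is kept when its area-weighted tissue fraction, computed on the
downsampled mask, reaches ``min_tissue_fraction``. Windows that would extend
past the slide edge are discarded, so every emitted patch has full pixel
content. Coordinates are 0-based level-0 pixels, half-open intervals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .segmentation import TissueMask
from .slide import SlideImage

__all__ = ["PatchGridParams", "PatchRecord", "extract_patch_grid", "read_patch",
           "patches_to_manifest"]


@dataclasses.dataclass
class PatchGridParams:
    patch_px: int = 256
    stride_px: int = 256
    min_tissue_fraction: float = 0.5

    def validate(self) -> None:
        if self.patch_px < 32:
            raise ValueError("patch_px must be >= 32")
        if self.stride_px < 1:
            raise ValueError("stride_px must be >= 1")
        if not 0.0 < self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must be in (0, 1]")


@dataclasses.dataclass
class PatchRecord:
    """One square patch; ``pixels`` stays None until read from the slide."""

    patient_id: str
    slide_id: str
    x0: int
    y0: int
    size_px: int
    tissue_fraction: float
    pixels: np.ndarray | None = None
    label: str = "unknown"  # normal | anomalous | unknown

    def pixels_float(self) -> np.ndarray:
        """Pixel content scaled to [0, 1] floats (model input convention)."""
        if self.pixels is None:
            raise ValueError("patch pixels not read")
        return self.pixels.astype(np.float32) / 255.0


def _axis_weights(start: int, length: int, f: int, n_cells: int):
    """Overlap (in level-0 pixels) of [start, start+length) with each mask cell."""
    lo = start // f
    hi = min((start + length - 1) // f, n_cells - 1)
    cells = np.arange(lo, hi + 1)
    left = np.maximum(cells * f, start)
    right = np.minimum((cells + 1) * f, start + length)
    return cells, (right - left).astype(np.float64)


def tissue_fraction(mask: TissueMask, x0: int, y0: int, size_px: int) -> float:
    """Area-weighted tissue fraction of a level-0 window on the coarse mask.

    Each mask cell covers ``downsample_factor``² level-0 pixels; cells past
    the mask boundary (possible when slide dims are not multiples of the
    factor) count as non-tissue.
    """
    m = mask.mask
    f = mask.downsample_factor
    ys, wy = _axis_weights(y0, size_px, f, m.shape[0])
    xs, wx = _axis_weights(x0, size_px, f, m.shape[1])
    sub = m[np.ix_(ys, xs)].astype(np.float64)
    covered = wy @ sub @ wx
    return float(covered / (size_px * size_px))


def extract_patch_grid(mask: TissueMask, slide_dims: tuple[int, int],
                       params: PatchGridParams | None = None,
                       patient_id: str = "unknown",
                       slide_id: str = "slide") -> list[PatchRecord]:
    """Coordinates-only patch records for all qualifying grid windows."""
    params = params or PatchGridParams()
    params.validate()
    w, h = slide_dims
    p, s = params.patch_px, params.stride_px
    records: list[PatchRecord] = []
    for y0 in range(0, h - p + 1, s):
        for x0 in range(0, w - p + 1, s):
            frac = tissue_fraction(mask, x0, y0, p)
            if frac >= params.min_tissue_fraction:
                records.append(PatchRecord(
                    patient_id=patient_id, slide_id=slide_id,
                    x0=x0, y0=y0, size_px=p, tissue_fraction=frac))
    return records


def read_patch(slide: SlideImage, record: PatchRecord) -> PatchRecord:
    """Return a copy of ``record`` with its pixel content filled in."""
    w, h = slide.dims
    p = record.size_px
    if not (0 <= record.x0 and record.x0 + p <= w and 0 <= record.y0 and record.y0 + p <= h):
        raise ValueError(
            f"patch ({record.x0}, {record.y0}, {p}) out of slide bounds {w}x{h}")
    pixels = np.ascontiguousarray(
        slide.image[record.y0:record.y0 + p, record.x0:record.x0 + p])
    return dataclasses.replace(record, pixels=pixels)


def patches_to_manifest(records: list[PatchRecord]) -> pd.DataFrame:
    """Patch manifest (no pixel data), suitable for CSV round trips."""
    return pd.DataFrame([
        {"patient_id": r.patient_id, "slide_id": r.slide_id, "x0": r.x0,
         "y0": r.y0, "size_px": r.size_px, "tissue_fraction": r.tissue_fraction,
         "label": r.label}
        for r in records
    ])
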