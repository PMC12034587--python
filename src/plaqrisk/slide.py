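"""Slide container and image I/O.

Slides are single-level RGB 8-bit images (PNG or TIFF). Pyramidal formats are
out of scope; the segmentation stage takes an explicit downsample factor
instead of reading a pyramid level.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np


@dataclasses.dataclass
class SlideImage:
    """An RGB slide held in memory, the unit of preprocessing."""

    image: np.ndarray  # H x W x 3, uint8
    slide_id: str = "slide"

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
        if img.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {img.dtype}")
        self.image = img

    @property
    def dims(self) -> tuple[int, int]:
        """(width, height) in level-0 pixels."""
        return self.image.shape[1], self.image.shape[0]

    @classmethod
    def from_file(cls, path: str | Path, slide_id: str | None = None) -> "SlideImage":
        import imageio.v3 as iio

        path = Path(path)
        try:
            img = iio.imread(path)
        except OSError as exc:
            raise IOError(f"cannot read slide {path}: {exc}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        return cls(image=np.ascontiguousarray(img, dtype=np.uint8),
                   slide_id=slide_id or path.stem)

    def save(self, path: str | Path) -> None:
        import imageio.v3 as iio

        iio.imwrite(Path(path), self.image)
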