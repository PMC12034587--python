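"""Seeded synthetic slides, patch banks, and clinical tables.

Every downstream stage (segmentation, patching, anomaly scoring, risk
aggregation, classification) is testable against these generators because the
ground truth is exact: tissue and anomaly masks are recorded pixel-by-pixel,
and the clinical table's class-conditional distributions are the generator's
own parameters.

Slides emulate an H&E-stained plaque section: pink/purple tissue blobs on a
near-white scanner background, with background-colored holes inside the
tissue and, optionally, localized anomalous textures standing in for the
pathologies seen in unstable plaques (hemorrhage-like dark-red clots,
infiltrate-like fields of small dark nuclei, deposit-like brown granules).
Clinical tables follow the 18-variable schema of the study cohort, with the
class-conditional means/proportions of that cohort as defaults; additional
class effects and MCAR missingness are configurable.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import schema
from .patching import PatchRecord

# H&E-like palette (RGB, uint8 scale). Background near white so that
# HSV-saturation thresholding separates tissue exactly as on real scans.
BACKGROUND_RGB = (245, 245, 245)
TISSUE_RGB = (230, 160, 190)

# texture name -> (fill RGB, fraction of the lesion disc the texture covers)
ANOMALY_TEXTURES = {
    "hemorrhage_like": ((120, 30, 40), 1.0),
    "infiltrate_like": ((60, 40, 90), 0.40),
    "deposit_like": ((110, 80, 40), 0.45),
}


def expected_mean_contrast(texture: str, lesion_fraction: float) -> float:
    """Expected drop in mean gray intensity of a patch containing a lesion.

    Derived purely from generator parameters: the lesion covers
    ``lesion_fraction`` of the patch, the texture covers a known fraction of
    the lesion, and each covered pixel moves from the tissue color to the
    texture color.
    """
    fill, cover = ANOMALY_TEXTURES[texture]
    tissue_mean = float(np.mean(TISSUE_RGB))
    fill_mean = float(np.mean(fill))
    return lesion_fraction * cover * (tissue_mean - fill_mean)


@dataclasses.dataclass
class SlideGenConfig:
    width_px: int = 1024
    height_px: int = 1024
    background_rgb: tuple[int, int, int] = BACKGROUND_RGB
    tissue_blob_count: int = 3
    hole_count: int = 2
    anomaly_lesion_count: int = 0
    anomaly_texture: str = "hemorrhage_like"
    noise_sd: float = 6.0
    seed: int = 0
    # optional explicit placement: lists of (cx, cy, radius) in pixels;
    # override random placement of tissue blobs / holes when given
    blob_specs: Sequence[tuple[int, int, int]] | None = None
    hole_specs: Sequence[tuple[int, int, int]] | None = None

    def validate(self) -> None:
        if self.width_px < 512 or self.height_px < 512:
            raise ValueError("slide dimensions must be at least 512 px")
        if min(self.tissue_blob_count, self.hole_count, self.anomaly_lesion_count) < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.anomaly_texture not in ANOMALY_TEXTURES:
            raise ValueError(f"unknown anomaly texture {self.anomaly_texture!r}")


@dataclasses.dataclass
class SyntheticSlide:
    image: np.ndarray        # H x W x 3 uint8
    tissue_truth: np.ndarray  # H x W bool, tissue excluding holes
    anomaly_truth: np.ndarray  # H x W bool, subset of tissue_truth
    seed: int


def _disc(h: int, w: int, cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _paint_texture(img: np.ndarray, region: np.ndarray, texture: str,
                   rng: np.random.Generator, noise_sd: float) -> None:
    """Render an anomaly texture into ``region`` (bool mask) of ``img``."""
    fill, cover = ANOMALY_TEXTURES[texture]
    h, w = region.shape
    if cover >= 1.0:
        colored = region
    else:
        # scatter small dots/granules until the requested cover fraction:
        # a per-pixel Bernoulli field dilated to ~2 px speckles
        speck = rng.random((h, w)) < cover / 4.0
        from scipy import ndimage

        speck = ndimage.binary_dilation(speck, iterations=1)
        colored = region & speck
    base = np.array(fill, dtype=np.float64)
    noise = rng.normal(0.0, noise_sd, size=(int(colored.sum()), 3))
    img[colored] = np.clip(base + noise, 0, 255).astype(np.uint8)


def generate_slide(config: SlideGenConfig) -> SyntheticSlide:
    """Render one synthetic slide with exact tissue and anomaly ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    img = np.clip(
        rng.normal(0.0, config.noise_sd, size=(h, w, 3))
        + np.array(config.background_rgb, dtype=np.float64),
        0, 255,
    ).astype(np.uint8)

    # tissue blobs
    tissue = np.zeros((h, w), dtype=bool)
    if config.blob_specs is not None:
        specs = list(config.blob_specs)
    else:
        specs = []
        rmin, rmax = 0.12 * min(h, w), 0.22 * min(h, w)
        if rmax < 16:
            raise ValueError("slide too small to place tissue blobs")
        for _ in range(config.tissue_blob_count):
            r = rng.uniform(rmin, rmax)
            cx = rng.uniform(r, w - r)
            cy = rng.uniform(r, h - r)
            specs.append((cx, cy, r))
    for cx, cy, r in specs:
        if r <= 0 or r > min(h, w) / 2:
            raise ValueError(f"blob radius {r} does not fit the slide")
        tissue |= _disc(h, w, cx, cy, r)

    noise = rng.normal(0.0, config.noise_sd, size=(int(tissue.sum()), 3))
    img[tissue] = np.clip(np.array(TISSUE_RGB, dtype=np.float64) + noise, 0, 255).astype(np.uint8)

    # holes: background-colored discs fully inside tissue
    holes = np.zeros((h, w), dtype=bool)
    if config.hole_specs is not None:
        for cx, cy, r in config.hole_specs:
            holes |= _disc(h, w, cx, cy, r) & tissue
    else:
        tissue_idx = np.flatnonzero(tissue)
        for _ in range(config.hole_count):
            if tissue_idx.size == 0:
                break
            pos = tissue_idx[rng.integers(tissue_idx.size)]
            cy, cx = divmod(int(pos), w)
            r = rng.uniform(0.015, 0.04) * min(h, w)
            holes |= _disc(h, w, cx, cy, r) & tissue
    hnoise = rng.normal(0.0, config.noise_sd, size=(int(holes.sum()), 3))
    img[holes] = np.clip(np.array(config.background_rgb, dtype=np.float64) + hnoise,
                         0, 255).astype(np.uint8)

    tissue_truth = tissue & ~holes

    # anomaly lesions: textured discs inside tissue, avoiding holes
    anomaly = np.zeros((h, w), dtype=bool)
    usable = np.flatnonzero(tissue_truth)
    for _ in range(config.anomaly_lesion_count):
        if usable.size == 0:
            break
        pos = usable[rng.integers(usable.size)]
        cy, cx = divmod(int(pos), w)
        r = rng.uniform(0.04, 0.08) * min(h, w)
        lesion = _disc(h, w, cx, cy, r) & tissue_truth
        _paint_texture(img, lesion, config.anomaly_texture, rng, config.noise_sd)
        anomaly |= lesion

    return SyntheticSlide(image=img, tissue_truth=tissue_truth,
                          anomaly_truth=anomaly & tissue_truth, seed=config.seed)


def generate_patch_bank(config: SlideGenConfig, n_normal: int, n_anomalous: int,
                        patch_px: int = 64,
                        lesion_radius_frac: float = 0.35) -> list[PatchRecord]:
    """Standalone labelled patches of normal tissue texture vs lesion texture.

    Normal patches are pure tissue texture; anomalous patches carry one
    centered lesion disc of radius ``lesion_radius_frac * patch_px`` rendered
    with the configured texture. Deterministic under ``config.seed``.
    """
    config.validate()
    if patch_px < 32:
        raise ValueError("patch_px must be >= 32")
    rng = np.random.default_rng(config.seed)
    records: list[PatchRecord] = []
    for i in range(n_normal + n_anomalous):
        anomalous = i >= n_normal
        noise = rng.normal(0.0, config.noise_sd, size=(patch_px, patch_px, 3))
        img = np.clip(np.array(TISSUE_RGB, dtype=np.float64) + noise, 0, 255).astype(np.uint8)
        if anomalous:
            r = lesion_radius_frac * patch_px
            cx = rng.uniform(patch_px * 0.4, patch_px * 0.6)
            cy = rng.uniform(patch_px * 0.4, patch_px * 0.6)
            lesion = _disc(patch_px, patch_px, cx, cy, r)
            _paint_texture(img, lesion, config.anomaly_texture, rng, config.noise_sd)
        records.append(PatchRecord(
            patient_id="synthetic", slide_id=f"bank-{i}", x0=0, y0=0,
            size_px=patch_px, tissue_fraction=1.0, pixels=img,
            label="anomalous" if anomalous else "normal",
        ))
    return records


# ---------------------------------------------------------------------------
# clinical tables
# ---------------------------------------------------------------------------

# class-conditional parameters of the study cohort:
# continuous -> (normal mean, normal sd, abnormal mean, abnormal sd)
_CONTINUOUS_PARAMS = {
    "Age": (70.1, 6.5, 69.5, 6.7),
    "Vessel stenosis rate": (68.5, 26.4, 68.7, 27.0),
    "NIHSS": (1.2, 2.68, 3.0, 5.7),
    "MPRAGE": (1.9, 1.0, 2.1, 1.2),
}
# binary -> (normal proportion, abnormal proportion)
_BINARY_PARAMS = {
    "Male sex": (0.925, 1.0),
    "Smoking history": (0.600, 0.571),
    "Hypertension": (0.800, 0.904),
    "Diabetes mellitus": (0.433, 0.190),
    "Dyslipidemia": (0.716, 0.857),
    "Arteriosclerosis obliterans": (0.133, 0.047),
    "Coronary artery disease": (0.333, 0.238),
    "Aspirin": (0.900, 0.809),
    "Ticlopidine": (0.175, 0.333),
    "Clopidogrel": (0.158, 0.142),
    "Cilostazol": (0.158, 0.142),
    "Warfarin": (0.0, 0.380),
    "Heparin/argatroban": (0.116, 0.190),
    "Statins": (0.666, 0.619),
}


@dataclasses.dataclass
class ClinicalGenConfig:
    """Per-class sample sizes, missingness, and extra class effects.

    ``effect_sizes`` maps a feature name to an additional shift applied to the
    abnormal class on top of the cohort defaults: an additive shift for
    continuous features, an additive probability shift (clipped to [0, 1]) for
    binary ones.
    """

    n_normal: int = 50
    n_abnormal: int = 21
    missing_rate: float = 0.0
    effect_sizes: dict[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_normal < 1 or self.n_abnormal < 1:
            raise ValueError("need at least one patient per class")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        unknown = set(self.effect_sizes) - set(schema.CLINICAL_COLUMNS)
        if unknown:
            raise ValueError(f"unknown features in effect_sizes: {sorted(unknown)}")


def generate_clinical_table(config: ClinicalGenConfig) -> pd.DataFrame:
    """Per-patient clinical table: id, 18 features, binary outcome label."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_normal + config.n_abnormal
    labels = np.concatenate([np.zeros(config.n_normal, dtype=int),
                             np.ones(config.n_abnormal, dtype=int)])
    data: dict[str, np.ndarray] = {
        schema.ID_COLUMN: np.array([f"P{i:04d}" for i in range(n)], dtype=object)
    }
    for col in schema.CONTINUOUS_COLUMNS:
        m0, s0, m1, s1 = _CONTINUOUS_PARAMS[col]
        m1 = m1 + config.effect_sizes.get(col, 0.0)
        vals = np.where(labels == 0,
                        rng.normal(m0, s0, size=n),
                        rng.normal(m1, s1, size=n))
        if col in ("NIHSS", "MPRAGE", "Vessel stenosis rate"):
            vals = np.clip(vals, 0.0, None)
        data[col] = np.round(vals, 2)
    for col in schema.BINARY_COLUMNS:
        p0, p1 = _BINARY_PARAMS[col]
        p1 = float(np.clip(p1 + config.effect_sizes.get(col, 0.0), 0.0, 1.0))
        p = np.where(labels == 0, p0, p1)
        data[col] = (rng.random(n) < p).astype(float)
    df = pd.DataFrame(data)
    if config.missing_rate > 0:
        miss = rng.random((n, len(schema.CLINICAL_COLUMNS))) < config.missing_rate
        for j, col in enumerate(schema.CLINICAL_COLUMNS):
            df.loc[miss[:, j], col] = np.nan
    df[schema.LABEL_COLUMN] = labels
    return df
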