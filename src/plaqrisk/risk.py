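"""Patient-level pathological risk score and anomaly heat maps.

The pathological risk score of a patient is the mean of the anomaly scores of
all of that patient's patches:

    A_p = sum_{x in X} A(x) / |X|

where X pools the patches from every slide of the patient before averaging.
Heat maps render per-patch scores back onto the slide footprint at mask
resolution: brightness increases monotonically with score, non-tissue regions
stay black, and the normalization range is recorded so brightness is
comparable across patients when a cohort-wide range is supplied.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .patching import PatchRecord
from .segmentation import TissueMask

__all__ = ["PatientScoreSet", "patient_risk_score", "risk_table", "render_heatmap"]


@dataclasses.dataclass
class PatientScoreSet:
    """All patch anomaly scores for one patient (pooled across slides)."""

    patient_id: str
    records: list[PatchRecord]
    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.records) != self.scores.size:
            raise ValueError("one score per patch record required")


def patient_risk_score(scores) -> float:
    """A_p: arithmetic mean of a patient's patch anomaly scores.

    Accepts a `PatientScoreSet` or a plain sequence of scores; raises on an
    empty patch set (the patient is unscoreable).
    """
    values = scores.scores if isinstance(scores, PatientScoreSet) else np.asarray(
        list(scores), dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty patch set: patient is unscoreable")
    if np.any(values < 0):
        raise ValueError("anomaly scores must be non-negative")
    return float(values.mean())


def risk_table(patch_scores: pd.DataFrame) -> pd.DataFrame:
    """Per-patient risk scores from a (patient_id, score) patch table.

    Patches from all slides of a patient are pooled before averaging.
    """
    grouped = patch_scores.groupby("patient_id")["score"]
    out = grouped.agg(n_patches="size", risk_score="mean").reset_index()
    return out


def render_heatmap(mask: TissueMask, records: Sequence[PatchRecord],
                   scores: Sequence[float],
                   norm_range: tuple[float, float] | None = None,
                   ) -> tuple[np.ndarray, dict]:
    """Anomaly heat map at mask resolution.

    Each patch footprint is filled with its min-max-normalized score; higher
    brightness means a higher anomaly score. ``norm_range`` supplies a
    cohort-wide (lo, hi) so maps are comparable across slides; per-slide range
    is used when omitted. Returns (float image in [0, 1], metadata).
    """
    scores = np.asarray(list(scores), dtype=np.float64)
    if len(records) != scores.size:
        raise ValueError("one score per patch record required")
    lo, hi = norm_range if norm_range is not None else (
        (float(scores.min()), float(scores.max())) if scores.size else (0.0, 1.0))
    heat = np.zeros(mask.mask.shape, dtype=np.float64)
    f = mask.downsample_factor
    for rec, s in zip(records, scores):
        bright = 1.0 if hi <= lo else float(np.clip((s - lo) / (hi - lo), 0.0, 1.0))
        r0, r1 = rec.y0 // f, -(-(rec.y0 + rec.size_px) // f)
        c0, c1 = rec.x0 // f, -(-(rec.x0 + rec.size_px) // f)
        block = heat[r0:r1, c0:c1]
        np.maximum(block, bright, out=block)
    heat *= mask.mask.astype(np.float64)
    meta = {"norm_lo": lo, "norm_hi": hi, "downsample_factor": f}
    return heat, meta
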