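"""Two-channel colocalization metrics.

Three families, increasingly object-aware:

* **PCC** — Pearson correlation of the two channels' intensities over
  every crop pixel; global, intensity-based, range [-1, 1].
* **Manders (M1/M2)** — per-channel fraction of thresholded signal
  pixels that are also signal in the other channel.  Implemented on
  binary indicators (pixel counts), not the classic intensity-weighted
  form.
* **ROI Overlap Ratios (R1/R2)** — per-channel fraction of ROIs whose
  pixel overlap with the other channel's signal reaches a user-set
  Overlap Threshold theta; object-based and binary per punctum, so small
  boundary brushes between adjacent puncta are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ColocalizationResult:
    """All metrics for one two-channel crop at one overlap threshold."""

    pcc: float
    pcc_normalized: float
    m1: float
    m2: float
    r1: float
    r2: float
    overlap_threshold: float


def pcc(ch1: np.ndarray, ch2: np.ndarray) -> float:
    """Pearson correlation of pixel intensities over the whole crop."""
    ch1 = np.asarray(ch1, dtype=float).ravel()
    ch2 = np.asarray(ch2, dtype=float).ravel()
    if ch1.shape != ch2.shape:
        raise ValueError("channels must share a shape")
    d1 = ch1 - ch1.mean()
    d2 = ch2 - ch2.mean()
    denom = np.sqrt((d1**2).sum() * (d2**2).sum())
    if denom == 0.0:
        raise ValueError("PCC undefined: a channel is constant")
    return float((d1 * d2).sum() / denom)


def pcc_normalized(ch1: np.ndarray, ch2: np.ndarray) -> float:
    """PCC mapped from [-1, 1] onto [0, 1] for comparison with M1/R1."""
    return (pcc(ch1, ch2) + 1.0) / 2.0


def manders(mask1: np.ndarray, mask2: np.ndarray) -> tuple[float, float]:
    """Binary Manders coefficients (M1, M2) from two signal masks.

    M1 = |mask1 & mask2| / |mask1| and symmetrically for M2; pixel
    counts of binary indicators, exactly as the thresholded-signal
    definition prescribes.
    """
    mask1 = np.asarray(mask1, dtype=bool)
    mask2 = np.asarray(mask2, dtype=bool)
    if mask1.shape != mask2.shape:
        raise ValueError("masks must share a shape")
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("Manders coefficient undefined for an empty mask")
    both = int((mask1 & mask2).sum())
    return both / n1, both / n2


def roi_overlap_ratio(labels1: np.ndarray, signal2: np.ndarray, theta: float) -> float:
    """Fraction of channel-1 ROIs colocalized with channel-2 signal.

    ROI a is colocalized when the fraction of its pixels that are signal
    in the other channel is >= theta *and* nonzero — so even at theta=0
    an ROI with no overlapping pixel never counts.
    """
    labels1 = np.asarray(labels1)
    signal2 = np.asarray(signal2, dtype=bool)
    if labels1.shape != signal2.shape:
        raise ValueError("label map and signal mask must share a shape")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("overlap threshold must be in [0, 1]")
    n = int(labels1.max(initial=0))
    if n == 0:
        raise ValueError("no ROIs in channel 1")
    coloc = 0
    for k in range(1, n + 1):
        roi = labels1 == k
        area = int(roi.sum())
        overlap = int((roi & signal2).sum())
        if overlap > 0 and overlap / area >= theta:
            coloc += 1
    return coloc / n


def colocalize(
    ch1: np.ndarray,
    ch2: np.ndarray,
    labels1: np.ndarray,
    labels2: np.ndarray,
    overlap_threshold: float,
) -> ColocalizationResult:
    """All three metric families for one crop.

    Manders and the overlap ratios use the post-restriction label
    support of each channel as its signal mask, so both channels have
    passed identical detection pipelines.
    """
    sig1 = np.asarray(labels1) > 0
    sig2 = np.asarray(labels2) > 0
    m1, m2 = manders(sig1, sig2)
    r1 = roi_overlap_ratio(labels1, sig2, overlap_threshold)
    r2 = roi_overlap_ratio(labels2, sig1, overlap_threshold)
    p = pcc(ch1, ch2)
    return ColocalizationResult(
        pcc=p,
        pcc_normalized=(p + 1.0) / 2.0,
        m1=m1,
        m2=m2,
        r1=r1,
        r2=r2,
        overlap_threshold=overlap_threshold,
    )


def overlap_curve(
    crop_results: Sequence[dict],
    thresholds: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """R1/R2 as functions of the overlap threshold over a dataset.

    ``crop_results`` holds one dict per crop with keys ``crop_id``,
    ``genotype``, ``labels1``, ``labels2``.  Returns a per-crop
    long-format table (crop_id, genotype, theta, r1, r2) and a
    per-genotype summary with mean and SD.  Per-crop failures (e.g. a
    channel with no ROIs) become missing values with a warning.
    """
    thetas = sorted(float(t) for t in thresholds)
    rows = []
    for rec in crop_results:
        lab1 = np.asarray(rec["labels1"])
        lab2 = np.asarray(rec["labels2"])
        sig1 = lab1 > 0
        sig2 = lab2 > 0
        for theta in thetas:
            try:
                r1 = roi_overlap_ratio(lab1, sig2, theta)
                r2 = roi_overlap_ratio(lab2, sig1, theta)
            except ValueError as exc:
                warnings.warn(f"crop {rec.get('crop_id')}: {exc}", stacklevel=2)
                r1 = r2 = float("nan")
            rows.append(
                {
                    "crop_id": rec.get("crop_id", ""),
                    "genotype": rec.get("genotype", ""),
                    "theta": theta,
                    "r1": r1,
                    "r2": r2,
                }
            )
    per_crop = pd.DataFrame(rows, columns=["crop_id", "genotype", "theta", "r1", "r2"])
    summary = (
        per_crop.groupby(["genotype", "theta"], sort=True)[["r1", "r2"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    summary.columns = ["genotype", "theta", "r1_mean", "r1_sd", "r2_mean", "r2_sd"]
    return per_crop, summary
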