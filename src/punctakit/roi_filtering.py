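"""Per-ROI measurement, restriction filters, and crop-level summaries.

Measurement produces one record per labeled ROI (area, intensity stats,
shape descriptors, position).  Restriction then drops ROIs that touch an
edge band of the crop (where autofluorescent gut granules impinge) or
violate feature bounds — area, circularity, length-to-width ratio,
within-ROI intensity variance — which removes the one-to-few-pixel
specks that camera noise throws above an adaptive threshold.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from skimage import measure

from .crop_io import RestrictionParams
from .detection import relabel_contiguous

ROI_COLUMNS = [
    "label",
    "area_px2",
    "area_um2",
    "sum_intensity",
    "mean_intensity",
    "max_intensity",
    "centroid_row",
    "centroid_col",
    "circularity",
    "length_width_ratio",
    "intensity_variance",
    "min_row",
    "min_col",
    "max_row",
    "max_col",
    "touches_x_margin",
    "touches_y_margin",
]


def _check_labels(labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    n = len(ids)
    if n and (ids[0] != 1 or ids[-1] != n):
        raise ValueError(f"labels must be contiguous 1..K, found ids {ids.tolist()}")
    return n


def measure_rois(labels: np.ndarray, channel: np.ndarray, pixel_size_um: float) -> pd.DataFrame:
    """Measure features for every label; one row per ROI, columns ``ROI_COLUMNS``.

    Conventions for degenerate ROIs: a single pixel has circularity 1,
    length-to-width ratio 1 and variance 0.  Circularity is 4*pi*A/P^2
    with the boundary-weighted perimeter, clamped to 1 (tiny digital
    regions can nominally exceed it).  A zero minor axis (perfectly
    straight multi-pixel ROI) gets the documented sentinel ratio = area.
    """
    labels = np.asarray(labels)
    channel = np.asarray(channel, dtype=float)
    if labels.shape != channel.shape:
        raise ValueError("labels and channel shapes differ")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    n = _check_labels(labels)
    h, w = labels.shape
    rows = []
    for p in measure.regionprops(labels, intensity_image=channel):
        area = float(p.area)
        pixels = channel[labels == p.label]
        var = float(np.var(pixels))
        if area == 1:
            circ = 1.0
            lw = 1.0
        else:
            perim = p.perimeter
            circ = 1.0 if perim == 0 else min(1.0, 4.0 * math.pi * area / perim**2)
            minor = p.axis_minor_length
            lw = area if minor == 0 else p.axis_major_length / minor
        minr, minc, maxr, maxc = p.bbox  # max exclusive
        rows.append(
            {
                "label": int(p.label),
                "area_px2": area,
                "area_um2": area * pixel_size_um**2,
                "sum_intensity": float(pixels.sum()),
                "mean_intensity": float(pixels.mean()),
                "max_intensity": float(pixels.max()),
                "centroid_row": float(p.centroid[0]),
                "centroid_col": float(p.centroid[1]),
                "circularity": circ,
                "length_width_ratio": float(lw),
                "intensity_variance": var,
                "min_row": int(minr),
                "min_col": int(minc),
                "max_row": int(maxr) - 1,
                "max_col": int(maxc) - 1,
                "touches_x_margin": bool(minc == 0 or maxc == w),
                "touches_y_margin": bool(minr == 0 or maxr == h),
            }
        )
    df = pd.DataFrame(rows, columns=ROI_COLUMNS)
    assert len(df) == n
    return df


def _keep_roi(row: pd.Series, params: RestrictionParams, shape: tuple[int, int]) -> bool:
    """Restriction predicate for one ROI record (True = survives)."""
    h, w = shape
    if params.x_edge_px > 0 and (
        row["min_col"] < params.x_edge_px or row["max_col"] >= w - params.x_edge_px
    ):
        return False
    if params.y_edge_px > 0 and (
        row["min_row"] < params.y_edge_px or row["max_row"] >= h - params.y_edge_px
    ):
        return False
    checks = (
        (params.min_area_px2, row["area_px2"], "ge"),
        (params.max_area_px2, row["area_px2"], "le"),
        (params.min_circularity, row["circularity"], "ge"),
        (params.max_circularity, row["circularity"], "le"),
        (params.max_length_width_ratio, row["length_width_ratio"], "le"),
        (params.min_variance, row["intensity_variance"], "ge"),
        (params.max_variance, row["intensity_variance"], "le"),
    )
    for bound, value, sense in checks:
        if bound is None:
            continue
        if sense == "ge" and value < bound:
            return False
        if sense == "le" and value > bound:
            return False
    return True


def restrict_rois(
    labels: np.ndarray, table: pd.DataFrame, params: RestrictionParams
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop ROIs failing the edge or feature rules; relabel survivors 1..K.

    Each ROI is judged independently, so the result does not depend on
    evaluation order and the operation is idempotent.  Survivor pixel
    sets are untouched; only ids change.
    """
    labels = np.asarray(labels)
    _check_labels(labels)
    if len(table) != int(labels.max(initial=0)):
        raise ValueError("table does not correspond to labels")
    keep = [bool(_keep_roi(row, params, labels.shape)) for _, row in table.iterrows()]
    survivors = table.loc[keep].copy()
    drop_ids = table.loc[[not k for k in keep], "label"].to_numpy()
    out = labels.copy()
    if len(drop_ids):
        out[np.isin(out, drop_ids)] = 0
    out = relabel_contiguous(out)
    survivors["label"] = np.arange(1, len(survivors) + 1, dtype=int)
    return out, survivors.reset_index(drop=True)


def count_per_100um(n_rois: int, crop_length_px: int, pixel_size_um: float) -> float:
    """Normalized ROI count per 100 um of crop length."""
    if crop_length_px < 1:
        raise ValueError("crop_length_px must be >= 1")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    return n_rois / (crop_length_px * pixel_size_um) * 100.0


def snr(channel: np.ndarray, roi_mask: np.ndarray) -> float:
    """Signal-to-noise ratio: summed intensity inside ROIs over outside."""
    channel = np.asarray(channel, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if channel.shape != roi_mask.shape:
        raise ValueError("mask shape must match channel shape")
    noise = float(channel[~roi_mask].sum())
    if noise == 0.0:
        raise ValueError("background intensity sum is zero; SNR undefined")
    return float(channel[roi_mask].sum()) / noise
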