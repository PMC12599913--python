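"""Validation against ground truth, comparison baselines, and the
sensitivity robustness sweep.

Segmentation quality is scored pixelwise against a ground-truth mask
with the receiver-operating characteristics TPR (sensitivity), TNR
(specificity) and their mean, Balanced Accuracy.  Because the 1D
plot-profile baseline cannot assign individual pixels, a column mode
collapses both masks column-wise first (a column is positive when it
holds at least one ROI pixel).

The robustness sweep re-runs the full detection pipeline over a grid of
sensitivity values around the chosen optimum and asks, per grid point,
whether genotype groups still separate (Welch one-way ANOVA), i.e.
whether the scientific conclusion depends on the exact setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .crop_io import AnalysisConfig, CropDataset
from .pipeline import analyze_channel
from .roi_filtering import count_per_100um


# ---------------------------------------------------------------------------
# confusion rates
# ---------------------------------------------------------------------------

@dataclass
class ConfusionRates:
    tpr: float
    tnr: float
    balanced_accuracy: float
    mode: str


def collapse_columns(mask: np.ndarray) -> np.ndarray:
    """Column-wise collapse: a column is positive if any pixel in it is."""
    return np.asarray(mask, dtype=bool).any(axis=0, keepdims=True)


def confusion_rates(pred: np.ndarray, truth: np.ndarray, mode: str = "pixel2d") -> ConfusionRates:
    """TPR, TNR and Balanced Accuracy of a predicted mask vs ground truth.

    TPR = true ROI px / total truth ROI px; TNR = true non-ROI px /
    total truth non-ROI px; BA = (TPR + TNR) / 2.  Ground truth with no
    positives (or no negatives) leaves the corresponding rate undefined
    and raises.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    if mode == "column1d":
        pred = collapse_columns(pred)
        truth = collapse_columns(truth)
    elif mode != "pixel2d":
        raise ValueError(f"unknown mode {mode!r}")
    pos = int(truth.sum())
    neg = truth.size - pos
    if pos == 0:
        raise ValueError("TPR undefined: ground truth has no ROI pixels")
    if neg == 0:
        raise ValueError("TNR undefined: ground truth has no background pixels")
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    tpr = tp / pos
    tnr = tn / neg
    return ConfusionRates(tpr=tpr, tnr=tnr, balanced_accuracy=(tpr + tnr) / 2.0, mode=mode)


# ---------------------------------------------------------------------------
# 1D plot-profile peakfinder baseline
# ---------------------------------------------------------------------------

@dataclass
class Peak:
    position: int
    height: float
    prominence: float
    width: float
    col_start: int
    col_stop: int  # inclusive


@dataclass
class PeakList:
    peaks: list[Peak]
    n_cols: int

    def to_column_mask(self) -> np.ndarray:
        """1 x n_cols boolean mask of the columns claimed by peaks."""
        mask = np.zeros((1, self.n_cols), dtype=bool)
        for p in self.peaks:
            mask[0, p.col_start : p.col_stop + 1] = True
        return mask

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Broadcast the claimed columns over a full crop height."""
        return np.broadcast_to(self.to_column_mask(), shape).copy()


def peakfinder_1d(
    channel: np.ndarray,
    min_prominence: float,
    max_width_cols: float,
    noise_to_signal_ratio: float = 0.0,
) -> PeakList:
    """1D sum-projection peak detection, the classic plot-profile method.

    The crop is collapsed to a profile by summing rows, then strict
    local maxima are kept when their prominence is >= ``min_prominence``,
    their width at half prominence is <= ``max_width_cols`` and their
    height clears ``noise_to_signal_ratio`` times the profile median (a
    relative noise floor).  Each surviving peak claims the column
    interval spanned by its half-prominence width.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim == 1:
        channel = channel[None, :]
    if channel.shape[0] < 1:
        raise ValueError("crop height must be >= 1")
    profile = channel.sum(axis=0)
    n = profile.size
    if profile.max() == profile.min():
        return PeakList(peaks=[], n_cols=n)
    floor = noise_to_signal_ratio * float(np.median(profile))
    idx, props = signal.find_peaks(
        profile,
        prominence=min_prominence,
        width=(None, max_width_cols),
        height=floor if floor > 0 else None,
        rel_height=0.5,
    )
    peaks = []
    for i, pos in enumerate(idx):
        lo = int(np.floor(props["left_ips"][i] + 0.5))
        hi = int(np.ceil(props["right_ips"][i] - 0.5))
        lo = max(0, min(lo, int(pos)))
        hi = min(n - 1, max(hi, int(pos)))
        peaks.append(
            Peak(
                position=int(pos),
                height=float(profile[pos]),
                prominence=float(props["prominences"][i]),
                width=float(props["widths"][i]),
                col_start=lo,
                col_stop=hi,
            )
        )
    return PeakList(peaks=peaks, n_cols=n)


# ---------------------------------------------------------------------------
# sensitivity robustness sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Counts and group-separation p-values over a sensitivity grid."""

    grid: list[float]
    counts: pd.DataFrame  # sensitivity, crop_id, genotype, n_rois, count_per_100um
    pvalues: pd.DataFrame  # sensitivity, p_value
    excluded_genotypes: list[str] = field(default_factory=list)


def sensitivity_grid(optimum: float, half_range: float = 0.15, step: float = 0.01) -> list[float]:
    """Grid of sensitivities centered on the optimum, clipped to [0, 1]."""
    n = int(round(half_range / step))
    vals = [round(optimum + k * step, 10) for k in range(-n, n + 1)]
    return [v for v in vals if 0.0 <= v <= 1.0]


def welch_anova_p(values: pd.DataFrame, dv: str, between: str) -> float:
    """Welch one-way ANOVA p-value (delegated to a standard routine).

    Welch's statistic divides by within-group variances, so groups with
    zero spread (possible here: noiseless scenes recovered perfectly)
    are degenerate.  If every group is constant the answer is forced:
    p=1 when all group means agree, p->0 when they differ.  If only some
    groups are constant the classic equal-variance ANOVA is used as the
    fallback.
    """
    from scipy import stats

    groups = [g[dv].to_numpy(dtype=float) for _, g in values.groupby(between)]
    variances = [g.var(ddof=1) if len(g) > 1 else 0.0 for g in groups]
    if all(v == 0.0 for v in variances):
        means = [g.mean() for g in groups]
        return 1.0 if len(set(means)) == 1 else 0.0
    if any(v == 0.0 for v in variances):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.f_oneway(*groups).pvalue)
        return 0.0 if np.isnan(p) else p
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.welch_anova(data=values, dv=dv, between=between)
    col = "p_unc" if "p_unc" in res.columns else "p-unc"
    return float(res[col].iloc[0])


def pairwise_gameshowell(values: pd.DataFrame, dv: str, between: str) -> pd.DataFrame:
    """Unequal-variance pairwise comparisons (Games-Howell), as glue."""
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pg.pairwise_gameshowell(data=values, dv=dv, between=between)


def sensitivity_sweep(
    dataset: CropDataset,
    base_config: AnalysisConfig,
    half_range: float = 0.15,
    step: float = 0.01,
    channel: int = 0,
    normalized: bool = False,
) -> SweepResult:
    """Re-run the full pipeline over a sensitivity grid and test robustness.

    For each grid point every active crop is re-thresholded, segmented
    and restricted, its ROI count (or count per 100 um when
    ``normalized``) recorded per genotype, and a Welch one-way ANOVA
    p-value computed across genotypes.  Genotypes with fewer than two
    crops are excluded from the test with a warning.
    """
    det = base_config.detection[channel]
    restr = base_config.restriction[channel]
    grid = sensitivity_grid(det.sensitivity, half_range, step)
    crops = dataset.active()

    sizes: dict[str, int] = {}
    for c in crops:
        sizes[c.genotype] = sizes.get(c.genotype, 0) + 1
    excluded = sorted(g for g, n in sizes.items() if n < 2)
    if excluded:
        warnings.warn(
            f"genotype(s) with <2 crops excluded from ANOVA: {', '.join(excluded)}",
            stacklevel=2,
        )
    tested = [g for g in sizes if g not in excluded]
    if len(tested) < 2:
        raise ValueError("sweep needs >= 2 genotypes with >= 2 crops each")

    count_rows = []
    p_rows = []
    dv = "count_per_100um" if normalized else "n_rois"
    for s in grid:
        det_s = type(det)(sensitivity=s, neighborhood_size=det.neighborhood_size, method=det.method)
        for crop in crops:
            res = analyze_channel(
                crop.channels[channel], det_s, restr, base_config.pixel_size_um
            )
            n = len(res.table)
            count_rows.append(
                {
                    "sensitivity": s,
                    "crop_id": crop.crop_id,
                    "genotype": crop.genotype,
                    "n_rois": n,
                    "count_per_100um": count_per_100um(
                        n, crop.length_px, base_config.pixel_size_um
                    ),
                }
            )
        df = pd.DataFrame([r for r in count_rows if r["sensitivity"] == s])
        df = df[df["genotype"].isin(tested)]
        p_rows.append({"sensitivity": s, "p_value": welch_anova_p(df, dv, "genotype")})

    return SweepResult(
        grid=grid,
        counts=pd.DataFrame(count_rows),
        pvalues=pd.DataFrame(p_rows),
        excluded_genotypes=excluded,
    )
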