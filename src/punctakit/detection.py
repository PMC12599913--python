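"""Puncta detection: thresholding and watershed segmentation.

The primary threshold is an adaptive local-means (Bradley) rule: a pixel
is signal when its intensity exceeds the mean of its square neighborhood
scaled by a sensitivity factor.  Adaptive thresholds cope with the
sloping backgrounds and low signal-to-noise of straightened nerve-cord
crops far better than a single global cut; a global Otsu threshold is
kept as the comparison baseline.

Touching puncta that threshold into one connected component are split by
a marker-free watershed on the elevation

    E = -(bwdist(~mask) * normImg)

i.e. the negative product of the Euclidean distance to the nearest
background pixel and the min-max-normalized intensity, so basins deepen
both toward punctum centers (distance) and toward bright pixels
(intensity).  Flooding starts from the regional minima of E inside the
mask; watershed ridge lines are left as background.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation

from .crop_io import DetectionParams

_EIGHT = np.ones((3, 3), dtype=bool)


def normalize_image(channel: np.ndarray) -> np.ndarray:
    """Min-max rescale a channel to [0, 1]; a constant image maps to zeros."""
    channel = np.asarray(channel, dtype=float)
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    lo = channel.min()
    hi = channel.max()
    if hi == lo:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def local_mean(channel: np.ndarray, neighborhood_size: int) -> np.ndarray:
    """Window mean at every pixel with edge-replicated padding."""
    if neighborhood_size < 3 or neighborhood_size % 2 == 0:
        raise ValueError(f"neighborhood_size must be odd and >= 3, got {neighborhood_size}")
    channel = np.asarray(channel, dtype=float)
    mu = ndi.uniform_filter(channel, size=neighborhood_size, mode="nearest")
    if channel.min() >= 0.0:
        # running-sum rounding can drift a flat zero background to ~-1e-17,
        # which would flip the strict comparison; the true mean of a
        # non-negative window is non-negative
        np.clip(mu, 0.0, None, out=mu)
    return mu


def bradley_threshold(channel: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Adaptive local-means threshold.

    Pixel p is foreground iff ``I(p) > mean_w(p) * 2 * (1 - s)`` where
    ``mean_w`` is the neighborhood mean and ``s`` the sensitivity.  The
    mapping makes s=0.5 a plain compare-to-local-mean and is monotone:
    raising s (more permissive) can only grow the mask on non-negative
    images.  Comparison is strict, so flat zero regions yield no signal.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(channel)):
        raise ValueError("channel contains non-finite pixels")
    mu = local_mean(channel, params.neighborhood_size)
    return channel > mu * 2.0 * (1.0 - params.sensitivity)


def otsu_threshold(channel: np.ndarray) -> np.ndarray:
    """Global Otsu baseline on a 256-bin histogram of the normalized image.

    Foreground is strictly above the between-class-variance-maximizing
    threshold; a constant image has no separating threshold and returns
    an empty mask.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty image")
    norm = normalize_image(channel)
    if norm.max() == 0.0 and channel.max() == channel.min():
        return np.zeros(channel.shape, dtype=bool)
    t = filters.threshold_otsu(norm, nbins=256)
    return norm > t


def segment_rois(mask: np.ndarray, channel: np.ndarray) -> np.ndarray:
    """Split a foreground mask into labeled ROIs by intensity-weighted watershed.

    Elevation is ``-(D * normImg)`` with D the Euclidean distance to the
    nearest background pixel (zero on background).  Each 8-connected
    regional-minimum plateau of the elevation inside the mask seeds one
    basin; flooding is 8-connected and confined to the mask, and ridge
    pixels between basins stay background.  Labels are relabeled to a
    contiguous 1..K in seed order, so output is fully deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    channel = np.asarray(channel, dtype=float)
    if mask.shape != channel.shape:
        raise ValueError(f"mask shape {mask.shape} != channel shape {channel.shape}")
    labels = np.zeros(mask.shape, dtype=np.int32)
    if not mask.any():
        return labels

    norm = normalize_image(channel)
    dist = ndi.distance_transform_edt(mask)
    elevation = -(dist * norm)

    # regional minima restricted to the mask: background forced above any
    # in-mask elevation so it can never form or join a minimum plateau
    guarded = np.where(mask, elevation, 1.0)
    minima = morphology.local_minima(guarded, connectivity=2) & mask
    markers, n_seeds = ndi.label(minima, structure=_EIGHT)
    if n_seeds == 0:  # pragma: no cover - mask nonempty always yields a minimum
        return labels

    ws = segmentation.watershed(
        elevation, markers=markers, mask=mask, connectivity=2, watershed_line=True
    )
    return relabel_contiguous(ws)


def relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel positive labels to contiguous 1..K preserving label order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max(initial=0)) + 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]


def detect(channel: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Threshold (per ``params.method``) then watershed-segment one channel."""
    if params.method == "global_otsu":
        mask = otsu_threshold(channel)
    else:
        mask = bradley_threshold(channel, params)
    return segment_rois(mask, channel)
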